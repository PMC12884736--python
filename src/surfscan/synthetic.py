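"""Synthetic fixtures emulating every input the instrument produces.

The generators stand in for the physical system: smooth irregular tissue
surfaces at the ~15 x 15 x 10 mm scale with height variation up to
~10 mm, fluorescence tissue textures with bright nuclei on dimmer
cytoplasm (positive-margin tissue gets denser, larger, brighter and more
disorganised nuclei than negative tissue), focal stacks whose per-pixel
blur grows with distance from a focus plane, and chessboard calibration
scenes projected through a known ground-truth homography.  Every
generator is a pure function of its parameters and seed: repeated calls
are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import (
    CameraIntrinsics,
    ChessboardModel,
    ExtrinsicPose,
    compose_homography,
)
from .cad import SubImage, tile_image
from .fusion import FocalStack
from .geometry import SurfaceMesh

__all__ = [
    "TissueParams",
    "DefocusModel",
    "make_surface",
    "make_tissue_texture",
    "make_focal_stack",
    "make_calibration_scene",
    "make_margin_dataset",
]


@dataclass(frozen=True)
class TissueParams:
    """Parameters of a simulated fluorescence tissue texture.

    Densities are nuclei per mm^2; radii in micrometres; intensities in
    the 16-bit range.  ``disorganised`` relaxes the minimum nucleus
    spacing from one mean radius to 0.3 of it, mimicking the crowded,
    irregular nuclear arrangement of malignant tissue.
    """

    nuclear_density: float = 800.0
    radius_mean: float = 4.0
    radius_sd: float = 0.8
    nuclear_intensity: float = 12000.0
    cytoplasm_intensity: float = 4000.0
    noise_sd: float = 300.0
    disorganised: bool = False

    def __post_init__(self) -> None:
        if self.nuclear_density < 0:
            raise ValueError("density must be >= 0")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be > 0")


#: Paired defaults for the margin classes: positive tissue has strictly
#: higher nuclear density, radius and intensity than negative tissue.
POSITIVE_TISSUE = TissueParams(
    nuclear_density=2200.0,
    radius_mean=5.5,
    radius_sd=1.2,
    nuclear_intensity=15000.0,
    cytoplasm_intensity=4000.0,
    noise_sd=300.0,
    disorganised=True,
)
NEGATIVE_TISSUE = TissueParams(
    nuclear_density=800.0,
    radius_mean=4.0,
    radius_sd=0.8,
    nuclear_intensity=11000.0,
    cytoplasm_intensity=4000.0,
    noise_sd=300.0,
    disorganised=False,
)


@dataclass(frozen=True)
class DefocusModel:
    """Linear defocus: blur sigma (px) = blur_scale * |elevation - focus|."""

    focus_elevation: float = 0.0  # mm
    blur_scale: float = 20.0  # px per mm of defocus

    def __post_init__(self) -> None:
        if self.blur_scale < 0:
            raise ValueError("blur_scale must be >= 0")


def make_surface(shape: str, params: dict | None = None, seed: int = 0) -> SurfaceMesh:
    """Generate a fixture surface mesh.

    Shapes
    ------
    plane : flat rectangle; params ``extent`` (mm, default 15) and
        ``spacing`` (mm, default 0.5).
    hemisphere : upper half-sphere, apex up; params ``radius`` (default
        7.5) and ``n_theta`` rings (default 24).
    ellipsoid : upper half of an axis-aligned ellipsoid; params
        ``semi_axes`` (default (7.5, 6.0, 5.0)).
    bumpy : plane plus a seeded smooth random height field; params
        ``amplitude`` (mm, default 2), ``extent``, ``spacing``,
        ``correlation`` (mm, default 3).
    """
    params = dict(params or {})
    if shape == "plane":
        return _plane_mesh(params.get("extent", 15.0), params.get("spacing", 0.5))
    if shape == "hemisphere":
        return _dome_mesh((params.get("radius", 7.5),) * 3, params.get("n_theta", 24))
    if shape == "ellipsoid":
        return _dome_mesh(tuple(params.get("semi_axes", (7.5, 6.0, 5.0))), params.get("n_theta", 24))
    if shape == "bumpy":
        return _bumpy_mesh(
            params.get("extent", 15.0),
            params.get("spacing", 0.5),
            params.get("amplitude", 2.0),
            params.get("correlation", 3.0),
            seed,
        )
    raise ValueError(f"unknown surface shape {shape!r}")


def _plane_grid(extent: float, spacing: float) -> tuple[np.ndarray, np.ndarray, int, int]:
    if extent <= 0 or spacing <= 0:
        raise ValueError("extent and spacing must be > 0")
    n = max(2, int(round(extent / spacing)) + 1)
    axis = np.linspace(-extent / 2.0, extent / 2.0, n)
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    return xx, yy, n, n


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + 1
            c = a + ny
            d = c + 1
            faces.append([a, c, b])
            faces.append([b, c, d])
    return np.array(faces, dtype=np.int64)


def _plane_mesh(extent: float, spacing: float) -> SurfaceMesh:
    xx, yy, nx, ny = _plane_grid(extent, spacing)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    normals = np.tile([0.0, 0.0, 1.0], (len(vertices), 1))
    return SurfaceMesh(vertices, _grid_faces(nx, ny), normals)


def _bumpy_mesh(
    extent: float, spacing: float, amplitude: float, correlation: float, seed: int
) -> SurfaceMesh:
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    xx, yy, nx, ny = _plane_grid(extent, spacing)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nx, ny))
    height = ndimage.gaussian_filter(noise, sigma=correlation / spacing, mode="reflect")
    span = np.ptp(height)
    if span > 0:
        height = (height - height.min()) / span * amplitude
    vertices = np.column_stack([xx.ravel(), yy.ravel(), height.ravel()])
    return SurfaceMesh(vertices, _grid_faces(nx, ny))


def _dome_mesh(semi_axes: tuple[float, float, float], n_theta: int) -> SurfaceMesh:
    ax, ay, az = semi_axes
    if min(semi_axes) <= 0:
        raise ValueError("semi-axes must be > 0")
    thetas = np.linspace(0.0, np.pi / 2.0, n_theta + 1)
    vertices = [np.array([0.0, 0.0, az])]
    rings: list[np.ndarray] = []
    for theta in thetas[1:]:
        n_phi = max(6, int(round(4 * n_theta * np.sin(theta))))
        phis = np.arange(n_phi) * 2 * np.pi / n_phi
        ring = np.column_stack(
            [
                ax * np.sin(theta) * np.cos(phis),
                ay * np.sin(theta) * np.sin(phis),
                az * np.cos(theta) * np.ones(n_phi),
            ]
        )
        rings.append(np.arange(len(vertices), len(vertices) + n_phi))
        vertices.extend(ring)
    vertices = np.asarray(vertices)

    faces = []
    first = rings[0]
    for k in range(len(first)):
        faces.append([0, first[k], first[(k + 1) % len(first)]])
    for upper, lower in zip(rings[:-1], rings[1:]):
        faces.extend(_stitch_rings(upper, lower))
    faces = np.array(faces, dtype=np.int64)

    # outward normals of the ellipsoid: gradient of the implicit function
    normals = vertices / np.array([ax**2, ay**2, az**2])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfaceMesh(vertices, faces, normals)


def _stitch_rings(upper: np.ndarray, lower: np.ndarray) -> list[list[int]]:
    faces = []
    nu, nl = len(upper), len(lower)
    i = j = 0
    while i < nu or j < nl:
        next_u = (i + 1) / nu if i < nu else np.inf
        next_l = (j + 1) / nl if j < nl else np.inf
        if next_u <= next_l:
            faces.append([upper[i % nu], lower[j % nl], upper[(i + 1) % nu]])
            i += 1
        else:
            faces.append([upper[i % nu], lower[j % nl], lower[(j + 1) % nl]])
            j += 1
    return faces


def make_tissue_texture(
    params: TissueParams,
    extent_mm: float = 0.6,
    pixel_pitch_um: float = 0.9,
    seed: int = 0,
    max_attempts: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated fluorescence texture with its ground-truth nucleus mask.

    Nuclei are placed by Poisson-disk (dart-throwing) sampling at the
    requested density with minimum spacing of one mean radius (0.3 mean
    radii when ``disorganised``); per-nucleus radii are
    Normal(radius_mean, radius_sd) truncated positive.  Nuclei are
    rendered brighter than the cytoplasm background and Gaussian read
    noise is added.  Returns (image float64 in 16-bit range, bool mask).

    Raises
    ------
    RuntimeError
        If the density is so high that placement fails after bounded
        retries.
    """
    if extent_mm <= 0 or pixel_pitch_um <= 0:
        raise ValueError("extent and pitch must be > 0")
    rng = np.random.default_rng(seed)
    n_px = int(round(extent_mm * 1000.0 / pixel_pitch_um))
    area_mm2 = extent_mm**2
    n_target = int(rng.poisson(params.nuclear_density * area_mm2))

    min_spacing_px = (0.3 if params.disorganised else 1.0) * params.radius_mean / pixel_pitch_um
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_target and attempts < max_attempts * max(1, n_target):
        cand = rng.uniform(0, n_px, size=2)
        attempts += 1
        if centers:
            d = np.linalg.norm(np.asarray(centers) - cand, axis=1)
            if d.min() < min_spacing_px:
                continue
        centers.append((cand[0], cand[1]))
    if n_target > 0 and len(centers) < 0.5 * n_target:
        raise RuntimeError(
            f"nucleus placement failed: placed {len(centers)} of {n_target}"
        )

    image = np.full((n_px, n_px), params.cytoplasm_intensity, dtype=float)
    mask = np.zeros((n_px, n_px), dtype=bool)
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    for cy, cx in centers:
        r_um = rng.normal(params.radius_mean, params.radius_sd)
        while r_um <= 0:
            r_um = rng.normal(params.radius_mean, params.radius_sd)
        r_px = r_um / pixel_pitch_um
        y0, y1 = max(0, int(cy - r_px) - 1), min(n_px, int(cy + r_px) + 2)
        x0, x1 = max(0, int(cx - r_px) - 1), min(n_px, int(cx + r_px) + 2)
        disk = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r_px**2
        mask[y0:y1, x0:x1] |= disk
    image[mask] = params.nuclear_intensity
    image += rng.normal(0.0, params.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 65535.0), mask


def make_focal_stack(
    sharp_image: np.ndarray,
    elevations: np.ndarray,
    defocus: DefocusModel,
    grid_id: int = 0,
) -> FocalStack:
    """Blur a sharp image per elevation to emulate a focal stack.

    Frame i is the sharp image convolved with an isotropic Gaussian of
    sigma = ``blur_scale * |elevation_i - focus_elevation|`` pixels
    (sigma 0 leaves the frame untouched).
    """
    elevations = np.asarray(elevations, dtype=float).reshape(-1)
    if len(elevations) < 1:
        raise ValueError("need at least one elevation")
    frames = []
    for e in elevations:
        sigma = defocus.blur_scale * abs(e - defocus.focus_elevation)
        if sigma == 0:
            frames.append(np.asarray(sharp_image, dtype=float).copy())
        else:
            frames.append(ndimage.gaussian_filter(np.asarray(sharp_image, dtype=float), sigma))
    return FocalStack(frames=np.stack(frames), elevations=elevations, grid_id=grid_id)


def make_calibration_scene(
    true_m: float,
    true_pose: ExtrinsicPose | None = None,
    noise_px: float = 0.0,
    seed: int = 0,
    du: float = 4.5,
    pixel_n: int = 5120,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the 13 chessboard dots through a known homography.

    Returns (image_dots_px, board_dots_mm): the dots' pixel displacements
    from the FOV centre (with seeded Gaussian noise of ``noise_px``) and
    their true board coordinates.
    """
    if true_m <= 0:
        raise ValueError("true_m must be > 0")
    pose = true_pose or ExtrinsicPose.identity()
    intr = CameraIntrinsics(m=true_m, du=du, pixel_n=pixel_n)
    h = compose_homography(intr, pose)
    board_mm = ChessboardModel().dot_coordinates_mm()
    image_px = h.apply(board_mm * 1000.0)
    if noise_px > 0:
        rng = np.random.default_rng(seed)
        image_px = image_px + rng.normal(0.0, noise_px, size=image_px.shape)
    return image_px, board_mm


def make_margin_dataset(
    n_pos: int,
    n_neg: int,
    pos_params: TissueParams = POSITIVE_TISSUE,
    neg_params: TissueParams = NEGATIVE_TISSUE,
    seed: int = 0,
    tile_size: int = 128,
    pixel_pitch_um: float = 0.9,
) -> list[SubImage]:
    """Labelled subimages for margin-classifier training and testing.

    Textures are generated per class (positive tissue must have strictly
    greater nuclear density and mean radius than negative tissue), tiled
    into ``tile_size`` subimages, and labelled.  Reproducible per seed.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subimage per class")
    if not (
        pos_params.nuclear_density > neg_params.nuclear_density
        and pos_params.radius_mean > neg_params.radius_mean
    ):
        raise ValueError(
            "positive tissue must have strictly greater density and radius_mean"
        )
    subs: list[SubImage] = []
    for label, n_needed, params, sub_seed in (
        ("positive", n_pos, pos_params, seed * 2 + 1),
        ("negative", n_neg, neg_params, seed * 2 + 2),
    ):
        collected = 0
        texture_idx = 0
        while collected < n_needed:
            # one texture yields a block of tiles; repeat until enough
            tiles_per_side = max(2, int(np.ceil(np.sqrt(n_needed - collected))))
            extent_mm = tiles_per_side * tile_size * pixel_pitch_um / 1000.0
            img, _ = make_tissue_texture(
                params,
                extent_mm=extent_mm,
                pixel_pitch_um=pixel_pitch_um,
                seed=hash((sub_seed, texture_idx)) % (2**31),
            )
            for tile in tile_image(img, size=tile_size):
                if collected >= n_needed:
                    break
                tile.label = label
                subs.append(tile)
                collected += 1
            texture_idx += 1
    return subs
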