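"""Mapping fused tiles onto the surface mesh and rendering utilities.

Fused 2D tiles are projected onto mesh facets through the estimated
homography and the per-grid microscope pose.  Facets seen by several
tiles get a single view assigned by a pairwise Markov random field
(unary cost = viewing obliquity, pairwise cost = label disagreement
between edge-adjacent facets), solved with iterated conditional modes.
Brightness seams between neighbouring views are removed by
gradient-domain (Poisson) editing.  Rendering helpers provide the
intensity inversion that makes nuclei dark on a bright background, a
deterministic Beer-Lambert pseudo-H&E colormap, and the colour-moment
loss used to score colour consistency between image pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from .calibration import Homography
from .fusion import FusedTile
from .geometry import SurfaceMesh
from .trajectory import MicroscopePose

__all__ = [
    "TexturedSurface",
    "ColorMoments",
    "project_tile",
    "select_views",
    "view_energy",
    "blend_brightness",
    "seam_jump",
    "invert_intensity",
    "color_moment_loss",
    "pseudo_he_render",
]

# Beer-Lambert absorption vectors (R, G, B) for the pseudo-H&E colormap;
# hematoxylin transmits blue-purple, eosin transmits pink.
HEMATOXYLIN_RGB = np.array([0.65, 0.70, 0.29])
EOSIN_RGB = np.array([0.07, 0.99, 0.11])


@dataclass
class ColorMoments:
    """Per-channel mean and standard deviation of an image."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def of(cls, image: np.ndarray) -> "ColorMoments":
        img = np.asarray(image, dtype=float)
        if img.ndim == 2:
            img = img[..., None]
        flat = img.reshape(-1, img.shape[-1])
        return cls(mean=flat.mean(axis=0), std=flat.std(axis=0))


@dataclass
class TexturedSurface:
    """A mesh with per-facet view assignment and texture coordinates."""

    mesh: SurfaceMesh
    facet_view: np.ndarray  # per-facet tile id, -1 = unassigned
    atlas: dict = field(default_factory=dict)  # tile id -> image
    texcoords: dict = field(default_factory=dict)  # facet id -> (3, 2) pixels
    seam_set: list = field(default_factory=list)  # (facet_a, facet_b) pairs

    def compute_seams(self) -> None:
        """Populate seam_set with edge-adjacent facet pairs whose views differ."""
        self.seam_set = [
            (int(a), int(b))
            for a, b in _facet_adjacency(self.mesh.facets)
            if self.facet_view[a] != self.facet_view[b]
            and self.facet_view[a] >= 0
            and self.facet_view[b] >= 0
        ]


def _facet_adjacency(facets: np.ndarray) -> list[tuple[int, int]]:
    edge_map: dict[tuple[int, int], int] = {}
    pairs = []
    for fid, (a, b, c) in enumerate(facets):
        for e in ((a, b), (b, c), (c, a)):
            key = (min(e), max(e))
            if key in edge_map:
                pairs.append((edge_map[key], fid))
            else:
                edge_map[key] = fid
    return pairs


def project_tile(
    tile: FusedTile,
    pose: MicroscopePose,
    h_hat: Homography,
    mesh: SurfaceMesh,
) -> dict[int, np.ndarray]:
    """Texture coordinates of facets whose centroid projects into a tile.

    A surface point ``p`` is expressed in the tile's camera frame (axes =
    the pose's rotation columns, origin on the optical axis at the pose
    target), its in-plane millimetre coordinates are converted to
    micrometres and pushed through the homography, and the result is
    offset to the tile's pixel centre.  Facets whose centroid lands
    outside the tile footprint stay unassigned.

    Returns a mapping facet id -> (3, 2) pixel coordinates of its vertices.
    """
    rot = pose.rotation_matrix()
    origin = np.array([pose.x, pose.y, pose.z])
    h, w = tile.image.shape[:2]
    center_px = np.array([w / 2.0, h / 2.0])

    def to_pixels(points: np.ndarray) -> np.ndarray:
        local = (points - origin) @ rot  # camera-frame coordinates
        uv_um = local[:, :2] * 1000.0
        return h_hat.apply(uv_um) + center_px

    out: dict[int, np.ndarray] = {}
    centroids = mesh.vertices[mesh.facets].mean(axis=1)
    cpx = to_pixels(centroids)
    inside = (
        (cpx[:, 0] >= 0) & (cpx[:, 0] < w) & (cpx[:, 1] >= 0) & (cpx[:, 1] < h)
    )
    for fid in np.nonzero(inside)[0]:
        out[int(fid)] = to_pixels(mesh.vertices[mesh.facets[fid]])
    return out


def pixel_to_plane_mm(
    px: np.ndarray, pose: MicroscopePose, h_hat: Homography, tile_shape: tuple[int, int]
) -> np.ndarray:
    """Inverse of the projection: pixels back to world mm on the tile plane."""
    h, w = tile_shape
    center_px = np.array([w / 2.0, h / 2.0])
    uv_um = h_hat.inverse_apply(np.atleast_2d(px) - center_px)
    rot = pose.rotation_matrix()
    origin = np.array([pose.x, pose.y, pose.z])
    local = np.hstack([uv_um / 1000.0, np.zeros((len(uv_um), 1))])
    return origin + local @ rot.T


def view_energy(
    assignment: np.ndarray,
    unary: list[dict[int, float]],
    adjacency: list[tuple[int, int]],
    lam: float,
) -> float:
    """MRF energy: sum of unary costs + lam per disagreeing adjacent pair."""
    e = 0.0
    for f, label in enumerate(assignment):
        if label >= 0:
            e += unary[f][int(label)]
    for a, b in adjacency:
        if assignment[a] >= 0 and assignment[b] >= 0 and assignment[a] != assignment[b]:
            e += lam
    return e


def select_views(
    facet_normals: np.ndarray,
    candidates: list[list[int]],
    tile_axes: dict[int, np.ndarray],
    facets: np.ndarray,
    lam: float = 0.5,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Assign one tile per facet with a pairwise MRF.

    Unary cost is the viewing obliquity ``1 - cos(angle(facet normal,
    tile axis))``; each edge-adjacent facet pair with differing labels
    pays ``lam``.  Minimised by iterated conditional modes from the
    best-unary initialisation, sweeping facets in index order; the energy
    never increases across sweeps.  Facets without candidates stay
    unassigned (-1).
    """
    n = len(candidates)
    unary: list[dict[int, float]] = []
    for f in range(n):
        costs = {}
        for t in candidates[f]:
            axis = tile_axes[t] / np.linalg.norm(tile_axes[t])
            costs[t] = 1.0 - float(np.dot(facet_normals[f], axis))
        unary.append(costs)

    assignment = np.full(n, -1, dtype=np.int64)
    for f in range(n):
        if unary[f]:
            assignment[f] = min(unary[f], key=lambda t: (unary[f][t], t))

    adjacency = _facet_adjacency(facets)
    neighbours: list[list[int]] = [[] for _ in range(n)]
    for a, b in adjacency:
        neighbours[a].append(b)
        neighbours[b].append(a)

    for _ in range(max_sweeps):
        changed = False
        for f in range(n):
            if not unary[f]:
                continue
            best_t, best_c = int(assignment[f]), np.inf
            for t in sorted(unary[f]):
                c = unary[f][t] + lam * sum(
                    1 for nb in neighbours[f] if assignment[nb] >= 0 and assignment[nb] != t
                )
                if c < best_c - 1e-15:
                    best_t, best_c = t, c
            if best_t != assignment[f]:
                assignment[f] = best_t
                changed = True
        if not changed:
            break
    return assignment


def seam_jump(atlas: dict, seams: list) -> float:
    """Mean absolute cross-seam intensity step.

    ``seams`` entries are ``(id_a, pixels_a, id_b, pixels_b)`` with
    elementwise-corresponding (n, 2) row/col index arrays.
    """
    diffs = []
    for id_a, pix_a, id_b, pix_b in seams:
        va = atlas[id_a][tuple(np.asarray(pix_a).T)]
        vb = atlas[id_b][tuple(np.asarray(pix_b).T)]
        diffs.append(np.abs(va - vb))
    if not diffs:
        return 0.0
    return float(np.concatenate(diffs).mean())


def blend_brightness(
    atlas: dict,
    seams: list,
    tol: float = 1e-6,
) -> dict:
    """Remove brightness seams between patches by Poisson editing.

    For each patch the discrete Poisson equation is solved with the
    source patch's own Laplacian as the interior target (gradients
    preserved), natural (Neumann) boundaries elsewhere, and Dirichlet
    values at seam pixels fixed to the across-seam average of the two
    patches.  Patches of identical brightness are left unchanged; a
    constant brightness offset between two patches is removed entirely.

    Raises
    ------
    RuntimeError
        If a linear solve leaves a relative residual above ``tol``.
    """
    dirichlet: dict[int, dict[tuple[int, int], float]] = {k: {} for k in atlas}
    for id_a, pix_a, id_b, pix_b in seams:
        pa = np.asarray(pix_a)
        pb = np.asarray(pix_b)
        va = atlas[id_a][tuple(pa.T)]
        vb = atlas[id_b][tuple(pb.T)]
        avg = 0.5 * (va + vb)
        for p, val in zip(pa, avg):
            dirichlet[id_a][tuple(p)] = float(val)
        for p, val in zip(pb, avg):
            dirichlet[id_b][tuple(p)] = float(val)

    out = {}
    for pid, img in atlas.items():
        if not dirichlet[pid]:
            out[pid] = img.copy()
            continue
        out[pid] = _poisson_solve(np.asarray(img, dtype=float), dirichlet[pid], tol)
    return out


def _neumann_laplacian(img: np.ndarray) -> np.ndarray:
    """5-point Laplacian with mirrored (zero-flux) boundaries."""
    h, w = img.shape
    lap = np.zeros_like(img)
    lap[1:, :] += img[:-1, :] - img[1:, :]
    lap[:-1, :] += img[1:, :] - img[:-1, :]
    lap[:, 1:] += img[:, :-1] - img[:, 1:]
    lap[:, :-1] += img[:, 1:] - img[:, :-1]
    return lap


def _poisson_solve(
    img: np.ndarray, dirichlet: dict[tuple[int, int], float], tol: float
) -> np.ndarray:
    h, w = img.shape
    n = h * w
    rhs_full = _neumann_laplacian(img)

    idx = lambda r, c: r * w + c  # noqa: E731
    a = lil_matrix((n, n))
    rhs = np.zeros(n)
    fixed = dirichlet
    for r in range(h):
        for c in range(w):
            i = idx(r, c)
            if (r, c) in fixed:
                a[i, i] = 1.0
                rhs[i] = fixed[(r, c)]
                continue
            nbs = [
                (r + dr, c + dc)
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            a[i, i] = -len(nbs)
            for nb in nbs:
                a[i, idx(*nb)] = 1.0
            rhs[i] = rhs_full[r, c]

    sol = spsolve(a.tocsr(), rhs)
    resid = np.linalg.norm(a.tocsr() @ sol - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if resid / scale > tol:
        raise RuntimeError(f"Poisson solve residual {resid / scale:.2e} exceeds {tol}")
    return sol.reshape(h, w)


def invert_intensity(image: np.ndarray, i_max: float | None = None) -> np.ndarray:
    """Pixelwise ``I_max - I`` so bright nuclei render dark.

    ``i_max`` defaults to the dtype maximum for integer images and to the
    image maximum for float images.  Double inversion is the identity.
    """
    image = np.asarray(image)
    if i_max is None:
        if np.issubdtype(image.dtype, np.integer):
            i_max = float(np.iinfo(image.dtype).max)
        else:
            i_max = float(image.max())
    return (i_max - image.astype(float)).astype(image.dtype) if np.issubdtype(
        image.dtype, np.integer
    ) else i_max - image


def color_moment_loss(img_a: np.ndarray, img_b: np.ndarray, reduction: str = "mean") -> float:
    """Colour-moment loss between two images.

    ``loss = MSE(mean_a, mean_b) + MSE(std_a, std_b)`` over the
    per-channel mean and standard-deviation vectors.  ``reduction``
    selects whether the squared differences are averaged (default) or
    summed over channels.  Symmetric, non-negative, and invariant to any
    spatial permutation of pixels.
    """
    ma = ColorMoments.of(img_a)
    mb = ColorMoments.of(img_b)
    if ma.mean.shape != mb.mean.shape:
        raise ValueError("images differ in channel count")
    dmean = (ma.mean - mb.mean) ** 2
    dstd = (ma.std - mb.std) ** 2
    if reduction == "mean":
        return float(dmean.mean() + dstd.mean())
    if reduction == "sum":
        return float(dmean.sum() + dstd.sum())
    raise ValueError("reduction must be 'mean' or 'sum'")


def pseudo_he_render(
    nuclear: np.ndarray,
    background: np.ndarray,
    c_h: np.ndarray = HEMATOXYLIN_RGB,
    c_e: np.ndarray = EOSIN_RGB,
    gain: float = 1.0,
) -> np.ndarray:
    """Deterministic Beer-Lambert pseudo-H&E rendering.

    Registered single-channel nuclear and background (cytoplasm) signals
    in [0, 1] are mapped to ``RGB = 255 * exp(-(c_H * nuclear + c_E *
    background) * gain)``: zero signal is pure white, nuclear signal
    darkens toward the hematoxylin blue-purple, background toward the
    eosin pink, and increasing either signal never brightens any channel.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    background = np.asarray(background, dtype=float)
    if nuclear.shape != background.shape:
        raise ValueError("nuclear and background images must share a shape")
    od = (
        nuclear[..., None] * np.asarray(c_h)[None, None, :]
        + background[..., None] * np.asarray(c_e)[None, None, :]
    ) * gain
    rgb = 255.0 * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
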