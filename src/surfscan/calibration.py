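"""Microscope projection model and mechanical-platform calibration fits.

The microscope is modelled as an infinity-corrected optical system.  Its
intrinsic matrix is

    A = [[m/du, 0,    0],
         [0,    m/du, 0],
         [0,    0,    1]]

with magnification ``m`` (dimensionless) and sensor pixel pitch ``du``
(micrometres), so A converts micrometres on the sample plane to pixels.
The extrinsic matrix B carries the in-plane rotation rows (r11..r23) and
translation (tx, ty, micrometres) of the microscope relative to the
calibration chessboard, and the homography H = A @ B maps chessboard-plane
coordinates to pixel displacements from the field-of-view centre at
(pixel_N/2, pixel_N/2).

Calibration proceeds in three steps, each fit here:

1. *Microscope*: effective magnification by bundle adjustment over the 13
   chessboard dots, then the extrinsic pose until the sensor is parallel
   to the board.
2. *Rotation stages*: per-step positional corrections from the chessboard
   centre's pixel deviation, ``offset = H_hat^-1 @ (O_x - N/2, O_y - N/2,
   1)``, linearly interpolated between steps; the R_z stage's true axis
   from a circle fit of the centre-dot track.
3. *Linear stages*: axis-skew angles from total-least-squares line fits of
   chessboard square vertices.

Units inside this module are micrometres; geometry elsewhere in the
package is millimetres, and conversions are explicit at call sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "ExtrinsicPose",
    "Homography",
    "ChessboardModel",
    "intrinsic_matrix",
    "compose_homography",
    "estimate_magnification",
    "estimate_extrinsic",
    "rotation_offset",
    "interpolate_offsets",
    "fit_circle",
    "fit_axis_skew",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Intrinsic matrix of the infinity-corrected microscope."""

    m: float  # magnification
    du: float  # sensor pixel pitch, um
    pixel_n: int = 5120  # pixels per sensor side

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("magnification must be > 0")
        if self.du <= 0:
            raise ValueError("pixel pitch must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        s = self.m / self.du  # pixels per um
        return np.array([[s, 0.0, 0.0], [0.0, s, 0.0], [0.0, 0.0, 1.0]])

    @property
    def fov_um(self) -> float:
        return self.du * self.pixel_n / self.m


@dataclass(frozen=True)
class ExtrinsicPose:
    """Extrinsic parameters: rotation rows r11..r23 and translation (um).

    The 3x3 plane-to-plane matrix used in the homography is

        [[r11, r12, tx],
         [r21, r22, ty],
         [0,   0,   1 ]]

    with r13, r23 completing the two rotation rows to unit length (they
    encode the out-of-plane tilt and drop out of the planar mapping).
    """

    r11: float
    r12: float
    r13: float
    r21: float
    r22: float
    r23: float
    tx: float
    ty: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.r11, self.r12, self.tx],
                [self.r21, self.r22, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    @classmethod
    def identity(cls) -> "ExtrinsicPose":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_rotation(cls, rotation: np.ndarray, tx: float = 0.0, ty: float = 0.0) -> "ExtrinsicPose":
        """Top two rows of a 3x3 rotation matrix plus translation."""
        r = np.asarray(rotation, dtype=float)
        return cls(r[0, 0], r[0, 1], r[0, 2], r[1, 0], r[1, 1], r[1, 2], tx, ty)

    def parallelism_deviation(self) -> float:
        """How far (r11..r23) is from the top rows of an in-plane rotation.

        Zero when the sensor is parallel to the board (r13 = r23 = 0 and
        the 2x2 block is a pure rotation).
        """
        block = np.array([[self.r11, self.r12], [self.r21, self.r22]])
        sv = np.linalg.svd(block, compute_uv=False)
        return float(abs(self.r13) + abs(self.r23) + abs(sv[0] - 1) + abs(sv[1] - 1))

    def tilt_deg(self) -> float:
        """Out-of-plane tilt implied by the 2x2 block's smaller stretch."""
        block = np.array([[self.r11, self.r12], [self.r21, self.r22]])
        sv = np.linalg.svd(block, compute_uv=False)
        return float(np.degrees(np.arccos(np.clip(sv[1], -1.0, 1.0))))


@dataclass(frozen=True)
class Homography:
    """Plane-to-pixel projective map, H = A @ B.

    ``estimated=True`` marks an H-hat built from commanded stage angles
    rather than measured correspondences.
    """

    H: np.ndarray
    estimated: bool = False

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float).reshape(3, 3)
        object.__setattr__(self, "H", H)
        if abs(np.linalg.det(H)) <= 1e-12:
            raise ValueError("homography is singular")

    def apply(self, xy_um: np.ndarray) -> np.ndarray:
        """Map board-plane points (um) to pixel displacements from centre."""
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        h = np.hstack([xy, np.ones((len(xy), 1))]) @ self.H.T
        return h[:, :2] / h[:, 2:3]

    def inverse_apply(self, px: np.ndarray) -> np.ndarray:
        px = np.atleast_2d(np.asarray(px, dtype=float))
        hinv = np.linalg.inv(self.H)
        h = np.hstack([px, np.ones((len(px), 1))]) @ hinv.T
        return h[:, :2] / h[:, 2:3]


@dataclass(frozen=True)
class ChessboardModel:
    """The calibration chessboard: 4 mm squares, centre dot at the origin.

    Thirteen 0.1 mm dots serve the microscope calibration: the central dot
    O plus 12 auxiliary dots placed symmetrically about O — the four edge
    midpoint positions and four corners of the central square ring, and
    four dots one further square out along the axes.
    """

    square_size_mm: float = 4.0
    dot_diameter_mm: float = 0.1

    def dot_coordinates_mm(self) -> np.ndarray:
        """(13, 2) dot positions in mm, centre dot first, symmetric about O."""
        s = self.square_size_mm
        dots = [(0.0, 0.0)]
        dots += [(s, 0.0), (-s, 0.0), (0.0, s), (0.0, -s)]  # edge ring
        dots += [(s, s), (-s, s), (-s, -s), (s, -s)]  # corner ring
        dots += [(2 * s, 0.0), (-2 * s, 0.0), (0.0, 2 * s), (0.0, -2 * s)]
        return np.array(dots, dtype=float)


def intrinsic_matrix(m: float, du: float, pixel_n: int = 5120) -> CameraIntrinsics:
    """Build the intrinsic matrix A = diag(m/du, m/du, 1) (pixels per um)."""
    return CameraIntrinsics(m=m, du=du, pixel_n=pixel_n)


def compose_homography(a: CameraIntrinsics, b: ExtrinsicPose, estimated: bool = False) -> Homography:
    """H = A @ B; raises if the product is singular."""
    return Homography(a.matrix @ b.matrix, estimated=estimated)


def _check_correspondences(image_px: np.ndarray, board_um: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    image_px = np.asarray(image_px, dtype=float).reshape(-1, 2)
    board_um = np.asarray(board_um, dtype=float).reshape(-1, 2)
    if len(image_px) != len(board_um):
        raise ValueError("correspondence lists differ in length")
    if len(image_px) < min_n:
        raise ValueError(f"need at least {min_n} correspondences")
    centred = board_um - board_um.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-300):
        raise ValueError("degenerate (collinear or coincident) correspondences")
    return image_px, board_um


def estimate_magnification(
    image_dots_px: np.ndarray,
    board_dots_mm: np.ndarray,
    du: float = 4.5,
    max_iter: int = 50,
) -> tuple[float, float]:
    """Effective magnification by bundle adjustment over dot correspondences.

    Jointly fits (m, in-plane rotation, tx, ty) minimising pixel
    reprojection error: a closed-form similarity (Procrustes) fit provides
    the initialisation and a Gauss-Newton refinement polishes it.  Image
    dots are pixel displacements from the FOV centre; board dots are mm.

    Returns
    -------
    (m, rms) : the magnification estimate and the residual RMS in pixels.
    """
    image_px, board_um = _check_correspondences(
        image_dots_px, np.asarray(board_dots_mm, dtype=float) * 1000.0, min_n=3
    )
    # Procrustes similarity: image ~ s * R(theta) @ board + t
    mu_i = image_px.mean(axis=0)
    mu_b = board_um.mean(axis=0)
    ic = image_px - mu_i
    bc = board_um - mu_b
    cov = ic.T @ bc  # 2x2
    u, sv, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, d]) @ vt
    scale = (sv * np.array([1.0, d])).sum() / (bc**2).sum()
    theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    t = mu_i - scale * (rot @ mu_b)
    params = np.array([scale, theta, t[0], t[1]])

    def residuals(p: np.ndarray) -> np.ndarray:
        s, th, tx, ty = p
        c, sn = np.cos(th), np.sin(th)
        r = np.array([[c, -sn], [sn, c]])
        pred = s * (board_um @ r.T) + np.array([tx, ty])
        return (pred - image_px).ravel()

    for _ in range(max_iter):
        r0 = residuals(params)
        jac = np.empty((len(r0), 4))
        h = 1e-7 * np.maximum(np.abs(params), 1.0)
        for j in range(4):
            dp = np.zeros(4)
            dp[j] = h[j]
            jac[:, j] = (residuals(params + dp) - r0) / h[j]
        step, *_ = np.linalg.lstsq(jac, -r0, rcond=None)
        params = params + step
        if np.linalg.norm(step) < 1e-14 * max(1.0, np.linalg.norm(params)):
            break

    rms = float(np.sqrt(np.mean(residuals(params) ** 2)))
    m = float(params[0] * du)  # scale is px/um; m = scale * du
    return m, rms


def estimate_extrinsic(
    a: CameraIntrinsics,
    image_dots_px: np.ndarray,
    board_dots_mm: np.ndarray,
) -> tuple[ExtrinsicPose, float]:
    """Fit the extrinsic pose B minimising pixel reprojection RMS.

    Solves the linear least-squares problem for (r11, r12, tx, r21, r22,
    ty) in ``px = A @ [[r11,r12,tx],[r21,r22,ty],[0,0,1]] @ (X, Y, 1)``,
    then completes r13, r23 so each rotation row has unit norm (sign taken
    non-negative).  The pose's ``parallelism_deviation`` measures how far
    the sensor is from parallel to the board.

    Returns
    -------
    (pose, rms) : the fitted pose and residual RMS in pixels.
    """
    image_px, board_um = _check_correspondences(
        image_dots_px, np.asarray(board_dots_mm, dtype=float) * 1000.0, min_n=4
    )
    s = a.m / a.du  # px per um
    # one linear system per pixel axis
    design = np.hstack([board_um, np.ones((len(board_um), 1))])
    coef_x, *_ = np.linalg.lstsq(design, image_px[:, 0] / s, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, image_px[:, 1] / s, rcond=None)
    r11, r12, tx = coef_x
    r21, r22, ty = coef_y
    r13 = float(np.sqrt(max(0.0, 1.0 - r11**2 - r12**2)))
    r23 = float(np.sqrt(max(0.0, 1.0 - r21**2 - r22**2)))
    pose = ExtrinsicPose(r11, r12, r13, r21, r22, r23, float(tx), float(ty))
    pred = s * (design @ np.vstack([coef_x, coef_y]).T)
    rms = float(np.sqrt(np.mean((pred - image_px) ** 2)))
    return pose, rms


def rotation_offset(
    o_pixel: tuple[float, float],
    h_hat: Homography,
    pixel_n: int = 5120,
) -> tuple[float, float]:
    """Positional correction (um) from the chessboard centre's pixel drift.

    Implements ``(offset_x, offset_y, 1)^T = H_hat^-1 @ (O_x - N/2,
    O_y - N/2, 1)^T`` with the third homogeneous component renormalised
    to 1.  A perfectly centred dot yields (0, 0).
    """
    ox, oy = o_pixel
    v = np.array([ox - pixel_n / 2.0, oy - pixel_n / 2.0, 1.0])
    out = np.linalg.inv(h_hat.H) @ v
    if abs(out[2]) < 1e-300:
        raise ValueError("degenerate homography mapping (zero homogeneous component)")
    return float(out[0] / out[2]), float(out[1] / out[2])


def interpolate_offsets(
    step_angles_deg: np.ndarray,
    offsets_um: np.ndarray,
    query_deg: float,
) -> tuple[float, float]:
    """Piecewise-linear positional correction between calibrated steps.

    Refuses to extrapolate: the query must lie inside the calibrated
    angle range.
    """
    angles = np.asarray(step_angles_deg, dtype=float)
    offsets = np.asarray(offsets_um, dtype=float).reshape(len(angles), 2)
    if len(angles) < 2 or not np.all(np.diff(angles) > 0):
        raise ValueError("step angles must be strictly increasing (>= 2 knots)")
    if query_deg < angles[0] or query_deg > angles[-1]:
        raise ValueError(
            f"query {query_deg} deg outside calibrated range [{angles[0]}, {angles[-1]}]"
        )
    ox = float(np.interp(query_deg, angles, offsets[:, 0]))
    oy = float(np.interp(query_deg, angles, offsets[:, 1]))
    return ox, oy


def fit_circle(points_um: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic (Kasa) least-squares circle fit.

    Used to locate the true R_z rotation axis: the tracked chessboard
    centre traces a circle whose centre is the actual axis and whose
    radius is the alignment offset.

    Returns
    -------
    (center, radius, rms) : centre (um), radius (um) and radial residual RMS.
    """
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-300):
        raise ValueError("collinear points cannot define a circle")
    # Kasa: minimise ||x^2+y^2 - 2ax - 2by - c||
    x, y = pts[:, 0], pts[:, 1]
    design = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    rhs = x**2 + y**2
    (a, b, c), *_ = np.linalg.lstsq(design, rhs, rcond=None)
    center = np.array([a, b])
    radius = float(np.sqrt(max(0.0, c + a**2 + b**2)))
    resid = np.hypot(x - a, y - b) - radius
    return center, radius, float(np.sqrt(np.mean(resid**2)))


def fit_axis_skew(points_mm: np.ndarray, axis: str = "x") -> float:
    """Signed skew angle (degrees) between a fitted line and a named axis.

    Total-least-squares line through chessboard square vertices recorded
    while scanning a linear stage; a nonzero angle reveals stage
    misalignment.  ``axis`` is ``"x"`` or ``"y"``; positive angles rotate
    counter-clockwise from the axis toward the line.
    """
    pts = np.asarray(points_mm, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    centred = pts - pts.mean(axis=0)
    if np.allclose(centred, 0.0, atol=1e-15):
        raise ValueError("identical points cannot define a line")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if axis == "x":
        ref = np.array([1.0, 0.0])
    elif axis == "y":
        ref = np.array([0.0, 1.0])
    else:
        raise ValueError("axis must be 'x' or 'y'")
    if np.dot(direction, ref) < 0:
        direction = -direction
    cross = ref[0] * direction[1] - ref[1] * direction[0]
    angle = np.degrees(np.arctan2(cross, np.dot(ref, direction)))
    return float(angle)
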