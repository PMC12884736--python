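"""Scan-trajectory planning over a triangulated tissue surface.

The microscope images the surface one field of view (FOV) at a time.  The
planner decomposes the mesh into FOV-sized *grids* by breadth-first
propagation from the surface centroid: at each grid centre the local
tangent plane defines four step directions (the +-x and +-y axes projected
onto the plane) along which neighbouring grid centres are placed at
``overlap_factor * l`` so adjacent fields overlap by roughly 20%.  Each
grid then receives a microscope pose — Z-X-Y Euler angles whose rotation
matrix has the grid's average normal as its third column — and an
elevation schedule stepping through the grid's height range at the
objective's depth of field.  Finally the grids are ordered into a scan
path that keeps rotation-stage motion small, and the sample-rotation stage
(R_z) can be used to confine scanning to a single x-y quadrant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import SurfaceMesh, SurfacePoint, local_normal, mesh_centroid

__all__ = [
    "ObjectiveSpec",
    "ScanGrid",
    "MicroscopePose",
    "Trajectory",
    "OBJECTIVE_PRESETS",
    "euler_zxy_matrix",
    "plan_grids",
    "grid_pose",
    "elevation_schedule",
    "order_path",
    "confine_quadrant",
]

#: Hard tilt limit of the rotation stages, degrees from the vertical axis.
MAX_TILT_DEG = 83.3


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective-lens parameters relevant to planning.

    ``dof`` is the depth of field in mm (sets the elevation step);
    ``working_distance`` is the lens-to-sample distance in mm.
    """

    magnification: float
    dof: float
    working_distance: float

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError("magnification must be > 0")
        if self.dof <= 0:
            raise ValueError("dof must be > 0")


#: Long-working-distance plan-apochromat presets used throughout.
OBJECTIVE_PRESETS = {
    "5x": ObjectiveSpec(magnification=5.0, dof=0.05, working_distance=34.0),
    "10x": ObjectiveSpec(magnification=10.0, dof=0.025, working_distance=34.0),
    "20x": ObjectiveSpec(magnification=20.0, dof=0.012, working_distance=20.0),
}


@dataclass
class ScanGrid:
    """One FOV-sized surface patch with its centre, normal and members."""

    id: int
    center: SurfacePoint
    avg_normal: np.ndarray
    grid_length: float
    member_vertices: np.ndarray
    z_lo: float  # elevation extremes of members along avg_normal, mm (unpadded)
    z_hi: float

    def __post_init__(self) -> None:
        if self.grid_length <= 0:
            raise ValueError("grid_length must be > 0")
        if self.z_hi < self.z_lo:
            raise ValueError("z_hi must be >= z_lo")
        self.avg_normal = np.asarray(self.avg_normal, dtype=float)
        self.avg_normal = self.avg_normal / np.linalg.norm(self.avg_normal)


@dataclass
class MicroscopePose:
    """Stage coordinates: linear x, y, z in mm; rx, ry, rz in degrees.

    Angles follow the Z-X-Y Euler convention: the composed rotation is
    ``Rz(rz) @ Rx(rx) @ Ry(ry)`` and its third column is the optical-axis
    direction.
    """

    x: float
    y: float
    z: float
    rx: float
    ry: float
    rz: float = 0.0

    def rotation_matrix(self) -> np.ndarray:
        return euler_zxy_matrix(self.rx, self.ry, self.rz)

    def optical_axis(self) -> np.ndarray:
        return self.rotation_matrix()[:, 2]

    def tilt_deg(self) -> float:
        """Angle between the optical axis and vertical, degrees."""
        nz = float(np.clip(self.rotation_matrix()[2, 2], -1.0, 1.0))
        return float(np.degrees(np.arccos(nz)))


@dataclass
class Trajectory:
    """Ordered scan plan: (grid id, pose, elevation schedule) per stop."""

    entries: list[tuple[int, MicroscopePose, list[float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [gid for gid, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("every grid must appear exactly once")
        for _, _, elevs in self.entries:
            if len(elevs) > 1 and not np.all(np.diff(elevs) > 0):
                raise ValueError("elevation lists must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [
            {
                "grid_id": int(gid),
                "pose_mm_deg": {
                    "x": p.x, "y": p.y, "z": p.z,
                    "rx": p.rx, "ry": p.ry, "rz": p.rz,
                },
                "elevations_mm": [float(e) for e in elevs],
            }
            for gid, p, elevs in self.entries
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "Trajectory":
        payload = json.loads(Path(path).read_text())
        entries = [
            (
                int(e["grid_id"]),
                MicroscopePose(**e["pose_mm_deg"]),
                [float(x) for x in e["elevations_mm"]],
            )
            for e in payload
        ]
        return cls(entries)


def euler_zxy_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """Rotation matrix ``Rz(rz) @ Rx(rx) @ Ry(ry)`` (Z-X-Y convention)."""
    ax, ay, az = np.radians([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ rx @ ry


def _tangent_directions(normal: np.ndarray) -> list[np.ndarray]:
    """Four unit step directions: +-x, +-y projected onto the tangent plane.

    When the normal is (anti)parallel to a reference axis the two
    degenerate directions are replaced by a deterministic orthonormal
    tangent pair derived from the normal's smallest component.
    """
    dirs: list[np.ndarray] = []
    refs = [np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]),
            np.array([0, 1.0, 0]), np.array([0, -1.0, 0])]
    degenerate = False
    for r in refs:
        t = r - np.dot(r, normal) * normal
        nt = np.linalg.norm(t)
        if nt < 1e-9:
            degenerate = True
            continue
        dirs.append(t / nt)
    if degenerate or len(dirs) < 4:
        # orthonormal tangent pair from the axis least aligned with n
        e = np.zeros(3)
        e[int(np.argmin(np.abs(normal)))] = 1.0
        t1 = np.cross(normal, e)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(normal, t1)
        dirs = [t1, -t1, t2, -t2]
    return dirs


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane axes (t1, t2) for the grid footprint square."""
    dirs = _tangent_directions(normal)
    t1 = dirs[0]
    t2 = np.cross(normal, t1)
    t2 /= np.linalg.norm(t2)
    return t1, t2


def _grid_members(
    vertices: np.ndarray, center: np.ndarray, normal: np.ndarray, l: float
) -> np.ndarray:
    t1, t2 = _tangent_frame(normal)
    d = vertices - center
    u = d @ t1
    v = d @ t2
    half = l / 2.0
    return np.nonzero((np.abs(u) <= half) & (np.abs(v) <= half))[0]


def plan_grids(
    mesh: SurfaceMesh,
    fov_length: float,
    overlap_factor: float = 0.8,
    k_normal: int = 12,
) -> list[ScanGrid]:
    """Decompose a mesh into FOV-sized scan grids by surface propagation.

    Starting from the area-weighted surface centroid, candidate neighbour
    centres are placed at ``overlap_factor * fov_length`` along the four
    tangent step directions, snapped back onto the surface when they fall
    off it, merged when they come within ``0.5 * overlap_factor *
    fov_length`` of an existing centre, and discarded when they add no new
    member vertices (the mesh-boundary termination).  A final repair pass
    seeds extra grids at any vertex left unassigned, so every mesh vertex
    belongs to at least one grid.  The centroid grid is always first.

    The procedure is deterministic: candidates are expanded breadth-first
    in creation order and the repair pass walks vertices in index order.
    """
    if fov_length <= 0:
        raise ValueError("fov_length must be > 0")
    if not (0 < overlap_factor <= 1):
        raise ValueError("overlap_factor must be in (0, 1]")
    l = float(fov_length)
    step = overlap_factor * l
    merge_radius = 0.5 * overlap_factor * l
    tm = mesh.as_trimesh()
    k = min(k_normal, mesh.n_vertices)

    seed = mesh_centroid(mesh)
    centers = [seed.position]
    covered = np.zeros(mesh.n_vertices, dtype=bool)
    member_lists: list[np.ndarray] = []
    normals_at_center: list[np.ndarray] = []

    def register(center: np.ndarray) -> None:
        n = local_normal(mesh, center, k=k) if mesh.n_vertices >= 3 else seed.normal
        members = _grid_members(mesh.vertices, center, n, l)
        member_lists.append(members)
        normals_at_center.append(n)
        covered[members] = True

    register(centers[0])
    head = 0
    while head < len(centers):
        center = centers[head]
        n = normals_at_center[head]
        head += 1
        for t in _tangent_directions(n):
            cand = center + step * t
            closest, dist = mesh.nearest(cand[None, :])
            if dist[0] > 1e-9:  # off-surface candidate: snap
                cand = closest[0]
            existing = np.asarray(centers)
            if np.min(np.linalg.norm(existing - cand, axis=1)) < merge_radius:
                continue
            cn = local_normal(mesh, cand, k=k)
            members = _grid_members(mesh.vertices, cand, cn, l)
            if len(members) == 0 or np.all(covered[members]):
                continue  # boundary reached: nothing new to image
            centers.append(cand)
            member_lists.append(members)
            normals_at_center.append(cn)
            covered[members] = True

    # repair: any vertex not in a grid seeds one at its own position
    for vid in np.nonzero(~covered)[0]:
        if covered[vid]:
            continue
        cand = mesh.vertices[vid]
        cn = local_normal(mesh, cand, k=k)
        members = _grid_members(mesh.vertices, cand, cn, l)
        centers.append(cand)
        member_lists.append(members)
        normals_at_center.append(cn)
        covered[members] = True
        covered[vid] = True

    grids: list[ScanGrid] = []
    for gid, (center, members) in enumerate(zip(centers, member_lists)):
        if len(members) == 0:
            members = np.array([int(cKDTree(mesh.vertices).query(center)[1])])
        avg_n = mesh.vertex_normals[members].mean(axis=0)
        nn = np.linalg.norm(avg_n)
        avg_n = avg_n / nn if nn > 0 else normals_at_center[gid]
        elev = mesh.vertices[members] @ avg_n
        center_sp = SurfacePoint(position=center, normal=avg_n)
        grids.append(
            ScanGrid(
                id=gid,
                center=center_sp,
                avg_normal=avg_n,
                grid_length=l,
                member_vertices=members,
                z_lo=float(elev.min()),
                z_hi=float(elev.max()),
            )
        )
    return grids


def grid_pose(grid: ScanGrid, objective: ObjectiveSpec) -> MicroscopePose:
    """Microscope pose viewing a grid along its average normal.

    Solves the Z-X-Y Euler angles (with rz = 0) whose rotation matrix has
    ``grid.avg_normal`` as its third column:

    ``rx = atan2(-ny, nz)``, ``ry = atan2(nx, hypot(ny, nz))``.

    The linear stages place the lens at ``center + working_distance *
    avg_normal`` so the optical axis passes through the grid centre.

    Raises
    ------
    ValueError
        If the required tilt from vertical exceeds the stage limit of
        83.3 degrees (unreachable orientation).
    """
    n = grid.avg_normal
    tilt = np.degrees(np.arccos(np.clip(n[2], -1.0, 1.0)))
    if tilt > MAX_TILT_DEG:
        raise ValueError(
            f"required tilt {tilt:.2f} deg exceeds the {MAX_TILT_DEG} deg stage limit"
        )
    rx = np.degrees(np.arctan2(-n[1], n[2]))
    ry = np.degrees(np.arctan2(n[0], np.hypot(n[1], n[2])))
    pos = grid.center.position + objective.working_distance * n
    return MicroscopePose(
        x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
        rx=float(rx), ry=float(ry), rz=0.0,
    )


def elevation_schedule(
    grid: ScanGrid,
    objective: ObjectiveSpec,
    pad: float = 0.2,
    min_frames: int = 10,
    max_frames: int = 30,
) -> list[float]:
    """Evenly spaced focus elevations covering the grid's height range.

    The span runs from ``pad`` mm below the lowest member vertex to ``pad``
    mm above the highest (along the grid normal), absorbing scanner
    measurement error.  The step never exceeds the objective's depth of
    field, and the frame count is clamped to [min_frames, max_frames] with
    linear re-spacing when the clamp binds.
    """
    lo = grid.z_lo - pad
    hi = grid.z_hi + pad
    span = hi - lo
    n = int(np.ceil(span / objective.dof)) + 1 if span > 0 else min_frames
    n = int(np.clip(n, min_frames, max_frames))
    return [float(e) for e in np.linspace(lo, hi, n)]


def _pose_cost(a: MicroscopePose, b: MicroscopePose, eps: float = 0.01) -> float:
    rot = abs(a.rx - b.rx) + abs(a.ry - b.ry)
    lin = float(np.linalg.norm([a.x - b.x, a.y - b.y, a.z - b.z]))
    return rot + eps * lin


def path_cost(order: list[int], poses: list[MicroscopePose]) -> float:
    """Total stage-motion cost of visiting poses in the given order."""
    return sum(
        _pose_cost(poses[order[i]], poses[order[i + 1]]) for i in range(len(order) - 1)
    )


def order_path(
    grids: list[ScanGrid],
    poses: list[MicroscopePose],
    elevations: list[list[float]] | None = None,
) -> Trajectory:
    """Order grids into a scan path that keeps rotation-stage motion small.

    A greedy nearest-neighbour tour starts at the first (centroid) grid
    under cost ``|drx| + |dry| + 0.01 deg/mm * |dxyz|``; if the input order
    happens to be cheaper than the greedy tour, the input order is kept, so
    the returned path never costs more than the order given.
    """
    if len(grids) != len(poses):
        raise ValueError("grids and poses length mismatch")
    if len(grids) == 0:
        raise ValueError("no grids to order")
    if elevations is not None and len(elevations) != len(grids):
        raise ValueError("elevations length mismatch")

    n = len(grids)
    remaining = set(range(1, n))
    order = [0]
    while remaining:
        cur = order[-1]
        nxt = min(remaining, key=lambda j: (_pose_cost(poses[cur], poses[j]), j))
        order.append(nxt)
        remaining.remove(nxt)

    input_order = list(range(n))
    if path_cost(input_order, poses) < path_cost(order, poses):
        order = input_order

    entries = []
    for idx in order:
        elevs = elevations[idx] if elevations is not None else []
        entries.append((grids[idx].id, poses[idx], list(elevs)))
    return Trajectory(entries)


def confine_quadrant(pose: MicroscopePose) -> MicroscopePose:
    """Set rz (sample rotation) so the target lies in quadrant I.

    rz is restricted to multiples of 90 degrees; rotating the sample frame
    by ``-rz`` maps the pose's (x, y) target into x >= 0, y >= 0.  Points
    on the axes (including the origin) already satisfy quadrant I whenever
    possible, preferring the smallest rotation.
    """
    x, y = pose.x, pose.y
    for rz in (0.0, 90.0, 180.0, 270.0):
        a = np.radians(-rz)
        xr = np.cos(a) * x - np.sin(a) * y
        yr = np.sin(a) * x + np.cos(a) * y
        if xr >= -1e-12 and yr >= -1e-12:
            return MicroscopePose(pose.x, pose.y, pose.z, pose.rx, pose.ry, rz)
    return MicroscopePose(pose.x, pose.y, pose.z, pose.rx, pose.ry, 0.0)
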