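"""Surface-mesh handling for scan planning.

The scanning pipeline starts from a triangulated surface mesh of an excised
tissue sample, expressed in the instrument frame: millimetres, right-handed,
origin at the calibration-chessboard centre, z up.  This module covers mesh
ingestion and validation, cleaning (isolated-vertex removal and Laplacian
smoothing), the area-weighted surface centroid used as the scan seed point,
local least-squares normal estimation, and reconstruction of a triangulated
surface from an oriented point set.

Meshes are held in a light :class:`SurfaceMesh` container; file I/O and
proximity queries delegate to :mod:`trimesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "SurfaceMesh",
    "SurfacePoint",
    "load_mesh",
    "clean_mesh",
    "mesh_centroid",
    "local_normal",
    "reconstruct_surface",
]


@dataclass
class SurfacePoint:
    """A point constrained to a surface, with its outward unit normal."""

    position: np.ndarray  # (3,) mm
    normal: np.ndarray  # (3,) unit vector

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("surface point normal must be non-zero")
        self.normal = self.normal / n


@dataclass
class SurfaceMesh:
    """Oriented triangulated surface in instrument coordinates (mm).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    facets : (m, 3) int array
        Vertex-index triples.
    vertex_normals : (n, 3) float array, optional
        Outward unit normals.  When absent they are computed as
        area-weighted averages of incident facet normals.
    """

    vertices: np.ndarray
    facets: np.ndarray
    vertex_normals: np.ndarray | None = None
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.facets = np.asarray(self.facets, dtype=np.int64).reshape(-1, 3)
        if self.facets.shape[0] < 1:
            raise ValueError("mesh must have at least one facet")
        if self.facets.min() < 0 or self.facets.max() >= len(self.vertices):
            raise ValueError("facet references an invalid vertex index")
        if self.vertex_normals is None:
            self.vertex_normals = _area_weighted_vertex_normals(
                self.vertices, self.facets
            )
        else:
            vn = np.asarray(self.vertex_normals, dtype=float).reshape(-1, 3)
            norms = np.linalg.norm(vn, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self.vertex_normals = vn / norms

    # -- convenience -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.facets, process=False
            )
        return self._tm

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closest points on the surface and their distances (mm).

        Candidate facets come from a K-D tree over facet centroids; the
        exact point-to-triangle projection picks the winner.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        triangles = self.vertices[self.facets]
        centroids = triangles.mean(axis=1)
        k = min(32, len(centroids))
        _, cand = cKDTree(centroids).query(points, k=k)
        cand = np.atleast_2d(cand)
        closest = np.empty_like(points)
        dist = np.empty(len(points))
        for i, (p, ids) in enumerate(zip(points, cand)):
            ids = np.atleast_1d(ids)
            on_tri = trimesh.triangles.closest_point(
                triangles[ids], np.tile(p, (len(ids), 1))
            )
            d = np.linalg.norm(on_tri - p, axis=1)
            j = int(np.argmin(d))
            closest[i] = on_tri[j]
            dist[i] = d[j]
        return closest, dist

    def facet_areas(self) -> np.ndarray:
        tri = self.vertices[self.facets]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def save(self, path: str | Path) -> None:
        self.as_trimesh().export(str(path))

    def validation_report(self) -> dict:
        """JSON-serialisable summary used by the CLI."""
        areas = self.facet_areas()
        return {
            "n_vertices": int(self.n_vertices),
            "n_facets": int(self.n_facets),
            "bbox_mm": [self.vertices.min(axis=0).tolist(), self.vertices.max(axis=0).tolist()],
            "total_area_mm2": float(areas.sum()),
            "degenerate_facets": int(np.sum(areas <= 1e-12)),
            "normals_unit": bool(
                np.allclose(np.linalg.norm(self.vertex_normals, axis=1), 1.0, atol=1e-9)
            ),
        }


def _area_weighted_vertex_normals(vertices: np.ndarray, facets: np.ndarray) -> np.ndarray:
    tri = vertices[facets]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area*nhat
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, facets[:, k], cross)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return normals / norms


def load_mesh(path: str | Path) -> SurfaceMesh:
    """Load a PLY, OBJ, or STL surface mesh.

    Vertex normals absent from the file are computed as area-weighted
    averages of incident facet normals.

    Raises
    ------
    ValueError
        If the file cannot be read or contains no facets.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"mesh file does not exist: {path}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ValueError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"mesh file {path} contains no facets")
    normals = None
    # file-provided normals win; trimesh synthesises them otherwise
    if "vertex_normals" in tm._cache.cache or tm.vertex_normals is not None:
        normals = np.asarray(tm.vertex_normals, dtype=float)
        if normals.shape != (len(tm.vertices), 3) or not np.all(np.isfinite(normals)):
            normals = None
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), normals)


def clean_mesh(
    mesh: SurfaceMesh,
    smoothing_iters: int = 10,
    isolation_radius: float = 2.0,
) -> SurfaceMesh:
    """Remove isolated vertices and apply uniform Laplacian smoothing.

    A vertex is isolated when no other vertex lies within
    ``isolation_radius`` (mm); such vertices — and any facets referencing
    them — are dropped.  Smoothing moves each remaining vertex half-way
    (step 0.5) toward the mean of its edge-connected neighbours,
    ``smoothing_iters`` times.  The operation is idempotent at fixed
    parameters once the vertex set is stable.

    Raises
    ------
    ValueError
        If ``smoothing_iters`` is negative or cleaning removes every vertex.
    """
    if smoothing_iters < 0:
        raise ValueError("smoothing_iters must be >= 0")

    vertices = mesh.vertices.copy()
    facets = mesh.facets.copy()

    # isolated-vertex removal
    if len(vertices) > 1:
        tree = cKDTree(vertices)
        dist, _ = tree.query(vertices, k=2)
        keep = dist[:, 1] <= isolation_radius
    else:
        keep = np.ones(len(vertices), dtype=bool)
    if not np.any(keep):
        raise ValueError("cleaning removed all vertices")
    if not np.all(keep):
        remap = -np.ones(len(vertices), dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        vertices = vertices[keep]
        facets = remap[facets]
        facets = facets[(facets >= 0).all(axis=1)]
        if len(facets) == 0:
            raise ValueError("cleaning removed all facets")

    if smoothing_iters > 0:
        neighbors = _vertex_adjacency(len(vertices), facets)
        vertices = _laplacian_smooth(vertices, neighbors, smoothing_iters, lam=0.5)

    return SurfaceMesh(vertices, facets)


def _vertex_adjacency(n: int, facets: np.ndarray) -> list[np.ndarray]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in facets:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return [np.fromiter(s, dtype=np.int64) for s in adj]


def _laplacian_smooth(
    vertices: np.ndarray, neighbors: list[np.ndarray], iters: int, lam: float
) -> np.ndarray:
    v = vertices.copy()
    for _ in range(iters):
        mean = v.copy()
        for i, nb in enumerate(neighbors):
            if len(nb):
                mean[i] = v[nb].mean(axis=0)
        v = v + lam * (mean - v)
    return v


def mesh_centroid(mesh: SurfaceMesh) -> SurfacePoint:
    """Area-weighted surface centroid, snapped to the nearest surface point.

    The raw area-weighted average of facet centroids can lie off the
    surface for curved meshes; when it does, it is snapped to the nearest
    mesh vertex (vertex snapping keeps the seed on symmetry axes of
    symmetric tessellations, where projection onto tied facets would
    not).  An on-surface raw centroid is kept exactly.
    """
    areas = mesh.facet_areas()
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    facet_centroids = mesh.vertices[mesh.facets].mean(axis=1)
    raw = (facet_centroids * areas[:, None]).sum(axis=0) / total
    _, dist = mesh.nearest(raw)
    tree = cKDTree(mesh.vertices)
    _, idx = tree.query(raw)
    if dist[0] <= 1e-9:
        return SurfacePoint(position=raw, normal=mesh.vertex_normals[idx])
    return SurfacePoint(
        position=mesh.vertices[idx], normal=mesh.vertex_normals[idx]
    )


def local_normal(mesh: SurfaceMesh, point: np.ndarray, k: int = 12) -> np.ndarray:
    """Least-squares plane normal of the ``k`` mesh vertices nearest ``point``.

    The neighbourhood is found with a K-D tree; the plane is the
    total-least-squares fit (smallest principal component of the centred
    neighbourhood).  The normal is oriented to agree with the mean vertex
    normal of the neighbourhood (positive dot product).

    Raises
    ------
    ValueError
        If ``k < 3``, the mesh has fewer than ``k`` vertices, or the
        neighbourhood is degenerate (collinear).
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if mesh.n_vertices < k:
        raise ValueError(f"mesh has {mesh.n_vertices} vertices; need >= {k}")
    point = np.asarray(point, dtype=float).reshape(3)
    tree = cKDTree(mesh.vertices)
    _, idx = tree.query(point, k=k)
    nb = mesh.vertices[idx]
    centred = nb - nb.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) neighborhood")
    n = vt[2]
    reference = mesh.vertex_normals[idx].mean(axis=0)
    if np.dot(n, reference) < 0:
        n = -n
    return n / np.linalg.norm(n)


def reconstruct_surface(
    points: np.ndarray,
    normals: np.ndarray,
    tolerance: float = 0.1,
    grid_resolution: int = 64,
) -> SurfaceMesh:
    """Triangulate an oriented point set into a surface mesh.

    Non-planar sets are fit with a smooth implicit signed field
    (radial-basis interpolation of on-/off-surface constraints built from
    the oriented points) whose zero level set is extracted by marching
    cubes — a screened-Poisson-style implicit reconstruction.  Planar sets
    fall back to a 2D Delaunay triangulation in the plane.

    Parameters
    ----------
    points, normals : (n, 3) arrays
        Oriented sample points (mm) with unit normals.
    tolerance : float
        Maximum allowed point-to-surface distance (mm); exceeding it raises.
    grid_resolution : int
        Marching-cubes grid size per axis.

    Raises
    ------
    ValueError
        If fewer than 4 points are given, all points coincide, or the
        reconstruction misses the tolerance.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    normals = np.asarray(normals, dtype=float).reshape(-1, 3)
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    if np.allclose(points, points[0], atol=1e-12):
        raise ValueError("all points identical")
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals = normals / norms

    centred = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    extent = s[0] / np.sqrt(len(points))
    if s[2] <= 1e-9 * max(s[0], 1e-300):  # planar set
        return _planar_triangulation(points, vt)

    mesh = _implicit_reconstruction(points, normals, grid_resolution, extent)
    _, dist = mesh.nearest(points)
    if dist.mean() > tolerance:
        raise ValueError(
            f"reconstruction error {dist.mean():.4f} mm exceeds tolerance {tolerance} mm"
        )
    return mesh


def _planar_triangulation(points: np.ndarray, vt: np.ndarray) -> SurfaceMesh:
    uv = (points - points.mean(axis=0)) @ vt[:2].T
    tri = Delaunay(uv)
    return SurfaceMesh(points, tri.simplices)


def _implicit_reconstruction(
    points: np.ndarray, normals: np.ndarray, grid_resolution: int, extent: float
) -> SurfaceMesh:
    from skimage.measure import marching_cubes

    # signed-field constraints: 0 on surface, +/-eps at normal offsets
    eps = 0.05 * extent
    sites = np.vstack([points, points + eps * normals, points - eps * normals])
    values = np.concatenate(
        [np.zeros(len(points)), np.full(len(points), eps), np.full(len(points), -eps)]
    )
    rbf = RBFInterpolator(sites, values, kernel="linear", smoothing=0.0)

    lo = points.min(axis=0) - 0.15 * extent
    hi = points.max(axis=0) + 0.15 * extent
    axes = [np.linspace(lo[d], hi[d], grid_resolution) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # chunked evaluation keeps peak memory modest
    fields = []
    for chunk in np.array_split(grid, max(1, len(grid) // 65536)):
        fields.append(rbf(chunk))
    fieldv = np.concatenate(fields).reshape((grid_resolution,) * 3)

    spacing = tuple((hi - lo) / (grid_resolution - 1))
    verts, faces, _, _ = marching_cubes(fieldv, level=0.0, spacing=spacing)
    verts = verts + lo
    return SurfaceMesh(verts, faces)
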