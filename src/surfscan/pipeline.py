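"""End-to-end demo pipeline: mesh -> trajectory -> stacks -> fusion ->
surface synthesis -> features -> margin classifier.

`run_pipeline` wires every stage of the package together on synthetic
inputs, writing one artifact per stage into the run directory:

1. ``mesh.ply`` — the (simulated) surface mesh,
2. ``trajectory.json`` — ordered scan plan with poses and elevations,
3. ``fused_tiles.tif`` — per-grid extended-depth-of-field tiles,
4. ``textured_surface.obj`` (+ ``.mtl`` / atlas PNG) — tiles mapped back
   onto the mesh,
5. ``features.csv`` — per-subimage margin features,
6. ``model.json`` — the fitted logistic margin model,
7. ``evaluation.json`` — ROC/AUC report on the held-out split.

Stage failures abort with a stage-tagged error; all randomness derives
from the config seed, so a repeated run reproduces the report exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import cad, fusion, synthesis, synthetic, trajectory as traj
from .calibration import CameraIntrinsics, ExtrinsicPose, compose_homography
from .geometry import SurfaceMesh
from .trajectory import OBJECTIVE_PRESETS, ObjectiveSpec

logger = logging.getLogger("surfscan")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    The objective presets reproduce the instrument's field-of-view
    arithmetic (du = 4.5 um, 5120-pixel sensor): 4.608 / 2.304 / 1.152 mm
    for 5x / 10x / 20x.  ``sim_tile_px`` scales the simulated tile
    resolution (full sensor frames are far larger than a desk-scale demo
    needs); the physical FOV is unchanged.
    """

    objective: str = "5x"
    du_um: float = 4.5
    pixel_n: int = 5120
    overlap_factor: float = 0.8
    pad_mm: float = 0.2
    tile_size: int = 128
    train_fraction: float = 0.6
    seed: int = 0
    surface_shape: str = "plane"
    surface_params: dict = field(default_factory=lambda: {"extent": 10.0, "spacing": 0.5})
    sim_tile_px: int = 256
    texture_pitch_um: float = 0.9
    mesh_path: str | None = None
    out_dir: str = "runs/demo"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def objective_spec(self) -> ObjectiveSpec:
        if self.objective not in OBJECTIVE_PRESETS:
            raise ValueError(f"unknown objective preset {self.objective!r}")
        return OBJECTIVE_PRESETS[self.objective]

    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(
            m=self.objective_spec().magnification, du=self.du_um, pixel_n=self.pixel_n
        )


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return result

        return run

    return wrap


@_stage("mesh")
def _load_or_make_mesh(config: RunConfig) -> SurfaceMesh:
    if config.mesh_path:
        from .geometry import load_mesh

        return load_mesh(config.mesh_path)
    return synthetic.make_surface(config.surface_shape, config.surface_params, config.seed)


@_stage("plan")
def _plan(config: RunConfig, mesh: SurfaceMesh):
    objective = config.objective_spec()
    intr = config.intrinsics()
    fov = fusion.compute_fov(objective, intr)
    grids = traj.plan_grids(mesh, fov, config.overlap_factor)
    poses = [traj.grid_pose(g, objective) for g in grids]
    elevs = [traj.elevation_schedule(g, objective, pad=config.pad_mm) for g in grids]
    plan = traj.order_path(grids, poses, elevs)
    return grids, poses, plan


@_stage("fuse")
def _acquire_and_fuse(config: RunConfig, grids, plan):
    """Simulate a focal stack per grid and fuse it to a sharp tile."""
    rng = np.random.default_rng(config.seed)
    tiles = {}
    labels = {}
    pitch_um = config.texture_pitch_um
    by_id = {g.id: g for g in grids}
    for gid, _pose, elevs in plan.entries:
        grid = by_id[gid]
        # tumor occupies the +x half of the surface
        positive = grid.center.position[0] > 0
        params = synthetic.POSITIVE_TISSUE if positive else synthetic.NEGATIVE_TISSUE
        extent_mm = config.sim_tile_px * pitch_um / 1000.0
        sharp, _ = synthetic.make_tissue_texture(
            params,
            extent_mm=extent_mm,
            pixel_pitch_um=pitch_um,
            seed=int(rng.integers(2**31)),
        )
        focus = 0.5 * (elevs[0] + elevs[-1]) if elevs else 0.0
        stack = synthetic.make_focal_stack(
            sharp,
            elevs or [0.0],
            synthetic.DefocusModel(focus_elevation=focus, blur_scale=10.0),
            grid_id=gid,
        )
        tile = fusion.fuse_stack(stack)
        tile.image = fusion.equalize_tile(tile.image.astype(np.uint16))
        tiles[gid] = tile
        labels[gid] = "positive" if positive else "negative"
    return tiles, labels


@_stage("synthesize")
def _synthesize(config: RunConfig, mesh: SurfaceMesh, pose_by_gid: dict, tiles):
    intr = config.intrinsics()
    # the simulated tiles are coarser than the real sensor; scale the
    # homography so the tile footprint still spans the physical FOV
    scale = config.sim_tile_px / config.pixel_n
    h_hat = compose_homography(
        CameraIntrinsics(m=intr.m / scale, du=intr.du, pixel_n=config.sim_tile_px),
        ExtrinsicPose.identity(),
        estimated=True,
    )
    candidates: list[list[int]] = [[] for _ in range(mesh.n_facets)]
    axes = {}
    texcoords: dict[int, dict[int, np.ndarray]] = {}
    for gid, pose in pose_by_gid.items():
        if gid not in tiles:
            continue
        axes[gid] = pose.optical_axis()
        mapping = synthesis.project_tile(tiles[gid], pose, h_hat, mesh)
        texcoords[gid] = mapping
        for fid in mapping:
            candidates[fid].append(gid)
    normals = np.cross(
        mesh.vertices[mesh.facets[:, 1]] - mesh.vertices[mesh.facets[:, 0]],
        mesh.vertices[mesh.facets[:, 2]] - mesh.vertices[mesh.facets[:, 0]],
    )
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals = normals / norms
    assignment = synthesis.select_views(normals, candidates, axes, mesh.facets, lam=0.5)
    textured = synthesis.TexturedSurface(
        mesh=mesh,
        facet_view=assignment,
        atlas={gid: t.image for gid, t in tiles.items()},
        texcoords={
            fid: texcoords[int(assignment[fid])][fid]
            for fid in range(mesh.n_facets)
            if assignment[fid] >= 0 and fid in texcoords.get(int(assignment[fid]), {})
        },
    )
    textured.compute_seams()
    return textured


@_stage("features")
def _features(config: RunConfig, tiles, labels):
    rows = []
    for gid, tile in tiles.items():
        for sub in cad.tile_image(tile.image, size=config.tile_size):
            mask, comps = cad.segment_nuclei(sub)
            fv = cad.extract_features(sub, mask, comps)
            if fv.excluded:
                continue
            sub.label = labels[gid]
            rows.append((gid, sub, fv))
    return rows


@_stage("train")
def _train(config: RunConfig, rows):
    subs = [s for _, s, _ in rows]
    feats = {id(s): fv for _, s, fv in rows}
    train, test = cad.split_dataset(subs, config.train_fraction, seed=config.seed)
    xtr = np.array([feats[id(s)].as_array() for s in train])
    ytr = np.array([1 if s.label == "positive" else 0 for s in train])
    xte = np.array([feats[id(s)].as_array() for s in test])
    yte = np.array([1 if s.label == "positive" else 0 for s in test])
    model = cad.train_margin_model(xtr, ytr)
    return model, (xtr, ytr), (xte, yte)


@_stage("evaluate")
def _evaluate(model, test):
    xte, yte = test
    return cad.evaluate(model, xte, yte)


def _export_obj(textured: synthesis.TexturedSurface, out_dir: Path) -> None:
    """Minimal OBJ + MTL + PNG atlas export of the textured surface."""
    import imageio.v3 as iio

    mesh = textured.mesh
    tile_ids = sorted(textured.atlas)
    if tile_ids:
        shapes = [textured.atlas[t].shape for t in tile_ids]
        th = max(s[0] for s in shapes)
        tw = max(s[1] for s in shapes)
        cols = int(np.ceil(np.sqrt(len(tile_ids))))
        rows_n = int(np.ceil(len(tile_ids) / cols))
        atlas_img = np.zeros((rows_n * th, cols * tw), dtype=np.uint8)
        offsets = {}
        for i, t in enumerate(tile_ids):
            img = np.asarray(textured.atlas[t], dtype=float)
            lo, hi = img.min(), img.max()
            img8 = np.zeros_like(img, dtype=np.uint8) if hi <= lo else (
                (img - lo) / (hi - lo) * 255
            ).astype(np.uint8)
            r, c = divmod(i, cols)
            atlas_img[r * th : r * th + img.shape[0], c * tw : c * tw + img.shape[1]] = img8
            offsets[t] = (r * th, c * tw)
        iio.imwrite(out_dir / "textured_surface_atlas.png", atlas_img)
    else:
        offsets = {}
        atlas_img = np.zeros((1, 1), dtype=np.uint8)

    mtl = out_dir / "textured_surface.mtl"
    mtl.write_text(
        "newmtl atlas\nKa 1 1 1\nKd 1 1 1\nmap_Kd textured_surface_atlas.png\n"
    )
    lines = ["mtllib textured_surface.mtl", "usemtl atlas"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    vt_index: dict[tuple[int, int], int] = {}
    face_lines = []
    ah, aw = atlas_img.shape
    for fid, face in enumerate(mesh.facets):
        tid = int(textured.facet_view[fid]) if fid < len(textured.facet_view) else -1
        if tid >= 0 and fid in textured.texcoords and tid in offsets:
            ro, co = offsets[tid]
            refs = []
            for vi, px in zip(face, textured.texcoords[fid]):
                u = (co + px[0]) / aw
                v = 1.0 - (ro + px[1]) / ah
                key = (fid, int(vi))
                vt_index[key] = len(vt_index) + 1
                lines.append(f"vt {u:.6f} {v:.6f}")
                refs.append(f"{vi + 1}/{vt_index[key]}")
            face_lines.append("f " + " ".join(refs))
        else:
            face_lines.append("f " + " ".join(str(v + 1) for v in face))
    (out_dir / "textured_surface.obj").write_text("\n".join(lines + face_lines) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the artifact set; returns the run dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", asdict(config))

    mesh = _load_or_make_mesh(config)
    mesh.save(out_dir / "mesh.ply")

    grids, poses, plan = _plan(config, mesh)
    plan.to_json(out_dir / "trajectory.json")

    tiles, labels = _acquire_and_fuse(config, grids, plan)
    import tifffile

    tifffile.imwrite(
        out_dir / "fused_tiles.tif",
        np.stack([tiles[gid].image.astype(np.uint16) for gid in sorted(tiles)]),
        photometric="minisblack",
    )

    pose_by_gid = {g.id: p for g, p in zip(grids, poses)}
    textured = _synthesize(config, mesh, pose_by_gid, tiles)
    _export_obj(textured, out_dir)

    rows = _features(config, tiles, labels)
    import csv

    with open(out_dir / "features.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["grid_id", "row", "col", *cad.FEATURE_NAMES, "label"])
        for gid, sub, fv in rows:
            writer.writerow([gid, *sub.origin, *fv.as_array().tolist(), sub.label])

    model, train, test = _train(config, rows)
    (out_dir / "model.json").write_text(
        json.dumps(
            {
                "coefficients": model.coefficients.tolist(),
                "intercept": model.intercept,
                "feature_mean": model.feature_mean.tolist(),
                "feature_std": model.feature_std.tolist(),
                "threshold": model.threshold,
                "feature_names": list(cad.FEATURE_NAMES),
            },
            indent=2,
        )
    )

    report = _evaluate(model, test)
    (out_dir / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=2))
    logger.info(
        "pipeline complete: AUC %.3f, sensitivity %.3f, specificity %.3f",
        report.auc,
        report.sensitivity,
        report.specificity,
    )
    return out_dir
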