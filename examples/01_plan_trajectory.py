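"""Plan a microscope scan trajectory over an irregular tissue surface.

Builds a bumpy synthetic surface (~12 x 12 mm, 2 mm height variation),
decomposes it into FOV-sized grids, computes a pose and an elevation
schedule per grid, and orders the scan path to keep rotation-stage
motion small.
"""

import numpy as np

from surfscan import synthetic
from surfscan.calibration import intrinsic_matrix
from surfscan.fusion import compute_fov
from surfscan.trajectory import (
    OBJECTIVE_PRESETS,
    elevation_schedule,
    grid_pose,
    order_path,
    plan_grids,
)

mesh = synthetic.make_surface("bumpy", {"extent": 12.0, "amplitude": 2.0}, seed=1)
objective = OBJECTIVE_PRESETS["5x"]
fov = compute_fov(objective, intrinsic_matrix(objective.magnification, 4.5))
print(f"FOV edge at 5x: {fov:.3f} mm")

grids = plan_grids(mesh, fov)
poses = [grid_pose(g, objective) for g in grids]
elevs = [elevation_schedule(g, objective) for g in grids]
trajectory = order_path(grids, poses, elevs)

print(f"{len(grids)} grids cover {mesh.n_vertices} vertices")
tilts = [p.tilt_deg() for p in poses]
print(f"tilt range: {min(tilts):.1f} to {max(tilts):.1f} deg (limit 83.3)")
frames = [len(e) for e in elevs]
print(f"frames per grid: {min(frames)}..{max(frames)} (clamped to [10, 30])")
# each stop: grid id, stage angles, number of focus elevations
gid, pose, elev = trajectory.entries[0]
print(f"first stop: grid {gid}, rx={pose.rx:.2f} deg, ry={pose.ry:.2f} deg, "
      f"{len(elev)} elevations spanning {elev[-1] - elev[0]:.2f} mm")
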