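"""Calibrate the microscope from a simulated chessboard scene.

Projects the 13 calibration dots through a known homography (true
magnification 5.0, slight tilt), then recovers the magnification, the
extrinsic pose, a rotation-stage positional correction, and the R_z
rotation-axis offset by circle fitting.
"""

import numpy as np

from surfscan.calibration import (
    ExtrinsicPose,
    Homography,
    estimate_extrinsic,
    estimate_magnification,
    fit_circle,
    intrinsic_matrix,
    rotation_offset,
)
from surfscan.synthetic import make_calibration_scene

# --- magnification + extrinsic pose from dot correspondences -------
th = np.radians(1.5)
tilt = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]])
true_pose = ExtrinsicPose.from_rotation(tilt, tx=25.0, ty=-10.0)
image_px, board_mm = make_calibration_scene(5.0, true_pose=true_pose, noise_px=0.1, seed=0)

m, rms = estimate_magnification(image_px, board_mm)
print(f"recovered magnification: {m:.5f} (true 5.0), residual {rms:.3f} px")

intr = intrinsic_matrix(m, 4.5)
pose, rms_b = estimate_extrinsic(intr, image_px, board_mm)
print(f"recovered tilt: {pose.tilt_deg():.3f} deg (true 1.5), "
      f"translation ({pose.tx:.1f}, {pose.ty:.1f}) um")

# --- rotation-stage positional correction (centre-dot drift) -------
h_hat = Homography(intr.matrix, estimated=True)
offset = rotation_offset((2610.0, 2548.0), h_hat)
print(f"stage correction for a (50, -12) px drift: ({offset[0]:.1f}, {offset[1]:.1f}) um")

# --- R_z axis from the tracked centre-dot circle -------------------
t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
track = np.column_stack([40 + 120 * np.cos(t), -15 + 120 * np.sin(t)])
center, radius, _ = fit_circle(track + np.random.default_rng(1).normal(0, 0.5, track.shape))
print(f"R_z axis offset: centre ({center[0]:.1f}, {center[1]:.1f}) um, radius {radius:.1f} um")
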