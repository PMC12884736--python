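"""Projection model and calibration fits: parameter-recovery oracles."""

import numpy as np
import pytest

from surfscan import synthetic
from surfscan.calibration import (
    CameraIntrinsics,
    ExtrinsicPose,
    Homography,
    compose_homography,
    estimate_extrinsic,
    estimate_magnification,
    fit_axis_skew,
    fit_circle,
    interpolate_offsets,
    intrinsic_matrix,
    rotation_offset,
)


class TestIntrinsics:
    def test_printed_pixel_pitch_scale(self):
        a = intrinsic_matrix(5.0, 4.5)
        assert a.matrix[0, 0] == pytest.approx(5.0 / 4.5)
        assert a.matrix[1, 1] == pytest.approx(5.0 / 4.5)
        assert a.matrix[2, 2] == 1.0
        assert a.matrix[0, 1] == 0.0

    def test_unit_parameters_give_identity(self):
        np.testing.assert_array_equal(intrinsic_matrix(1.0, 1.0).matrix, np.eye(3))

    @pytest.mark.parametrize("m,du", [(0.0, 4.5), (5.0, 0.0), (-1.0, 4.5)])
    def test_nonpositive_parameters_error(self, m, du):
        with pytest.raises(ValueError):
            intrinsic_matrix(m, du)


class TestComposeHomography:
    def test_identity_extrinsic_gives_intrinsic(self, intrinsics_5x):
        h = compose_homography(intrinsics_5x, ExtrinsicPose.identity())
        np.testing.assert_allclose(h.H, intrinsics_5x.matrix)

    def test_matches_bruteforce_product(self, rng, intrinsics_5x):
        th = rng.uniform(0, 2 * np.pi)
        b = ExtrinsicPose(np.cos(th), -np.sin(th), 0.0, np.sin(th), np.cos(th), 0.0, 12.0, -7.0)
        h = compose_homography(intrinsics_5x, b)
        # elementwise multiply-accumulate oracle
        expect = np.zeros((3, 3))
        am, bm = intrinsics_5x.matrix, b.matrix
        for i in range(3):
            for j in range(3):
                expect[i, j] = sum(am[i, k] * bm[k, j] for k in range(3))
        np.testing.assert_allclose(h.H, expect)

    def test_singular_product_errors(self, intrinsics_5x):
        b = ExtrinsicPose(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            compose_homography(intrinsics_5x, b)

    def test_centre_displacement_closed_form(self, intrinsics_5x):
        h = compose_homography(intrinsics_5x, ExtrinsicPose.identity())
        for p in [1.0, 10.0, 517.0, -250.0]:
            # pixel displacement p corresponds to p * du / m micrometres
            um = h.inverse_apply(np.array([[p, 0.0]]))
            assert um[0, 0] == pytest.approx(p * 4.5 / 5.0, abs=1e-9)


class TestEstimateMagnification:
    def test_exact_recovery_noise_free(self):
        img, board = synthetic.make_calibration_scene(5.0)
        m, rms = estimate_magnification(img, board)
        assert m == pytest.approx(5.0, abs=1e-9)
        assert rms < 1e-9

    def test_recovery_under_pixel_noise(self):
        img, board = synthetic.make_calibration_scene(5.0, noise_px=0.1, seed=42)
        m, _ = estimate_magnification(img, board)
        assert abs(m - 5.0) < 0.01

    def test_rmse_decreases_with_more_points(self):
        # estimator error should shrink roughly like 1/sqrt(n points)
        clean, board = synthetic.make_calibration_scene(5.0, noise_px=0.0)

        def mc_rmse(reps, n_copies):
            errs = []
            for s in range(reps):
                rng = np.random.default_rng(1000 + s)
                imgs = np.tile(clean, (n_copies, 1))
                imgs = imgs + rng.normal(0, 0.5, imgs.shape)
                boards = np.tile(board, (n_copies, 1))
                m, _ = estimate_magnification(imgs, boards)
                errs.append(m - 5.0)
            return np.sqrt(np.mean(np.square(errs)))

        assert mc_rmse(30, 8) < mc_rmse(30, 1)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            estimate_magnification(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_collinear_points_error(self):
        board = np.column_stack([np.linspace(0, 10, 5), np.zeros(5)])
        img = board * 1000.0
        with pytest.raises(ValueError):
            estimate_magnification(img, board)


class TestEstimateExtrinsic:
    def test_identity_recovery(self, intrinsics_5x):
        img, board = synthetic.make_calibration_scene(5.0)
        pose, rms = estimate_extrinsic(intrinsics_5x, img, board)
        assert rms < 1e-9
        assert pose.parallelism_deviation() < 1e-9

    def test_tilt_recovery_within_tolerance(self, intrinsics_5x):
        th = np.radians(2.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        true_pose = ExtrinsicPose.from_rotation(rot, tx=50.0, ty=-20.0)
        img, board = synthetic.make_calibration_scene(5.0, true_pose=true_pose)
        pose, _ = estimate_extrinsic(intrinsics_5x, img, board)
        assert abs(pose.tilt_deg() - 2.0) < 0.05
        assert pose.tx == pytest.approx(50.0, abs=1e-6)
        assert pose.ty == pytest.approx(-20.0, abs=1e-6)

    def test_degenerate_points_error(self, intrinsics_5x):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            estimate_extrinsic(intrinsics_5x, pts, pts)


class TestRotationOffset:
    def test_centered_dot_gives_zero(self, intrinsics_5x):
        h = Homography(intrinsics_5x.matrix)
        assert rotation_offset((2560.0, 2560.0), h) == (0.0, 0.0)

    def test_known_displacement_closed_form(self, intrinsics_5x):
        h = Homography(intrinsics_5x.matrix)
        ox, oy = rotation_offset((2660.0, 2560.0), h)
        assert ox == pytest.approx(100 * 4.5 / 5.0)  # 90 um
        assert oy == pytest.approx(0.0)

    def test_singular_homography_rejected(self):
        with pytest.raises(ValueError):
            Homography(np.zeros((3, 3)))

    def test_agrees_with_explicit_inverse_on_random_homographies(self, rng):
        # oracle: cofactor-expansion 3x3 inverse, independent of np.linalg.inv
        def inv3(h):
            cof = np.array(
                [
                    [
                        h[1, 1] * h[2, 2] - h[1, 2] * h[2, 1],
                        h[0, 2] * h[2, 1] - h[0, 1] * h[2, 2],
                        h[0, 1] * h[1, 2] - h[0, 2] * h[1, 1],
                    ],
                    [
                        h[1, 2] * h[2, 0] - h[1, 0] * h[2, 2],
                        h[0, 0] * h[2, 2] - h[0, 2] * h[2, 0],
                        h[0, 2] * h[1, 0] - h[0, 0] * h[1, 2],
                    ],
                    [
                        h[1, 0] * h[2, 1] - h[1, 1] * h[2, 0],
                        h[0, 1] * h[2, 0] - h[0, 0] * h[2, 1],
                        h[0, 0] * h[1, 1] - h[0, 1] * h[1, 0],
                    ],
                ]
            )
            det = (
                h[0, 0] * cof[0, 0] + h[0, 1] * cof[1, 0] + h[0, 2] * cof[2, 0]
            )
            return cof / det

        for _ in range(200):
            hm = rng.uniform(-2, 2, (3, 3))
            hm[2] = [0, 0, 1]
            hm[0, 0] += 3.0
            hm[1, 1] += 3.0
            if abs(np.linalg.det(hm)) < 1e-6:
                continue
            h = Homography(hm)
            o = rng.uniform(0, 5120, 2)
            got = rotation_offset(tuple(o), h)
            v = inv3(hm) @ np.array([o[0] - 2560.0, o[1] - 2560.0, 1.0])
            np.testing.assert_allclose(got, v[:2] / v[2], atol=1e-9)

    def test_offset_recenters_simulated_image(self, rng, intrinsics_5x):
        # Eq-roundtrip: applying the offset through H re-centres the dot
        th = rng.uniform(-0.1, 0.1)
        b = ExtrinsicPose(np.cos(th), -np.sin(th), 0, np.sin(th), np.cos(th), 0, 33.0, -12.0)
        h = compose_homography(intrinsics_5x, b, estimated=True)
        o_px = np.array([2700.0, 2450.0])
        off = rotation_offset(tuple(o_px), h)
        repro = h.apply(np.array([off])) + 2560.0
        np.testing.assert_allclose(repro[0], o_px, atol=1e-9)


class TestInterpolateOffsets:
    def test_knot_is_exact(self):
        out = interpolate_offsets([0.0, 10.0], [(0.0, 0.0), (4.0, -2.0)], 10.0)
        assert out == (4.0, -2.0)

    def test_midpoint_linearity(self):
        out = interpolate_offsets([0.0, 10.0], [(0.0, 0.0), (4.0, -2.0)], 5.0)
        assert out == (2.0, -1.0)

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError):
            interpolate_offsets([0.0, 10.0], [(0.0, 0.0), (4.0, -2.0)], 11.0)


class TestFitCircle:
    def test_exact_points(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([100 + 300 * np.cos(t), -50 + 300 * np.sin(t)])
        center, radius, rms = fit_circle(pts)
        np.testing.assert_allclose(center, [100, -50], atol=1e-6)
        assert radius == pytest.approx(300.0, abs=1e-6)
        assert rms < 1e-6

    def test_noisy_points_center_within_2um(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts = np.column_stack([100 + 300 * np.cos(t), -50 + 300 * np.sin(t)])
        pts = pts + rng.normal(0, 1.0, pts.shape)
        center, _, _ = fit_circle(pts)
        assert np.linalg.norm(center - [100, -50]) < 2.0

    def test_collinear_points_error(self):
        pts = np.column_stack([np.arange(3.0), np.arange(3.0)])
        with pytest.raises(ValueError):
            fit_circle(pts)


class TestFitAxisSkew:
    def test_axis_aligned_is_zero(self):
        pts = np.column_stack([np.linspace(0, 10, 5), np.zeros(5)])
        assert fit_axis_skew(pts, "x") == pytest.approx(0.0, abs=1e-12)

    def test_one_degree_rotation_recovered(self):
        th = np.radians(1.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = np.column_stack([np.linspace(0, 10, 7), np.zeros(7)]) @ rot.T
        assert fit_axis_skew(pts, "x") == pytest.approx(1.0, abs=1e-6)

    def test_y_axis_reference(self):
        pts = np.column_stack([np.zeros(5), np.linspace(0, 8, 5)])
        assert fit_axis_skew(pts, "y") == pytest.approx(0.0, abs=1e-12)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            fit_axis_skew(np.array([[1.0, 1.0]]))
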