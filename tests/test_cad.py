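"""Subimage features, nucleus segmentation, and the margin classifier."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from surfscan import synthetic
from surfscan.cad import (
    FEATURE_NAMES,
    MarginModel,
    SubImage,
    class_balance,
    evaluate,
    exclude_artifacts,
    extract_features,
    filter_by_section_distance,
    margin_areas,
    segment_nuclei,
    split_dataset,
    subimage_edge_mm,
    tile_image,
    train_margin_model,
)
from surfscan.calibration import intrinsic_matrix


class TestTileImage:
    def test_exact_tiling_count(self):
        subs = tile_image(np.zeros((512, 512)), size=128)
        assert len(subs) == 16

    def test_partial_edges_discarded(self):
        subs = tile_image(np.zeros((130, 130)), size=128)
        assert len(subs) == 1
        assert subs[0].origin == (0, 0)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((100, 100)), size=128)

    def test_subimage_edge_matches_printed_footprint(self):
        edge = subimage_edge_mm(intrinsic_matrix(5.0, 4.5), size=128)
        assert edge == pytest.approx(0.1152)
        assert round(edge, 2) == 0.12


class TestSectionDistanceFilter:
    def line(self):
        return np.array([[-5.0, 0.0], [5.0, 0.0]])

    def sub_at(self, x, y):
        return SubImage(patch=np.zeros((128, 128)), surface_position=np.array([x, y]))

    def test_on_line_kept(self):
        assert filter_by_section_distance([self.sub_at(0, 0)], self.line())

    def test_band_boundary(self):
        kept = filter_by_section_distance(
            [self.sub_at(0, 0.49), self.sub_at(0, 0.51)], self.line()
        )
        assert len(kept) == 1
        assert kept[0].section_distance == pytest.approx(0.49)

    def test_all_far_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            kept = filter_by_section_distance([self.sub_at(0, 3.0)], self.line())
        assert kept == []


def disk_patch(centers, radius=10, size=128, fg=200.0, bg=50.0):
    img = np.full((size, size), bg)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    img[mask] = fg
    return img, mask


class TestSegmentNuclei:
    def test_separable_levels_exact(self):
        img, truth = disk_patch([(30, 30), (64, 90), (100, 40)])
        mask, comps = segment_nuclei(SubImage(patch=img))
        np.testing.assert_array_equal(mask, truth)
        assert len(comps) == 3

    def test_gaussian_mixture_under_2pct_error(self, rng):
        truth = np.zeros((128, 128), dtype=bool)
        yy, xx = np.mgrid[0:128, 0:128]
        for cy, cx in rng.uniform(10, 118, (12, 2)):
            truth |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 64
        img = np.where(truth, rng.normal(180, 15, truth.shape), rng.normal(60, 15, truth.shape))
        mask, _ = segment_nuclei(SubImage(patch=img))
        assert (mask ^ truth).mean() < 0.02

    def test_constant_image_empty_mask(self):
        mask, comps = segment_nuclei(SubImage(patch=np.full((128, 128), 5.0)))
        assert not mask.any()
        assert comps == []


class TestExtractFeatures:
    def test_three_disk_fixture(self):
        img, mask = disk_patch([(30, 30), (64, 90), (100, 40)])
        m, comps = segment_nuclei(SubImage(patch=img))
        fv = extract_features(SubImage(patch=img), m, comps)
        # oracle: count rasterized pixels of one disk directly
        single = disk_patch([(64, 64)])[1].sum()
        assert fv.mean_nuclear_area == pytest.approx(single)
        assert fv.std_nuclear_area == pytest.approx(0.0)
        assert fv.nc_ratio == pytest.approx(3 * single / 128**2)
        assert fv.avg_nuclear_intensity == pytest.approx(200.0)

    def test_empty_mask_flagged(self):
        fv = extract_features(
            SubImage(patch=np.zeros((128, 128))), np.zeros((128, 128), dtype=bool), []
        )
        assert fv.excluded
        assert fv.as_array().tolist() == [0, 0, 0, 0]

    def test_single_component_zero_std(self):
        img, _ = disk_patch([(64, 64)])
        m, comps = segment_nuclei(SubImage(patch=img))
        fv = extract_features(SubImage(patch=img), m, comps)
        assert fv.std_nuclear_area == 0.0

    def test_nc_ratio_tracks_generated_nuclear_fraction(self):
        # nc_ratio must rise monotonically with the generator's density
        densities = np.linspace(300, 3000, 10)
        ratios = []
        for i, d in enumerate(densities):
            params = synthetic.TissueParams(nuclear_density=d)
            img, _ = synthetic.make_tissue_texture(
                params, extent_mm=0.9216, pixel_pitch_um=1.8, seed=500 + i
            )
            sub = SubImage(patch=img)
            mask, comps = segment_nuclei(sub)
            ratios.append(extract_features(sub, mask, comps).nc_ratio)
        rho, _ = spearmanr(densities, ratios)
        assert rho > 0.99


class TestExcludeArtifacts:
    def test_empty_mask_keeps_all(self):
        subs = tile_image(np.zeros((256, 256)), size=128)
        kept = exclude_artifacts(subs, np.zeros((256, 256), dtype=bool))
        assert len(kept) == 4

    def test_fully_masked_excluded(self):
        subs = tile_image(np.zeros((256, 256)), size=128)
        mask = np.zeros((256, 256), dtype=bool)
        mask[:128, :128] = True
        kept = exclude_artifacts(subs, mask)
        assert len(kept) == 3
        assert subs[0].excluded

    @pytest.mark.parametrize("overlap_rows,expect_kept", [(6, True), (20, False)])
    def test_overlap_fraction_rule(self, overlap_rows, expect_kept):
        # 6/128 ~ 4.7% kept; 20/128 ~ 15.6% excluded
        subs = tile_image(np.zeros((128, 128)), size=128)
        mask = np.zeros((128, 128), dtype=bool)
        mask[:overlap_rows, :] = True
        kept = exclude_artifacts(subs, mask)
        assert bool(kept) is expect_kept


class TestSplitDataset:
    def make_subs(self, n_pos, n_neg):
        subs = []
        for i in range(n_pos + n_neg):
            s = SubImage(patch=np.zeros((8, 8)))
            s.label = "positive" if i < n_pos else "negative"
            subs.append(s)
        return subs

    def test_stratified_counts(self):
        train, test = split_dataset(self.make_subs(50, 50), 0.6, seed=3)
        assert len(train) == 60 and len(test) == 40
        assert sum(s.label == "positive" for s in train) == 30
        assert sum(s.label == "positive" for s in test) == 20

    def test_same_seed_identical(self):
        subs = self.make_subs(20, 30)
        a = split_dataset(subs, seed=9)
        b = split_dataset(subs, seed=9)
        assert [id(s) for s in a[0]] == [id(s) for s in b[0]]

    def test_disjoint_and_exhaustive(self, rng):
        subs = self.make_subs(17, 23)
        train, test = split_dataset(subs, seed=int(rng.integers(100)))
        ids = [id(s) for s in train] + [id(s) for s in test]
        assert len(set(ids)) == 40

    def test_tiny_class_errors(self):
        with pytest.raises(ValueError):
            split_dataset(self.make_subs(1, 10))


class TestTrainMarginModel:
    def test_separable_features_perfect_training_auc(self, rng):
        x = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(6, 1, (50, 4))])
        y = np.r_[np.zeros(50), np.ones(50)]
        model = train_margin_model(x, y)
        rep = evaluate(model, x, y)
        assert rep.auc == pytest.approx(1.0)

    def test_coefficient_recovery_within_wald_intervals(self):
        rng = np.random.default_rng(77)
        beta = np.array([2.0, -1.0, 0.5, 0.0])
        n = 5000
        x = rng.standard_normal((n, 4))
        p = 1 / (1 + np.exp(-(x @ beta)))
        y = (rng.uniform(size=n) < p).astype(int)
        model = train_margin_model(x, y)
        ci = model.wald_intervals()
        # features standardized with SD ~ 1, so coefficients are comparable
        scaled_truth = beta * x.std(axis=0)
        for j in range(4):
            assert ci[j, 0] <= scaled_truth[j] <= ci[j, 1]

    def test_agrees_with_sklearn(self, rng):
        # independent route: sklearn's lbfgs solver on the same problem
        from sklearn.linear_model import LogisticRegression

        x = rng.standard_normal((400, 4))
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-(x @ [1.0, -0.5, 0.2, 0.0])))).astype(int)
        model = train_margin_model(x, y)
        z = (x - model.feature_mean) / model.feature_std
        sk = LogisticRegression(C=1e6, tol=1e-10, max_iter=2000).fit(z, y)
        np.testing.assert_allclose(model.coefficients, sk.coef_[0], atol=1e-3)
        assert model.intercept == pytest.approx(float(sk.intercept_[0]), abs=1e-3)

    def test_single_class_errors(self, rng):
        x = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            train_margin_model(x, np.ones(10))

    def test_nonfinite_features_error(self):
        x = np.zeros((10, 4))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_margin_model(x, np.r_[np.zeros(5), np.ones(5)])


def trivial_model():
    return MarginModel(
        coefficients=np.array([1.0, 0.0, 0.0, 0.0]),
        intercept=0.0,
        feature_mean=np.zeros(4),
        feature_std=np.ones(4),
        threshold=0.5,
    )


class TestEvaluate:
    def test_perfect_scores(self):
        x = np.zeros((20, 4))
        x[10:, 0] = 10.0
        x[:10, 0] = -10.0
        y = np.r_[np.zeros(10), np.ones(10)]
        rep = evaluate(trivial_model(), x, y)
        assert rep.auc == pytest.approx(1.0)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((2000, 4))
        y = rng.integers(0, 2, 2000)
        rep = evaluate(trivial_model(), x, y)
        assert 0.47 <= rep.auc <= 0.53

    def test_auc_equals_mann_whitney_bruteforce(self, rng):
        x = rng.standard_normal((150, 4))
        y = rng.integers(0, 2, 150)
        y[:5] = 1
        y[5:10] = 0
        model = trivial_model()
        rep = evaluate(model, x, y)
        scores = model.predict_proba(x)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal((100, 4))
        y = rng.integers(0, 2, 100)
        y[:3] = 1
        y[3:6] = 0
        rep1 = evaluate(trivial_model(), x, y)
        x2 = x.copy()
        x2[:, 0] = np.exp(x[:, 0])  # strictly increasing transform of the score
        rep2 = evaluate(trivial_model(), x2, y)
        assert rep1.auc == pytest.approx(rep2.auc, abs=1e-12)

    def test_roc_monotone(self, rng):
        x = rng.standard_normal((100, 4))
        y = rng.integers(0, 2, 100)
        y[:3] = 1
        y[3:6] = 0
        rep = evaluate(trivial_model(), x, y)
        assert np.all(np.diff(rep.fpr) >= 0)
        assert np.all(np.diff(rep.tpr) >= 0)

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            evaluate(trivial_model(), rng.standard_normal((10, 4)), np.ones(10))


class TestMarginAreas:
    def test_single_positive_subimage(self):
        edge = subimage_edge_mm(intrinsic_matrix(5.0, 4.5))
        areas = margin_areas(np.array([[True]]), edge)
        assert areas == [pytest.approx(0.1152**2)]
        assert areas[0] == pytest.approx(0.0133, abs=0.0002)

    def test_empty_map(self):
        assert margin_areas(np.zeros((4, 4), dtype=bool), 0.1) == []

    def test_block_is_one_component(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:3, 1:3] = True
        areas = margin_areas(m, 0.1152)
        assert areas == [pytest.approx(4 * 0.1152**2)]

    def test_diagonal_is_8_connected(self):
        m = np.eye(3, dtype=bool)
        assert len(margin_areas(m, 1.0)) == 1


class TestClassBalance:
    def test_percentages_from_counts(self):
        out = class_balance(4412, 5702, 2896, 3847)
        assert out["train_total"] == 10114
        assert out["test_total"] == 6743
        assert round(out["train_positive_pct"], 1) == 43.6
        assert round(out["test_positive_pct"], 1) == 42.9
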