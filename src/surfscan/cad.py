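"""Computer-aided tumor-margin assessment from fused surface images.

Fused tiles are cut into 128x128-pixel subimages (~0.12 x 0.12 mm^2 at
5x), restricted to a 0.5 mm band around the histology sectioning line so
labels transfer from the H&E ground truth, and cleared of annotated
artifacts (scratches, hemorrhagic necrosis).  In each subimage, nuclei —
brighter than cytoplasm in the fluorescence images — are segmented by
2-cluster K-means on pixel intensity, and four features are measured:

* nucleocytoplasmic (NC) ratio: nucleus pixels / total pixels,
* average nuclear signal intensity,
* mean nuclear cross-section area (pixels),
* standard deviation of nuclear cross-section area (pixels).

A logistic-regression margin model is trained on standardized features
(maximum likelihood via iteratively reweighted least squares) and
evaluated with ROC curves, AUC, and sensitivity/specificity with Wilson
95% confidence intervals at the Youden-optimal training threshold.
Positive-margin areas are the 8-connected components of positive
subimage calls times the subimage footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from sklearn.cluster import KMeans

from .calibration import CameraIntrinsics

__all__ = [
    "SubImage",
    "FeatureVector",
    "MarginModel",
    "EvalReport",
    "tile_image",
    "subimage_edge_mm",
    "filter_by_section_distance",
    "segment_nuclei",
    "extract_features",
    "exclude_artifacts",
    "split_dataset",
    "train_margin_model",
    "evaluate",
    "margin_areas",
    "class_balance",
]

FEATURE_NAMES = (
    "nc_ratio",
    "avg_nuclear_intensity",
    "mean_nuclear_area",
    "std_nuclear_area",
)


@dataclass
class SubImage:
    """One 128x128 patch with its provenance and pathology label."""

    patch: np.ndarray
    origin: tuple[int, int] = (0, 0)  # (row, col) offset in the source tile
    surface_position: np.ndarray | None = None  # mm
    section_distance: float = 0.0  # mm
    label: str = "unknown"  # positive | negative | unknown
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.patch.shape[0] != self.patch.shape[1]:
            raise ValueError("subimage patch must be square")
        if self.section_distance < 0:
            raise ValueError("section_distance must be >= 0")


@dataclass(frozen=True)
class FeatureVector:
    nc_ratio: float
    avg_nuclear_intensity: float
    mean_nuclear_area: float
    std_nuclear_area: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.nc_ratio <= 1.0):
            raise ValueError("nc_ratio must lie in [0, 1]")
        if self.mean_nuclear_area < 0 or self.std_nuclear_area < 0:
            raise ValueError("areas must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.nc_ratio,
                self.avg_nuclear_intensity,
                self.mean_nuclear_area,
                self.std_nuclear_area,
            ]
        )


@dataclass
class MarginModel:
    """Logistic margin classifier: standardized features, IRLS coefficients."""

    coefficients: np.ndarray  # (4,)
    intercept: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    threshold: float = 0.5  # operating probability threshold
    covariance: np.ndarray | None = None  # Wald covariance, standardized scale

    def __post_init__(self) -> None:
        if len(self.coefficients) != 4:
            raise ValueError("margin model uses exactly 4 features")

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        z = (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_std
        return z @ self.coefficients + self.intercept

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_scores(features))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_proba(features) >= self.threshold).astype(int)

    def wald_intervals(self, level: float = 0.95) -> np.ndarray:
        """(4, 2) per-coefficient Wald confidence bounds (standardized scale)."""
        if self.covariance is None:
            raise ValueError("model was fitted without covariance")
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.diag(self.covariance))[1:]  # skip intercept
        return np.column_stack([self.coefficients - z * se, self.coefficients + z * se])


@dataclass
class EvalReport:
    """ROC-based evaluation of a margin model on a labelled test set."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    confusion: dict  # tn, fp, fn, tp
    per_feature_auc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "confusion": self.confusion,
            "per_feature_auc": self.per_feature_auc,
        }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def tile_image(image: np.ndarray, size: int = 128) -> list[SubImage]:
    """Non-overlapping raster tiling into size x size subimages.

    Tiling starts at the top-left corner; partial tiles at the right and
    bottom edges are discarded, never padded.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than one {size}x{size} tile")
    subs = []
    for r in range(0, h - size + 1, size):
        for c in range(0, w - size + 1, size):
            subs.append(SubImage(patch=image[r : r + size, c : c + size], origin=(r, c)))
    return subs


def subimage_edge_mm(intrinsics: CameraIntrinsics, size: int = 128) -> float:
    """Physical edge length of a subimage: ``size * du / m`` in mm."""
    return size * intrinsics.du / intrinsics.m / 1000.0


def _point_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    p = np.asarray(point, dtype=float)
    line = np.asarray(polyline, dtype=float)
    d = p.shape[-1]
    line = line[:, :d] if line.shape[1] >= d else line
    if len(line) == 1:
        return float(np.linalg.norm(p - line[0]))
    best = np.inf
    for a, b in zip(line[:-1], line[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


def filter_by_section_distance(
    subimages: list[SubImage],
    section_line: np.ndarray,
    max_dist: float = 0.5,
) -> list[SubImage]:
    """Keep subimages within ``max_dist`` mm of the sectioning polyline.

    Distances are Euclidean in the surface's tangent-plane coordinates
    (the first components of ``surface_position``); each subimage's
    ``section_distance`` is updated in place.  An empty result triggers a
    warning.
    """
    line = np.asarray(section_line, dtype=float)
    if line.size == 0:
        raise ValueError("section polyline must be non-empty")
    kept = []
    for sub in subimages:
        if sub.surface_position is None:
            continue
        dist = _point_polyline_distance(np.asarray(sub.surface_position), line)
        sub.section_distance = dist
        if dist <= max_dist:
            kept.append(sub)
    if not kept:
        warnings.warn("no subimages within the section-distance band", stacklevel=2)
    return kept


def segment_nuclei(
    subimage: SubImage | np.ndarray, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, list]:
    """Segment nuclei by 2-cluster K-means on pixel intensity.

    The brighter cluster is labelled nuclei (fluorescence convention:
    stained nuclei outshine cytoplasm before any display inversion).
    Connected components use 8-connectivity; the returned component list
    carries per-nucleus centroids and pixel areas.  A constant patch
    yields an empty mask and no components.
    """
    patch = subimage.patch if isinstance(subimage, SubImage) else np.asarray(subimage)
    flat = patch.reshape(-1, 1).astype(float)
    if np.ptp(flat) == 0:
        return np.zeros(patch.shape, dtype=bool), []
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(flat)
    bright = int(np.argmax(km.cluster_centers_.ravel()))
    mask = (assignments == bright).reshape(patch.shape)
    labels = cc_label(mask, connectivity=2)
    components = regionprops(labels)
    return mask, components


def extract_features(
    subimage: SubImage | np.ndarray,
    mask: np.ndarray,
    components: list,
) -> FeatureVector:
    """The four margin features of one subimage.

    An empty mask returns the all-zero vector flagged ``excluded``;
    a single nucleus has zero area standard deviation.
    """
    patch = subimage.patch if isinstance(subimage, SubImage) else np.asarray(subimage)
    if mask.shape != patch.shape:
        raise ValueError("mask must align with the patch")
    n_pix = int(mask.sum())
    if n_pix == 0:
        return FeatureVector(0.0, 0.0, 0.0, 0.0, excluded=True)
    areas = np.array([c.area for c in components], dtype=float)
    return FeatureVector(
        nc_ratio=n_pix / mask.size,
        avg_nuclear_intensity=float(patch[mask].mean()),
        mean_nuclear_area=float(areas.mean()),
        std_nuclear_area=float(areas.std()),
    )


def exclude_artifacts(
    subimages: list[SubImage],
    exclusion_mask: np.ndarray,
    max_overlap: float = 0.10,
) -> list[SubImage]:
    """Drop subimages overlapping an annotated artifact mask by > 10%.

    The mask is an annotation layer aligned with the source tile
    (scratches, hemorrhagic necrosis); excluded subimages are flagged and
    removed from the returned list.
    """
    mask = np.asarray(exclusion_mask, dtype=bool)
    kept = []
    for sub in subimages:
        r, c = sub.origin
        size = sub.patch.shape[0]
        if r + size > mask.shape[0] or c + size > mask.shape[1]:
            raise ValueError("exclusion mask does not cover the subimage footprint")
        frac = mask[r : r + size, c : c + size].mean()
        if frac > max_overlap:
            sub.excluded = True
        else:
            kept.append(sub)
    return kept


def split_dataset(
    subimages: list[SubImage],
    train_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[list[SubImage], list[SubImage]]:
    """Seeded, label-stratified split into train and test sets.

    Per class, ``round(train_fraction * n)`` items go to training after a
    seeded shuffle; the split is disjoint and exhaustive and identical
    for identical seeds.
    """
    if len(subimages) < 2:
        raise ValueError("need at least 2 subimages")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {}
    for i, sub in enumerate(subimages):
        by_label.setdefault(sub.label, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lbl in sorted(by_label):
        idx = np.array(by_label[lbl])
        if len(idx) < 2:
            raise ValueError(f"class {lbl!r} has fewer than 2 members")
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    return (
        [subimages[i] for i in sorted(train_idx)],
        [subimages[i] for i in sorted(test_idx)],
    )


def _irls_logistic(
    x: np.ndarray, y: np.ndarray, ridge: float = 1e-6, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit by IRLS with a small L2 guard.

    Returns (beta, covariance) where beta[0] is the intercept and the
    covariance is the inverse penalised Fisher information.
    """
    n, p = x.shape
    design = np.hstack([np.ones((n, 1)), x])
    beta = np.zeros(p + 1)
    ll_old = -np.inf
    penalty = ridge * np.eye(p + 1)
    penalty[0, 0] = 0.0  # intercept unpenalised
    for _ in range(max_iter):
        eta = design @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        info = design.T @ (design * w[:, None]) + penalty
        grad = design.T @ (y - mu) - penalty @ beta
        beta = beta + np.linalg.solve(info, grad)
        eta = design @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    eta = design @ beta
    mu = _sigmoid(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv(design.T @ (design * w[:, None]) + penalty)
    return beta, cov


def train_margin_model(features: np.ndarray, labels: np.ndarray) -> MarginModel:
    """Fit the logistic margin model on training features.

    Features are standardized with the training mean and SD; the fit is
    maximum likelihood by iteratively reweighted least squares with an L2
    ridge of 1e-6 as a numerical guard (convergence: log-likelihood
    change < 1e-8).  The operating threshold is set to the Youden-optimal
    point (max sensitivity + specificity - 1) of the training ROC.

    Raises
    ------
    ValueError
        If only one class is present or features are non-finite.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if features.ndim != 2 or features.shape[1] != 4:
        raise ValueError("features must be (n, 4)")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("training labels must contain both classes")

    mean = features.mean(axis=0)
    std = features.std(axis=0)
    std[std == 0] = 1.0
    z = (features - mean) / std
    beta, cov = _irls_logistic(z, labels)

    model = MarginModel(
        coefficients=beta[1:],
        intercept=float(beta[0]),
        feature_mean=mean,
        feature_std=std,
        covariance=cov,
    )
    # Youden-optimal operating point on the training ROC
    proba = model.predict_proba(features)
    fpr, tpr, thr = _roc_curve(labels, proba)
    j = tpr - fpr
    model.threshold = float(np.clip(thr[int(np.argmax(j))], 0.0, 1.0))
    return model


def _roc_curve(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr


def _auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def _wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def evaluate(model: MarginModel, features: np.ndarray, labels: np.ndarray) -> EvalReport:
    """ROC evaluation of a margin model on a labelled test set.

    Sensitivity and specificity are reported at the model's stored
    operating threshold with Wilson 95% confidence intervals; the report
    also carries a per-single-feature ROC AUC for each of the four
    features (scored by the raw feature value).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("test labels must contain both classes")

    proba = model.predict_proba(features)
    fpr, tpr, thr = _roc_curve(labels, proba)
    auc = _auc(fpr, tpr)

    pred = (proba >= model.threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0

    per_feature = {}
    for j, name in enumerate(FEATURE_NAMES):
        f_fpr, f_tpr, _ = _roc_curve(labels, features[:, j])
        a = _auc(f_fpr, f_tpr)
        per_feature[name] = max(a, 1.0 - a)  # orientation-free discriminability

    return EvalReport(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=_wilson_ci(tp, tp + fn),
        specificity_ci=_wilson_ci(tn, tn + fp),
        confusion={"tn": tn, "fp": fp, "fn": fn, "tp": tp},
        per_feature_auc=per_feature,
    )


def margin_areas(positive_map: np.ndarray, edge_mm: float) -> list[float]:
    """Areas (mm^2) of 8-connected positive-subimage components.

    ``positive_map`` is the binary grid of positive subimage calls;
    each component's area is its subimage count times ``edge_mm ** 2``.
    """
    positive_map = np.asarray(positive_map, dtype=bool)
    if not positive_map.any():
        return []
    labels = cc_label(positive_map, connectivity=2)
    counts = np.bincount(labels.ravel())[1:]
    return [float(c * edge_mm**2) for c in counts]


def class_balance(
    n_pos_train: int, n_neg_train: int, n_pos_test: int, n_neg_test: int
) -> dict:
    """Bookkeeping percentages for a labelled train/test split."""
    train_total = n_pos_train + n_neg_train
    test_total = n_pos_test + n_neg_test
    return {
        "train_total": train_total,
        "test_total": test_total,
        "grand_total": train_total + test_total,
        "train_positive_pct": 100.0 * n_pos_train / train_total,
        "test_positive_pct": 100.0 * n_pos_test / test_total,
    }
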