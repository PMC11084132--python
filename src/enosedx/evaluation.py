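"""ROC/AUC, thresholded metrics, bootstrap CIs, subgroups, and PCA.

AUC is the Mann-Whitney pairwise probability that a randomly chosen case
scores above a randomly chosen control (ties count half). Sensitivity /
specificity / accuracy are reported at a threshold chosen by maximizing
Youden's J (sensitivity + specificity - 1) on the *validation* partition
and then frozen for the test set; scores exactly at the threshold classify
positive. Confidence intervals are percentile bootstrap over class-
stratified resamples, all metrics sharing one resample stream so that a
report's point estimates and intervals are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import InvalidArgumentError

DEFAULT_B = 1000
DEFAULT_ALPHA = 0.05


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class EvalReport:
    """Diagnostic performance of one condition on one evaluation set."""

    condition: str
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    ci: dict            # metric -> (lower, upper)
    n_evaluated: int
    threshold: float
    subgroups: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_evaluated": self.n_evaluated,
            "threshold": self.threshold,
            "subgroups": {
                k: {"accuracy": v[0], "ci": list(v[1]), "n": v[2]}
                for k, v in self.subgroups.items()
            },
        }


def _validate_binary(labels, scores):
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise InvalidArgumentError("labels and scores must be equal-length 1-D")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise InvalidArgumentError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise InvalidArgumentError("both classes must be present")
    return labels, scores


def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(case score > control score) + half ties."""
    labels, scores = _validate_binary(labels, scores)
    return float(roc_auc_score(labels, scores))


def roc_points(labels, scores) -> RocCurve:
    labels, scores = _validate_binary(labels, scores)
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def youden_threshold(labels, scores) -> float:
    """Threshold (from the observed scores) maximizing sensitivity+specificity-1.

    Ties in J resolve to the highest qualifying threshold, i.e. the most
    specific operating point.
    """
    labels, scores = _validate_binary(labels, scores)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j >= best_j:
            best_j, best_t = j, t
    return float(best_t)


def classification_metrics(labels, scores, threshold) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, threshold) at a fixed threshold."""
    labels, scores = _validate_binary(labels, scores)
    pred = scores >= threshold
    tp = np.sum(pred & (labels == 1))
    fn = np.sum(~pred & (labels == 1))
    tn = np.sum(~pred & (labels == 0))
    fp = np.sum(pred & (labels == 0))
    return (
        float(tp / (tp + fn)),
        float(tn / (tn + fp)),
        float((tp + tn) / len(labels)),
        float(threshold),
    )


def _stratified_resamples(labels, B, seed):
    """Yield index arrays resampled with replacement within each class.

    The documented stream contract (relied on by the dual-implementation
    test): one ``default_rng(seed)``; per replicate, first class-0 indices
    then class-1 indices via ``rng.integers``.
    """
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    rng = np.random.default_rng(seed)
    for _ in range(B):
        r0 = idx0[rng.integers(0, len(idx0), len(idx0))]
        r1 = idx1[rng.integers(0, len(idx1), len(idx1))]
        yield np.concatenate([r0, r1])


def bootstrap_ci(metric_fn, labels, scores, B: int = DEFAULT_B,
                 alpha: float = DEFAULT_ALPHA, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for one metric of (labels, scores)."""
    if B < 1 or not (0 < alpha < 1):
        raise InvalidArgumentError("need B >= 1 and 0 < alpha < 1")
    labels, scores = _validate_binary(labels, scores)
    vals = []
    for idx in _stratified_resamples(labels, B, seed):
        try:
            vals.append(metric_fn(labels[idx], scores[idx]))
        except InvalidArgumentError:
            continue
    if not vals:
        raise InvalidArgumentError("metric undefined on every bootstrap resample")
    vals = np.asarray(vals, dtype=float)
    return (
        float(np.quantile(vals, alpha / 2)),
        float(np.quantile(vals, 1 - alpha / 2)),
    )


def evaluate_condition(
    condition: str,
    labels,
    scores,
    threshold: float,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> EvalReport:
    """Full report: AUC + thresholded metrics, all CIs from one resample set."""
    labels, scores = _validate_binary(labels, scores)
    auc = roc_auc(labels, scores)
    sens, spec, acc, thr = classification_metrics(labels, scores, threshold)
    boots = {"auc": [], "sensitivity": [], "specificity": [], "accuracy": []}
    for idx in _stratified_resamples(labels, B, seed):
        lb, sc = labels[idx], scores[idx]
        boots["auc"].append(roc_auc(lb, sc))
        s2, p2, a2, _ = classification_metrics(lb, sc, thr)
        boots["sensitivity"].append(s2)
        boots["specificity"].append(p2)
        boots["accuracy"].append(a2)
    ci = {
        m: (float(np.quantile(v, alpha / 2)), float(np.quantile(v, 1 - alpha / 2)))
        for m, v in boots.items()
    }
    return EvalReport(
        condition=condition, auc=auc, sensitivity=sens, specificity=spec,
        accuracy=acc, ci=ci, n_evaluated=len(labels), threshold=thr,
    )


def reports_to_csv(reports, path) -> None:
    """Flat CSV: one row per condition x metric, with CI bounds."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["condition", "metric", "value", "ci_lower", "ci_upper", "n"])
        for r in reports:
            for metric in ("auc", "sensitivity", "specificity", "accuracy"):
                lo, hi = r.ci[metric]
                w.writerow([r.condition, metric, getattr(r, metric), lo, hi, r.n_evaluated])


_GROUPERS = {
    "age65": lambda cov, lab: "age>=65" if (cov.get("age") or 0) >= 65 else "age<65",
    "sex": lambda cov, lab: cov.get("sex", "unknown"),
    "smoking_ever": lambda cov, lab: (
        "ever_smoker" if cov.get("smoking") in ("current", "ex") else "never_smoker"
    ),
    "label_group": lambda cov, lab: lab,
    "histology": lambda cov, lab: cov.get("histology"),
    "stage": lambda cov, lab: cov.get("stage"),
}


def subgroup_accuracy(correct, images, grouping: str, B: int = DEFAULT_B,
                      alpha: float = DEFAULT_ALPHA, seed: int = 0) -> dict:
    """Per-subgroup accuracy with a percentile bootstrap CI and count.

    ``correct`` is the per-sample 0/1 correctness indicator aligned with
    ``images``. Samples whose grouping value is missing (e.g. histology of
    a control subject) are omitted, as are empty subgroups.
    """
    if grouping not in _GROUPERS:
        raise InvalidArgumentError(f"unknown grouping {grouping!r}; choose from {sorted(_GROUPERS)}")
    correct = np.asarray(correct, dtype=float)
    fn = _GROUPERS[grouping]
    groups: dict[str, list[int]] = {}
    for i, img in enumerate(images):
        g = fn(img.covariates, img.label)
        if g is None:
            continue
        groups.setdefault(g, []).append(i)
    out = {}
    rng = np.random.default_rng(seed)
    for g in sorted(groups):
        idx = np.array(groups[g])
        acc = float(correct[idx].mean())
        boots = [
            float(correct[idx[rng.integers(0, len(idx), len(idx))]].mean())
            for _ in range(B)
        ]
        out[g] = (
            acc,
            (float(np.quantile(boots, alpha / 2)), float(np.quantile(boots, 1 - alpha / 2))),
            int(len(idx)),
        )
    return out


def pca_embed(images) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 PCA of flattened, mean-centred images.

    Returns (coordinates (n, 2), explained-variance fractions (2,)). With
    the default two-site generator the first components separate the sites,
    while cancer and control samples intermix within each site.
    """
    if len(images) < 3:
        raise InvalidArgumentError("PCA embedding needs at least 3 samples")
    X = np.stack([
        img.tensor.ravel() if hasattr(img, "tensor") else np.asarray(img).ravel()
        for img in images
    ])
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_
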