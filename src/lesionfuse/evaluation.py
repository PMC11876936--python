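"""ROC/AUC, operating-point metrics, fold summaries, subgroup reports.

AUC is the Mann–Whitney statistic (ties counted one half), computed via
scikit-learn.  Confidence intervals are stratified-bootstrap percentile
intervals (2000 resamples by default).  The operating point is the
threshold maximizing sensitivity + specificity (the Youden point),
with ties broken toward higher specificity.  Rates are reported as
percentages; a zero-denominator rate carries an explicit
undefined marker (None) rather than a NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

UNDEFINED = None

DEFAULT_STRATA = {
    "sex": ("categorical", None),
    "age": ("threshold", 70),
    "nihss": ("threshold", 4),
    "chads_vasc": ("threshold", 3),
}


@dataclass
class MetricsReport:
    auc: float
    auc_ci: tuple[float, float] | None
    cutoff: float
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    n_pos: int
    n_neg: int
    head: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CrossValSummary:
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + ½P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
           level: float = 0.95) -> tuple[float, float]:
    """Stratified bootstrap percentile interval for the AUC.

    Resampling is within-class, so every resample keeps both classes
    and the interval is a pure function of (scores, labels, seed).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        stats[b] = roc_auc_score(
            np.r_[np.ones(ps.size, dtype=int), np.zeros(ns.size, dtype=int)],
            np.r_[ps, ns])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def optimal_cutoff(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are midpoints between adjacent distinct scores plus
    sentinels below/above the range; a score >= cutoff predicts class 1.
    Ties in the objective are broken toward the larger cutoff (higher
    specificity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    candidates = np.r_[uniq[0] - 1.0, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + 1.0]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best_obj, best_cut = -np.inf, candidates[0]
    for c in candidates:
        pred = scores >= c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        obj = sens + spec
        if obj > best_obj or (obj == best_obj and c > best_cut):
            best_obj, best_cut = obj, float(c)
    return best_cut


def confusion_metrics(scores, labels, cutoff: float, head: str = "",
                      auc_value: float | None = None,
                      ci: tuple[float, float] | None = None) -> MetricsReport:
    """Threshold at ``cutoff`` (score >= cutoff -> positive) and report
    sensitivity, specificity, accuracy, PPV, NPV as percentages."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = scores >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())

    def rate(num, den):
        return 100.0 * num / den if den > 0 else UNDEFINED

    return MetricsReport(
        auc=auc_value if auc_value is not None else
        (roc_auc(scores, labels) if len(np.unique(labels)) == 2 else np.nan),
        auc_ci=ci,
        cutoff=float(cutoff),
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        accuracy=rate(tp + tn, tp + fn + tn + fp),
        ppv=rate(tp, tp + fp),
        npv=rate(tn, tn + fn),
        n_pos=tp + fn, n_neg=tn + fp, head=head,
    )


def evaluate_head(scores, labels, head: str = "", n_boot: int = 2000,
                  seed: int = 0) -> MetricsReport:
    """AUC + CI + Youden-point confusion metrics for one classifier head."""
    auc = roc_auc(scores, labels)
    ci = auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    cut = optimal_cutoff(scores, labels)
    return confusion_metrics(scores, labels, cut, head=head,
                             auc_value=auc, ci=ci)


def crossval_summary(per_fold_reports: list[MetricsReport]) -> CrossValSummary:
    """Per-metric mean and sample SD across folds (>= 2 folds)."""
    if len(per_fold_reports) < 2:
        raise ValueError("need at least 2 folds")
    out = CrossValSummary()
    for metric in ("auc", "sensitivity", "specificity", "accuracy", "ppv", "npv"):
        vals = [getattr(r, metric) for r in per_fold_reports]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=np.float64)
        out.mean[metric] = float(arr.mean())
        out.sd[metric] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return out


def _stratum_masks(metadata_rows: list[dict], strata_spec: dict):
    for key, (kind, threshold) in strata_spec.items():
        values = [row.get(key) for row in metadata_rows]
        if any(v is None for v in values):
            raise KeyError(f"metadata key missing for some studies: {key!r}")
        values = np.asarray(values)
        if kind == "categorical":
            for level in np.unique(values):
                yield f"{key}={level}", values == level
        elif kind == "threshold":
            nums = values.astype(np.float64)
            yield f"{key}<={threshold}", nums <= threshold
            yield f"{key}>{threshold}", nums > threshold
        else:
            raise ValueError(f"unknown stratum kind {kind!r}")


def subgroup_report(scores, labels, metadata_rows: list[dict],
                    strata_spec: dict | None = None, head: str = "",
                    n_boot: int = 500, seed: int = 0) -> dict[str, MetricsReport | str]:
    """Metrics within metadata-defined strata.

    Default strata: sex; age <=70 vs >70; NIHSS <=4 vs >4;
    CHA2DS2-VASc <=3 vs >3.  A stratum containing a single class (or no
    studies) is reported as the string marker ``"not-evaluable"``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    strata_spec = strata_spec or DEFAULT_STRATA
    out: dict[str, MetricsReport | str] = {}
    for name, mask in _stratum_masks(metadata_rows, strata_spec):
        if mask.sum() == 0 or len(np.unique(labels[mask])) < 2:
            out[name] = "not-evaluable"
            continue
        out[name] = evaluate_head(scores[mask], labels[mask], head=head,
                                  n_boot=n_boot, seed=seed)
    return out
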