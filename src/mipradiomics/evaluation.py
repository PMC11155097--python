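"""ROC/AUC analysis with DeLong variance, paired AUC comparison, thresholded
classification metrics, cohort summaries and the fusion-weight grid.

AUC is the Mann-Whitney statistic computed from mid-ranks (ties receive half
credit).  Confidence intervals and paired model comparisons use the DeLong
structural-component estimator of the AUC (co)variance with a normal
approximation; intervals are truncated to [0, 1].  Classification metrics use
a threshold chosen by the Youden index on a designated training score set and
carried, not re-fit, to validation sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .modeling import ScoreSet, fuse_scores

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "DeLongResult",
    "roc_auc",
    "delong_ci",
    "delong_test",
    "youden_threshold",
    "classification_metrics",
    "fusion_weight_grid",
    "cohort_prevalence",
    "FUSION_WEIGHTS",
]

FUSION_WEIGHTS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class ROCResult:
    auc: float
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ContractError("AUC must lie in [0, 1]")


@dataclass
class DeLongResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    auc_b: float | None = None
    z: float | None = None
    p_value: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ContractError("CI must bracket the AUC")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ContractError("p-value must lie in [0, 1]")


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ContractError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ContractError("both classes must be present")
    return pos, neg


def _as_arrays(scores_or_set, labels=None):
    if isinstance(scores_or_set, ScoreSet):
        return scores_or_set.scores, scores_or_set.labels
    return np.asarray(scores_or_set, dtype=float), np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels=None) -> ROCResult:
    """AUC via the mid-rank Mann-Whitney statistic plus the ROC curve points."""
    scores, labels = _as_arrays(scores, labels)
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(scores, method="average")
    r_pos = ranks[np.asarray(labels) == 1].sum()
    auc = (r_pos - m * (m + 1) / 2.0) / (m * n)

    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(labels, scores)
    return ROCResult(auc=float(auc), thresholds=thresholds, fpr=fpr, tpr=tpr, n_pos=m, n_neg=n)


# ---------------------------------------------------------------------------
# DeLong variance / test
# ---------------------------------------------------------------------------

def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    both = np.concatenate([pos, neg])
    tz = stats.rankdata(both, method="average")
    tx = stats.rankdata(pos, method="average")
    ty = stats.rankdata(neg, method="average")
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_ci(scores, labels=None, level: float = 0.95) -> DeLongResult:
    """AUC with DeLong variance and a normal-approximation CI in [0, 1]."""
    scores, labels = _as_arrays(scores, labels)
    pos, neg = _split_scores(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ContractError("need at least 2 cases per class for a variance")
    auc, v10, v01 = _delong_components(pos, neg)
    var = float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))
    if var == 0.0 and auc in (0.0, 1.0):
        logger.warning("degenerate DeLong variance; CI collapses to the point AUC")
        return DeLongResult(auc=auc, variance=0.0, ci_low=auc, ci_high=auc)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return DeLongResult(
        auc=auc,
        variance=var,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
    )


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired two-sided z-test for the AUC difference of two models."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape:
        raise ContractError("paired score sets must cover the same cases")
    pos_a, neg_a = _split_scores(scores_a, labels)
    pos_b, neg_b = _split_scores(scores_b, labels)
    auc_a, v10_a, v01_a = _delong_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _delong_components(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var_a = s10[0, 0] / m + s01[0, 0] / n

    if var_diff <= 0:
        z = 0.0
        p = 1.0 if auc_a == auc_b else 0.0
    else:
        z = float((auc_a - auc_b) / np.sqrt(var_diff))
        p = float(2.0 * stats.norm.sf(abs(z)))

    zq = stats.norm.ppf(0.975)
    half = zq * np.sqrt(max(var_a, 0.0))
    return DeLongResult(
        auc=auc_a,
        variance=float(max(var_a, 0.0)),
        ci_low=float(max(0.0, auc_a - half)),
        ci_high=float(min(1.0, auc_a + half)),
        auc_b=auc_b,
        z=z,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# thresholded metrics
# ---------------------------------------------------------------------------

def youden_threshold(scores, labels=None) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (largest on ties)."""
    scores, labels = _as_arrays(scores, labels)
    _split_scores(scores, labels)
    candidates = np.unique(scores)
    best_t, best_j = None, -np.inf
    for t in candidates:  # predictions: score >= t
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j or (j == best_j and (best_t is None or t > best_t)):
            best_j, best_t = j, t
    if best_t is None or not np.isfinite(best_t):
        raise ContractError("no finite threshold")
    return float(best_t)


def classification_metrics(scores, labels=None, threshold: float | str = "youden") -> dict[str, float]:
    """Accuracy, precision, recall/sensitivity and specificity at a threshold.

    ``threshold="youden"`` fits the Youden threshold on the given scores;
    pass a float (learned on a training set) to carry a fixed rule.
    """
    scores, labels = _as_arrays(scores, labels)
    _split_scores(scores, labels)
    t = youden_threshold(scores, labels) if threshold == "youden" else float(threshold)
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    recall = tp / (tp + fn)
    return {
        "threshold": t,
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "precision": tp / (tp + fp) if (tp + fp) else 0.0,
        "recall": recall,
        "sensitivity": recall,
        "specificity": tn / (tn + fp),
    }


# ---------------------------------------------------------------------------
# fusion grid and cohort summary
# ---------------------------------------------------------------------------

def fusion_weight_grid(cohorts: dict[str, tuple[ScoreSet, ScoreSet]]):
    """Table-style AUC (+95% CI) per fusion rule and evaluation cohort.

    ``cohorts`` maps cohort name to an aligned (tumor, vessel) ScoreSet pair.
    Rows: min, max, and weighted fusion with w in {0.1..0.9} on the tumor
    score.  Returns ``(DataFrame, best_row_label)`` where the argmax row is
    chosen by AUC in the first cohort supplied.
    """
    if not cohorts:
        raise ContractError("at least one cohort is required")
    rules: list[tuple[str, str, float | None]] = [("min", "min", None), ("max", "max", None)]
    rules += [(f"w={w:.1f}", "weighted", w) for w in FUSION_WEIGHTS]

    records = {}
    for label, method, w in rules:
        row = {}
        for cohort_name, (tumor, vessel) in cohorts.items():
            fused = fuse_scores(tumor, vessel, method=method, w=w)
            res = delong_ci(fused.scores, fused.labels)
            row[(cohort_name, "auc")] = res.auc
            row[(cohort_name, "ci_low")] = res.ci_low
            row[(cohort_name, "ci_high")] = res.ci_high
        records[label] = row
    grid = pd.DataFrame.from_dict(records, orient="index")
    grid.columns = pd.MultiIndex.from_tuples(grid.columns)
    first = next(iter(cohorts))
    best = grid[(first, "auc")].idxmax()
    return grid, str(best)


def cohort_prevalence(labels_by_cohort: dict[str, np.ndarray]) -> pd.DataFrame:
    """Positive count and percentage per cohort and pooled (1-decimal %)."""
    rows = []
    pooled = []
    for name, labels in labels_by_cohort.items():
        labels = np.asarray(labels, dtype=int)
        if labels.size == 0:
            raise ContractError(f"cohort {name!r} is empty")
        if not set(np.unique(labels)).issubset({0, 1}):
            raise ContractError("labels must be binary")
        pooled.append(labels)
        rows.append(
            {
                "cohort": name,
                "n": labels.size,
                "n_positive": int(labels.sum()),
                "prevalence_pct": round(100.0 * labels.mean(), 1),
            }
        )
    all_labels = np.concatenate(pooled)
    rows.append(
        {
            "cohort": "pooled",
            "n": all_labels.size,
            "n_positive": int(all_labels.sum()),
            "prevalence_pct": round(100.0 * all_labels.mean(), 1),
        }
    )
    return pd.DataFrame(rows).set_index("cohort")
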