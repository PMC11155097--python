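"""Feature scaling, LASSO-configured RFE selection, k-NN scoring, fusion.

The model chain follows the development procedure of the analysis: features
are min-max scaled to [0, 1] using statistics learned from the training rows
only; recursive feature elimination driven by LASSO coefficient magnitudes
reduces each feature set to ``n_target`` features; a k-NN (k = 5) scorer
assigns each case the positive fraction among its k nearest training
neighbors; and tumor/vessel score pairs are fused by minimum, maximum, or a
weighted average.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import ContractError

logger = logging.getLogger(__name__)

__all__ = [
    "ScalerParams",
    "SelectionResult",
    "KNNModel",
    "ScoreSet",
    "fit_minmax",
    "apply_minmax",
    "select_features_lasso_rfe",
    "fit_knn",
    "predict_scores",
    "fuse_scores",
    "model_bundle_to_json",
    "model_bundle_from_json",
]


@dataclass
class ScalerParams:
    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ContractError("per-feature max must be >= min")


@dataclass
class SelectionResult:
    selected: tuple[str, ...]           # surviving features, input order
    eliminated: tuple[str, ...]         # drop order (first dropped first)
    lasso_alpha: float
    n_selected: int

    def __post_init__(self):
        if self.n_selected < 1:
            raise ContractError("at least one feature must be selected")


@dataclass
class KNNModel:
    X_train: np.ndarray
    y_train: np.ndarray
    feature_names: tuple[str, ...]
    k: int = 5

    def __post_init__(self):
        self.X_train = np.asarray(self.X_train, dtype=float)
        self.y_train = np.asarray(self.y_train, dtype=int)
        if not set(np.unique(self.y_train)).issubset({0, 1}):
            raise ContractError("labels must be binary 0/1")
        if self.k > len(self.y_train):
            raise ContractError(f"k={self.k} exceeds n_train={len(self.y_train)}")
        if self.k < 1:
            raise ContractError("k must be >= 1")


@dataclass
class ScoreSet:
    case_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray
    source: str = "tumor"   # tumor | vessel | fused

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.case_ids) == len(self.scores) == len(self.labels)):
            raise ContractError("case_ids, scores and labels must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ContractError("scores must be finite")


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------

def fit_minmax(train: pd.DataFrame) -> ScalerParams:
    """Learn per-feature (min, max) from the training rows."""
    if train.empty:
        raise ContractError("training matrix is empty")
    return ScalerParams(
        feature_names=tuple(train.columns),
        mins=train.min(axis=0).to_numpy(dtype=float),
        maxs=train.max(axis=0).to_numpy(dtype=float),
    )


def apply_minmax(params: ScalerParams, X: pd.DataFrame) -> pd.DataFrame:
    """(x - min) / (max - min), clipped to [0, 1]; constant features map to 0."""
    if tuple(X.columns) != params.feature_names:
        raise ContractError("feature names differ between fit and apply")
    denom = params.maxs - params.mins
    safe = np.where(denom > 0, denom, 1.0)
    scaled = (X.to_numpy(dtype=float) - params.mins) / safe
    scaled = np.where(denom > 0, scaled, 0.0)
    return pd.DataFrame(np.clip(scaled, 0.0, 1.0), index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# LASSO-configured RFE
# ---------------------------------------------------------------------------

def select_features_lasso_rfe(
    X: pd.DataFrame,
    y: np.ndarray,
    n_target: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination with a LASSO estimator (step 1).

    The LASSO penalty is chosen once by 5-fold cross-validation on the
    training matrix, then held fixed while the feature with the smallest
    absolute coefficient is dropped until ``n_target`` remain.  If every
    coefficient is zero at some step, the feature with the weakest univariate
    association with the outcome is dropped instead (with a warning).
    """
    y = np.asarray(y, dtype=float)
    if n_target > X.shape[1]:
        raise ContractError("n_target exceeds the number of features")
    if n_target < 1:
        raise ContractError("n_target must be >= 1")
    if X.shape[0] < 10:
        raise ContractError("need at least 10 training rows")
    if len(y) != X.shape[0]:
        raise ContractError("X and y row counts differ")

    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    lasso_cv = LassoCV(cv=cv, alphas=50, max_iter=20000, random_state=seed)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-unpenalized CV candidates may stop at max_iter; the selected
        # alpha itself converges, so the candidates' warnings are noise
        warnings.simplefilter("ignore", ConvergenceWarning)
        lasso_cv.fit(X.to_numpy(dtype=float), y)
    alpha = float(lasso_cv.alpha_)

    remaining = list(X.columns)
    eliminated: list[str] = []
    Xv = X.to_numpy(dtype=float)
    col_index = {name: i for i, name in enumerate(X.columns)}
    warned_fallback = False
    while len(remaining) > n_target:
        cols = [col_index[n] for n in remaining]
        sub = Xv[:, cols]
        model = Lasso(alpha=alpha, max_iter=20000)
        with np.errstate(all="ignore"):
            model.fit(sub, y)
        coefs = np.abs(model.coef_)
        if np.all(coefs == 0):
            if not warned_fallback:
                logger.warning(
                    "all LASSO coefficients zero with %d features left; "
                    "falling back to univariate association", len(remaining)
                )
                warned_fallback = True
            yc = y - y.mean()
            xc = sub - sub.mean(axis=0)
            denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
            assoc = np.abs(np.where(denom > 0, xc.T @ yc / np.where(denom == 0, 1, denom), 0.0))
            drop_idx = int(np.argmin(assoc))
        else:
            drop_idx = int(np.argmin(coefs))
        eliminated.append(remaining.pop(drop_idx))

    return SelectionResult(
        selected=tuple(remaining),
        eliminated=tuple(eliminated),
        lasso_alpha=alpha,
        n_selected=len(remaining),
    )


# ---------------------------------------------------------------------------
# k-NN scoring
# ---------------------------------------------------------------------------

def fit_knn(X: pd.DataFrame, y: np.ndarray, k: int = 5) -> KNNModel:
    """Store the (scaled) training matrix for k-NN vote scoring."""
    return KNNModel(
        X_train=X.to_numpy(dtype=float),
        y_train=np.asarray(y, dtype=int),
        feature_names=tuple(X.columns),
        k=k,
    )


def predict_scores(model: KNNModel, X: pd.DataFrame, labels, source: str = "tumor") -> ScoreSet:
    """Score = positive fraction among the k nearest training rows.

    Euclidean distance, uniform weights; exact distance ties are broken by
    training-row order (stable argsort).
    """
    if tuple(X.columns) != model.feature_names:
        raise ContractError("feature names differ between training and prediction")
    d = cdist(X.to_numpy(dtype=float), model.X_train, metric="euclidean")
    order = np.argsort(d, axis=1, kind="stable")[:, : model.k]
    scores = model.y_train[order].mean(axis=1)
    return ScoreSet(
        case_ids=tuple(str(i) for i in X.index),
        scores=scores,
        labels=np.asarray(labels, dtype=int),
        source=source,
    )


# ---------------------------------------------------------------------------
# score fusion
# ---------------------------------------------------------------------------

def fuse_scores(
    tumor: ScoreSet,
    vessel: ScoreSet,
    method: str = "weighted",
    w: float | None = None,
) -> ScoreSet:
    """Elementwise min / max / w*tumor + (1-w)*vessel fusion."""
    if tumor.case_ids != vessel.case_ids:
        raise ContractError("tumor and vessel score sets are not aligned by case")
    if not np.array_equal(tumor.labels, vessel.labels):
        raise ContractError("tumor and vessel labels differ")
    if method == "min":
        fused = np.minimum(tumor.scores, vessel.scores)
    elif method == "max":
        fused = np.maximum(tumor.scores, vessel.scores)
    elif method == "weighted":
        if w is None or not 0.0 <= w <= 1.0:
            raise ContractError("weighted fusion needs w in [0, 1]")
        fused = w * tumor.scores + (1.0 - w) * vessel.scores
    else:
        raise ContractError(f"unknown fusion method {method!r}")
    return ScoreSet(case_ids=tumor.case_ids, scores=fused, labels=tumor.labels, source="fused")


# ---------------------------------------------------------------------------
# model bundle serialization
# ---------------------------------------------------------------------------

def model_bundle_to_json(
    scaler: ScalerParams,
    selection: SelectionResult,
    knn: KNNModel,
) -> str:
    return json.dumps(
        {
            "scaler": {
                "feature_names": list(scaler.feature_names),
                "mins": scaler.mins.tolist(),
                "maxs": scaler.maxs.tolist(),
            },
            "selection": {
                "selected": list(selection.selected),
                "eliminated": list(selection.eliminated),
                "lasso_alpha": selection.lasso_alpha,
            },
            "knn": {
                "X_train": knn.X_train.tolist(),
                "y_train": knn.y_train.tolist(),
                "feature_names": list(knn.feature_names),
                "k": knn.k,
            },
        }
    )


def model_bundle_from_json(text: str) -> tuple[ScalerParams, SelectionResult, KNNModel]:
    obj = json.loads(text)
    scaler = ScalerParams(
        feature_names=tuple(obj["scaler"]["feature_names"]),
        mins=np.array(obj["scaler"]["mins"]),
        maxs=np.array(obj["scaler"]["maxs"]),
    )
    selection = SelectionResult(
        selected=tuple(obj["selection"]["selected"]),
        eliminated=tuple(obj["selection"]["eliminated"]),
        lasso_alpha=float(obj["selection"]["lasso_alpha"]),
        n_selected=len(obj["selection"]["selected"]),
    )
    knn = KNNModel(
        X_train=np.array(obj["knn"]["X_train"]),
        y_train=np.array(obj["knn"]["y_train"]),
        feature_names=tuple(obj["knn"]["feature_names"]),
        k=int(obj["knn"]["k"]),
    )
    return scaler, selection, knn
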