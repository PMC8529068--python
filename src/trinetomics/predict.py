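"""Repeated down-sampled k-fold cross-validation and its evaluation metrics.

Classification of disease status and prediction of continuous biomarkers
both use 5-repeat 10-fold cross-validation with a random-forest default
learner.  For classification the folds are stratified and, within each
training fold only, the majority class is randomly subsampled to the
minority-class size before fitting ("down-sampling"); test folds are never
touched.  Regression accuracy is the Spearman correlation between
out-of-fold predictions and observations; classification is scored by ROC
AUC, computed by the rank (Mann–Whitney) identity AUC = U / (n1 * n0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

from .correlate import spearman
from .io import OmicsMatrix


@dataclass
class CvScheme:
    """k folds x repeats, with optional training-fold down-sampling."""

    k: int = 10
    repeats: int = 5
    downsample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CvResult:
    task: str                                  # "classification" | "regression"
    predictions: pd.DataFrame                  # repeats x samples (scores / predicted values)
    fold_assignments: pd.DataFrame             # repeats x samples (test-fold index)
    per_repeat: list[float]
    aggregate: float
    importances: pd.Series | None = None
    per_repeat_curves: list[pd.DataFrame] = field(default_factory=list)


def default_classifier(seed: int = 0, n_estimators: int = 500) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_estimators, max_features="sqrt",
                                  random_state=seed)


def default_regressor(seed: int = 0, n_estimators: int = 500) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=n_estimators, max_features=1.0 / 3.0,
                                 random_state=seed)


def spearman_accuracy(predictions, observed) -> float:
    """Spearman correlation between predicted and measured values (NaN if undefined)."""
    try:
        rho, _ = spearman(predictions, observed)
    except ValueError:
        return float("nan")
    return rho


def roc_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via the rank identity U/(n1*n0)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    classes = set(np.unique(y))
    if classes - {0.0, 1.0} or len(classes) < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    ranks = stats.rankdata(s)
    u = float(ranks[y == 1].sum() - n1 * (n1 + 1) / 2)
    return u / (n1 * n0)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """FPR/TPR points of the empirical ROC curve (thresholds descending)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    n1, n0 = y.sum(), (1 - y).sum()
    return pd.DataFrame({
        "threshold": np.r_[np.inf, s[distinct]],
        "fpr": np.r_[0.0, fps / max(n0, 1)],
        "tpr": np.r_[0.0, tps / max(n1, 1)],
    })


def _downsample_train(idx: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subsample the majority class among training indices to the minority size."""
    ones = idx[y[idx] == 1]
    zeros = idx[y[idx] == 0]
    if len(ones) == 0 or len(zeros) == 0:
        return idx
    if len(ones) > len(zeros):
        ones = rng.choice(ones, size=len(zeros), replace=False)
    elif len(zeros) > len(ones):
        zeros = rng.choice(zeros, size=len(ones), replace=False)
    return np.sort(np.concatenate([ones, zeros]))


def repeated_cv(X, y, scheme: CvScheme | None = None, learner=None,
                task: str = "auto") -> CvResult:
    """Repeated k-fold CV with out-of-fold predictions and per-repeat metrics.

    ``X`` is an :class:`OmicsMatrix` or samples x features DataFrame;
    ``learner`` any scikit-learn style estimator (cloned per fold); the
    random-forest defaults are used when omitted.  Classification folds are
    stratified and training folds down-sampled when the scheme asks for it.
    """
    scheme = scheme or CvScheme()
    if isinstance(X, OmicsMatrix):
        X = X.data
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != X.shape[0]:
        raise ValueError("X and y must align")
    if task == "auto":
        task = "classification" if set(np.unique(yv)) <= {0.0, 1.0} else "regression"

    if task == "classification":
        counts = pd.Series(yv).value_counts()
        if len(counts) < 2:
            raise ValueError("classification needs both classes present")
        if counts.min() < scheme.k:
            raise ValueError(
                f"minority class ({int(counts.min())} samples) smaller than k={scheme.k}; "
                "use fewer folds")
        learner = learner if learner is not None else default_classifier(scheme.seed)
    else:
        learner = learner if learner is not None else default_regressor(scheme.seed)

    rng = np.random.default_rng(scheme.seed)
    preds = np.full((scheme.repeats, X.shape[0]), np.nan)
    folds = np.full((scheme.repeats, X.shape[0]), -1)
    per_repeat: list[float] = []
    curves: list[pd.DataFrame] = []
    importances = np.zeros(X.shape[1])
    n_fits = 0

    for rep in range(scheme.repeats):
        rep_seed = int(rng.integers(2**31))
        if task == "classification":
            splitter = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=rep_seed)
            split_iter = splitter.split(X, yv)
        else:
            splitter = KFold(n_splits=scheme.k, shuffle=True, random_state=rep_seed)
            split_iter = splitter.split(X)
        for fold_i, (train, test) in enumerate(split_iter):
            if task == "classification" and scheme.downsample:
                train = _downsample_train(train, yv, rng)
            model = clone(learner)
            if hasattr(model, "random_state"):
                model.set_params(random_state=int(rng.integers(2**31)))
            model.fit(X.iloc[train], yv[train])
            if task == "classification":
                proba = model.predict_proba(X.iloc[test])
                pos_col = list(model.classes_).index(1.0)
                preds[rep, test] = proba[:, pos_col]
            else:
                preds[rep, test] = model.predict(X.iloc[test])
            folds[rep, test] = fold_i
            if hasattr(model, "feature_importances_"):
                importances += model.feature_importances_
                n_fits += 1
        if task == "classification":
            per_repeat.append(roc_auc(preds[rep], yv))
            curves.append(roc_curve_points(preds[rep], yv))
        else:
            per_repeat.append(spearman_accuracy(preds[rep], yv))

    imp = pd.Series(importances / n_fits, index=X.columns, name="importance") if n_fits else None
    return CvResult(
        task=task,
        predictions=pd.DataFrame(preds, columns=X.index,
                                 index=[f"rep{r + 1}" for r in range(scheme.repeats)]),
        fold_assignments=pd.DataFrame(folds, columns=X.index,
                                      index=[f"rep{r + 1}" for r in range(scheme.repeats)]),
        per_repeat=per_repeat,
        aggregate=float(np.nanmean(per_repeat)),
        importances=imp,
        per_repeat_curves=curves,
    )
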