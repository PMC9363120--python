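"""Case/control classification from signature-weight features.

A linear maximum-margin classifier (SVM) on per-sample features — either the
k signature weights or per-bin weight vectors — evaluated by repeated
stratified 10-fold cross-validation. Standardization statistics and mean
imputation of missing features are computed on each training fold only, so
no information leaks from held-out samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "standardize",
    "auc",
    "weight_only_auc",
    "repeated_cv_auc",
]


def standardize(features: np.ndarray | pd.DataFrame,
                train_statistics: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None):
    """Z-score features; statistics come from the training data only.

    Without ``train_statistics``, per-feature mean and standard deviation
    (ddof=1) are computed from ``features`` and returned for later use on a
    held-out set; zero-variance features are dropped with a warning.

    Returns
    -------
    standardized : ndarray
    statistics : (mean, sd, keep_mask)
    """
    X = np.asarray(features, dtype=float)
    if train_statistics is None:
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance features", (~keep).sum())
    else:
        mean, sd, keep = train_statistics
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return Z, (mean, sd, keep)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, scores))


def weight_only_auc(weights: np.ndarray, labels: np.ndarray) -> float:
    """Discrimination of the raw tumor-signature weight, no classifier."""
    return auc(weights, labels)


def _impute_train_means(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    X = X.copy()
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.take(means, np.nonzero(nan)[1])
    return X


def repeated_cv_auc(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    repeats: int = 50,
    cost: float = 1.0,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean AUC of a linear SVM under repeated stratified k-fold CV.

    Per repeat, the samples get a fresh stratified fold assignment; per fold,
    missing features are imputed with training-fold means, features are
    standardized on the training fold, a linear SVM (fixed cost, no inner
    tuning) is fitted, and held-out samples are scored with the decision
    function. One AUC per repeat is computed from the pooled out-of-fold
    scores.

    Returns
    -------
    mean_auc : float
    per_repeat : ndarray of length ``repeats``
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds with only {counts.min()} samples "
            "in the smaller class")
    rng = np.random.SeedSequence(seed)
    per_repeat = np.empty(repeats)
    for rep, child in enumerate(rng.spawn(repeats)):
        fold_seed = int(child.generate_state(1)[0] >> 1)
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=fold_seed)
        pooled_scores = np.empty(y.size)
        for train_idx, test_idx in splitter.split(X, y):
            X_tr, X_te = X[train_idx], X[test_idx]
            col_means = np.nanmean(X_tr, axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            X_tr = _impute_train_means(X_tr, col_means)
            X_te = _impute_train_means(X_te, col_means)
            Z_tr, stats = standardize(X_tr)
            Z_te, _ = standardize(X_te, stats)
            model = SVC(kernel="linear", C=cost)
            model.fit(Z_tr, y[train_idx])
            pooled_scores[test_idx] = model.decision_function(Z_te)
        per_repeat[rep] = auc(pooled_scores, y)
    return float(per_repeat.mean()), per_repeat
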