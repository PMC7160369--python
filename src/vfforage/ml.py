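"""Classification machinery: robust quantile scaling, RFECV feature
selection, linear SVM training, and balanced leave-one-pair-out (LOPO)
cross-validation with sensitivity / specificity / AUC metrics.

The cohort is imbalanced (fewer MCI than CI subjects).  LOPO CV handles
this by pairing one subject of each class into a test fold and, for every
fold, subsampling the remaining subjects to class balance before training;
the whole scheme is repeated with reshuffled pairings and the metrics
averaged.  MCI is the positive class throughout.

Feature scaling follows the quantile rule f(x) = (x - Q1) / (Q3 - Q1),
applied per feature with quantiles estimated on the training rows only.
Note this centers on the first quartile (so Q1 maps to 0 and Q3 to 1); a
``scaler_center='median'`` option provides the conventional robust scaler
instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFECV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .errors import UndefinedMetricError, ValidationError

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "MCI"
NEGATIVE_LABEL = "CI"


@dataclass
class FeatureMatrix:
    """Rectangular per-subject feature table with aligned group labels."""

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.data) != len(self.labels):
            raise ValidationError("labels must align with subject rows")
        self.labels = pd.Series(np.asarray(self.labels, dtype=object),
                                index=self.data.index)
        bad = set(self.labels.unique()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValidationError(f"unknown labels {sorted(bad)}")

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 = MCI (positive), 0 = CI."""
        return (self.labels == POSITIVE_LABEL).to_numpy().astype(int)

    def select(self, features: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(data=self.data[list(features)].copy(),
                             labels=self.labels.copy())


@dataclass
class ClassifierConfig:
    C: float = 10.0
    penalty: str = "l1"
    C_grid: tuple[float, ...] = (1e-10, 0.1, 1.0, 10.0)
    penalty_grid: tuple[str, ...] = ("l1", "l2")
    inner_cv_folds: int = 5
    scaler_center: str = "q1"  # q1 | median

    def __post_init__(self) -> None:
        if not self.C_grid:
            raise ValidationError("C grid must be non-empty")
        if self.penalty not in ("l1", "l2"):
            raise ValidationError(f"unknown penalty {self.penalty!r}")


@dataclass
class CVReport:
    auc: float               # percent
    sensitivity: float       # percent
    specificity: float       # percent
    selected_features: list[str]
    n_repeats: int
    seed: int

    def __post_init__(self) -> None:
        for name in ("auc", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name}={v} outside [0, 100]")


class RobustQuantileScaler:
    """Per-feature scaling x -> (x - center) / (Q3 - Q1).

    ``center='q1'`` implements the quantile rule mapping Q1 to 0 and Q3 to
    1; ``center='median'`` matches the conventional robust scaler.
    Quantiles use linear interpolation between order statistics.  A feature
    that is constant on the fitting rows (Q3 == Q1) is flagged and scaled
    to 0.
    """

    def __init__(self, center: str = "q1") -> None:
        if center not in ("q1", "median"):
            raise ValidationError(f"unknown scaler center {center!r}")
        self.center = center
        self.q1_: Optional[np.ndarray] = None
        self.q3_: Optional[np.ndarray] = None
        self.center_: Optional[np.ndarray] = None
        self.constant_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "RobustQuantileScaler":
        X = np.asarray(X, dtype=float)
        self.q1_ = np.percentile(X, 25, axis=0)
        self.q3_ = np.percentile(X, 75, axis=0)
        self.center_ = (self.q1_ if self.center == "q1"
                        else np.percentile(X, 50, axis=0))
        self.constant_ = self.q3_ == self.q1_
        if np.any(self.constant_):
            logger.debug("%d constant feature column(s) scaled to 0",
                         int(self.constant_.sum()))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.q1_ is None:
            raise ValidationError("scaler must be fitted before transform")
        X = np.asarray(X, dtype=float)
        iqr = np.where(self.constant_, 1.0, self.q3_ - self.q1_)
        out = (X - self.center_) / iqr
        out[:, self.constant_] = 0.0
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def robust_scale(m: FeatureMatrix, center: str = "q1") -> FeatureMatrix:
    """Scale a whole matrix with quantiles fitted on all of its rows."""
    scaler = RobustQuantileScaler(center=center)
    scaled = scaler.fit_transform(m.data.to_numpy(dtype=float))
    return FeatureMatrix(
        data=pd.DataFrame(scaled, index=m.data.index, columns=m.data.columns),
        labels=m.labels.copy())


def impute_median(train: np.ndarray,
                  *others: np.ndarray) -> tuple[np.ndarray, ...]:
    """Fill NaNs with the training-rows median (0 if a column is all-NaN)."""
    train = np.asarray(train, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)

    def fill(X):
        X = np.array(X, dtype=float, copy=True)
        idx = np.where(np.isnan(X))
        X[idx] = med[idx[1]]
        return X

    return tuple(fill(X) for X in (train, *others))


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve of continuous scores against binary labels.

    Equals the fraction of (positive, negative) pairs ranked concordantly,
    ties counted one half.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sensitivity_specificity(predictions, labels) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) with MCI=1 positive, CI=0 negative."""
    pred = np.asarray(predictions).astype(int)
    lab = np.asarray(labels).astype(int)
    if not (set(lab.tolist()) == {0, 1}):
        raise UndefinedMetricError(
            "sensitivity/specificity need both classes in the labels")
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    tn = int(np.sum((pred == 0) & (lab == 0)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def _make_svm(C: float, penalty: str) -> LinearSVC:
    # liblinear L1 supports squared hinge only; use it for both penalties.
    # At large C the L1 solver cycles near the optimum without meeting tol,
    # so the iteration cap is the effective stopping rule.
    return LinearSVC(C=C, penalty=penalty, loss="squared_hinge", dual=False,
                     max_iter=2000, tol=1e-4, random_state=0)


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float,
             penalty: str) -> LinearSVC:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return _make_svm(C, penalty).fit(X, y)


def grid_search_svm(m: FeatureMatrix, cfg: ClassifierConfig,
                    seed: int = 0) -> tuple[float, str]:
    """Pick (C, penalty) maximizing inner stratified k-fold AUC."""
    X, = impute_median(m.data.to_numpy(dtype=float))
    y = m.y
    cv = StratifiedKFold(n_splits=cfg.inner_cv_folds, shuffle=True,
                         random_state=seed)
    best = (-np.inf, cfg.C, cfg.penalty)
    for C in cfg.C_grid:
        for penalty in cfg.penalty_grid:
            scores = []
            for tr, te in cv.split(X, y):
                scaler = RobustQuantileScaler(cfg.scaler_center)
                Xtr = scaler.fit_transform(X[tr])
                Xte = scaler.transform(X[te])
                model = _fit_svm(Xtr, y[tr], C, penalty)
                try:
                    scores.append(auc_roc(model.decision_function(Xte), y[te]))
                except UndefinedMetricError:
                    continue
            mean = float(np.mean(scores)) if scores else -np.inf
            if mean > best[0]:
                best = (mean, C, penalty)
    return best[1], best[2]


def rfecv_select(m: FeatureMatrix, cfg: ClassifierConfig,
                 seed: int = 0) -> list[str]:
    """Recursive feature elimination with cross-validation.

    Features are dropped one at a time by smallest |coefficient| of a
    linear SVM; each subset is scored by inner stratified k-fold AUC and
    the best-scoring subset is returned (as feature names).
    """
    if m.data.shape[1] < 2:
        return m.feature_names
    if len(set(m.labels)) < 2:
        raise UndefinedMetricError("RFECV needs both classes present")
    X, = impute_median(m.data.to_numpy(dtype=float))
    X = RobustQuantileScaler(cfg.scaler_center).fit_transform(X)
    cv = StratifiedKFold(n_splits=cfg.inner_cv_folds, shuffle=True,
                         random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        selector = RFECV(_make_svm(cfg.C, cfg.penalty), step=1, cv=cv,
                         scoring="roc_auc", min_features_to_select=1)
        selector.fit(X, m.y)
    return [f for f, keep in zip(m.feature_names, selector.support_) if keep]


def iter_lopo_folds(y: np.ndarray, rng: np.random.Generator):
    """One repeat of LOPO fold construction.

    Yields ``(test_indices, train_indices)``: each test fold is one MCI/CI
    pair (pairing uniformly random), and each training fold is the
    remaining subjects subsampled so both classes have the size of the
    smaller remaining class.
    """
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("LOPO CV needs >=2 subjects in each class")
    pos = rng.permutation(pos)
    neg = rng.permutation(neg)
    n_pairs = min(pos.size, neg.size)
    for k in range(n_pairs):
        test = np.array([pos[k], neg[k]])
        pos_pool = np.delete(pos, k)
        neg_pool = np.delete(neg, k)
        n_train = min(pos_pool.size, neg_pool.size)
        train = np.concatenate([
            rng.choice(pos_pool, size=n_train, replace=False),
            rng.choice(neg_pool, size=n_train, replace=False)])
        yield test, train


def lopo_cv(m: FeatureMatrix,
            cfg: ClassifierConfig | None = None,
            n_repeats: int = 500,
            seed: int = 0,
            model: str = "svm",
            rfe: str = "none") -> CVReport:
    """Balanced leave-one-pair-out cross-validation, averaged over repeats.

    Per repeat the pairing is reshuffled; per fold the training rows are
    median-imputed, quantile-scaled (fit on the training rows), and a
    linear SVM is trained and scored on the held-out pair.  Fold scores are
    pooled within a repeat into AUC / sensitivity / specificity; reported
    metrics are means over repeats, in percent.

    ``model='chance'`` replaces the SVM with label-independent random
    scores (the chance baseline).  ``rfe`` controls where feature selection
    runs: ``'none'``, ``'global'`` (once, on the full matrix), or
    ``'per_repeat'`` (on each repeat's shuffled training pool).
    """
    cfg = cfg or ClassifierConfig()
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    if model not in ("svm", "chance"):
        raise ValidationError(f"unknown model {model!r}")
    if rfe not in ("none", "global", "per_repeat"):
        raise ValidationError(f"unknown rfe mode {rfe!r}")
    rng = np.random.default_rng(seed)
    selected = m.feature_names
    work = m
    if rfe == "global" and model == "svm":
        selected = rfecv_select(m, cfg, seed=seed)
        work = m.select(selected)

    y_all = work.y
    X_all = work.data.to_numpy(dtype=float)
    aucs, sens, specs = [], [], []
    for _ in range(n_repeats):
        if rfe == "per_repeat" and model == "svm":
            rep_seed = int(rng.integers(2**31 - 1))
            selected = rfecv_select(m, cfg, seed=rep_seed)
            X_rep = m.select(selected).data.to_numpy(dtype=float)
        else:
            X_rep = X_all
        fold_scores, fold_preds, fold_labels = [], [], []
        for test, train in iter_lopo_folds(y_all, rng):
            if model == "chance":
                scores = rng.standard_normal(test.size)
                preds = (scores > 0).astype(int)
            else:
                Xtr, Xte = impute_median(X_rep[train], X_rep[test])
                scaler = RobustQuantileScaler(cfg.scaler_center)
                Xtr = scaler.fit_transform(Xtr)
                Xte = scaler.transform(Xte)
                clf = _fit_svm(Xtr, y_all[train], cfg.C, cfg.penalty)
                scores = clf.decision_function(Xte)
                preds = (scores > 0).astype(int)
            fold_scores.extend(scores.tolist())
            fold_preds.extend(preds.tolist())
            fold_labels.extend(y_all[test].tolist())
        aucs.append(auc_roc(fold_scores, fold_labels))
        se, sp = sensitivity_specificity(fold_preds, fold_labels)
        sens.append(se)
        specs.append(sp)
    return CVReport(auc=100 * float(np.mean(aucs)),
                    sensitivity=100 * float(np.mean(sens)),
                    specificity=100 * float(np.mean(specs)),
                    selected_features=list(selected),
                    n_repeats=n_repeats, seed=seed)
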