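"""Multi-modal heterogeneous stacking ensembles (Ensemble Integration).

For each data modality (ERK features, Akt features, ...) a roster of
heterogeneous base classifiers is trained with majority-class undersampling.
Their out-of-fold probability predictions form the input of a meta-classifier
("stacker"), selected from a roster (mean aggregation, logistic regression,
random forest) by nested cross-validation on minority-class F_max.  The
fitted model stores the F_max-optimal decision threshold learned on training
data so it can be transferred to held-out sets.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``), except that ``X`` is a mapping
``modality -> FeatureMatrix`` (or 2-D array) rather than a single matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import f_max
from .transforms import FeatureMatrix


def default_base_roster() -> list[tuple[str, BaseEstimator]]:
    """Heterogeneous per-modality base-classifier roster.

    A deliberately diverse mix of linear, instance-based, margin, tree and
    probabilistic learners; every member exposes ``predict_proba`` (the SVC
    through a cross-validated sigmoid calibration wrapper).
    """
    return [
        ("lr", LogisticRegression(max_iter=2000)),
        ("knn", KNeighborsClassifier()),
        ("svc", CalibratedClassifierCV(SVC(), ensemble=False)),
        ("rf", RandomForestClassifier(n_estimators=100)),
        ("gb", GradientBoostingClassifier()),
        ("nb", GaussianNB()),
        ("dt", DecisionTreeClassifier()),
        ("ada", AdaBoostClassifier()),
    ]


def compact_base_roster() -> list[tuple[str, BaseEstimator]]:
    """Smaller roster (linear, probabilistic, tree-ensemble) for quick runs."""
    return [
        ("lr", LogisticRegression(max_iter=2000)),
        ("nb", GaussianNB()),
        ("rf", RandomForestClassifier(n_estimators=50)),
    ]


class MeanAggregator(BaseEstimator, ClassifierMixin):
    """Closed-form stacker: the positive score is the row-mean of base columns."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        p = np.mean(np.asarray(X, dtype=float), axis=1)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def default_stacker_roster() -> list[tuple[str, BaseEstimator]]:
    return [
        ("mean", MeanAggregator()),
        ("stack_lr", LogisticRegression(max_iter=2000)),
        ("stack_rf", RandomForestClassifier(n_estimators=100)),
    ]


@dataclass
class EIConfig:
    """Configuration surface for building an ensemble-integration model."""

    base_roster: list[tuple[str, BaseEstimator]] | None = None
    stacker_roster: list[tuple[str, BaseEstimator]] | None = None
    inner_folds: int = 5
    undersample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.base_roster is not None and not self.base_roster:
            raise ValueError("base_roster must be non-empty")
        if self.stacker_roster is not None and not self.stacker_roster:
            raise ValueError("stacker_roster must be non-empty")

    def to_classifier(self) -> "EnsembleIntegrationClassifier":
        return EnsembleIntegrationClassifier(
            base_roster=self.base_roster,
            stacker_roster=self.stacker_roster,
            inner_folds=self.inner_folds,
            undersample=self.undersample,
            random_state=self.seed,
        )


@dataclass
class BasePredictionMatrix:
    """Cells x (modality, base classifier) probability matrix in [0, 1]."""

    values: np.ndarray
    column_names: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("base predictions must lie in [0, 1]")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column count mismatch")


def undersample_majority(labels, seed: int) -> np.ndarray:
    """Balanced index set: all minority indices plus an equal-size seeded
    random subset of majority indices, in sorted order."""
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels != minority)
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_idx, size=min_idx.size, replace=False)
    return np.sort(np.concatenate([min_idx, keep_maj]))


def _as_array(fm) -> np.ndarray:
    return fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)


def _seeded_clone(est: BaseEstimator, seed: int) -> BaseEstimator:
    out = clone(est)
    if "random_state" in out.get_params():
        out.set_params(random_state=seed)
    return out


class EnsembleIntegrationClassifier(BaseEstimator, ClassifierMixin):
    """Heterogeneous stacking ensemble over multiple feature modalities.

    Parameters
    ----------
    base_roster, stacker_roster : list of (name, estimator) or None
        ``None`` selects the default rosters.
    inner_folds : int
        Folds for out-of-fold base predictions and stacker selection.
    undersample : bool
        Balance classes by undersampling the majority inside each training
        fold (and for the final base refits).
    random_state : int
        Seeds fold shuffling, undersampling and every roster member.

    Fitted attributes
    -----------------
    base_models_ : dict (modality, base name) -> fitted estimator
    oof_predictions_ : BasePredictionMatrix of out-of-fold base scores
    stacker_, stacker_name_ : the selected, refitted meta-model
    stacker_cv_fmax_ : dict stacker name -> inner-CV F_max used for selection
    threshold_ : F_max-optimal decision threshold on training scores
    train_f_max_ : training F_max at ``threshold_``
    """

    def __init__(
        self,
        base_roster=None,
        stacker_roster=None,
        inner_folds: int = 5,
        undersample: bool = True,
        random_state: int = 0,
    ):
        self.base_roster = base_roster
        self.stacker_roster = stacker_roster
        self.inner_folds = inner_folds
        self.undersample = undersample
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _rosters(self):
        base = self.base_roster if self.base_roster is not None else default_base_roster()
        stack = (
            self.stacker_roster
            if self.stacker_roster is not None
            else default_stacker_roster()
        )
        if not base or not stack:
            raise ValueError("rosters must be non-empty")
        return base, stack

    def _check_X(self, X) -> dict[str, np.ndarray]:
        if not isinstance(X, dict):
            X = {"data": X}
        out = {}
        for m, fm in X.items():
            if isinstance(fm, FeatureMatrix) and hasattr(self, "feature_names_"):
                if fm.feature_names != self.feature_names_[m]:
                    raise ValueError(f"modality {m}: feature names do not match fit")
            out[m] = _as_array(fm)
        if hasattr(self, "modalities_") and list(X) != self.modalities_:
            raise ValueError("modalities do not match fit")
        return out

    def _train_subset(self, labels: np.ndarray, seed: int) -> np.ndarray:
        if self.undersample:
            return undersample_majority(labels, seed)
        return np.arange(labels.size)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        base_roster, stacker_roster = self._rosters()
        if not isinstance(X, dict):
            X = {"data": X}
        self.modalities_ = list(X)
        self.feature_names_ = {
            m: (fm.feature_names if isinstance(fm, FeatureMatrix) else None)
            for m, fm in X.items()
        }
        arrays = {m: _as_array(fm) for m, fm in X.items()}
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary labels required")
        rng = np.random.default_rng(self.random_state)
        seed_oof = int(rng.integers(2**31))
        seed_refit = int(rng.integers(2**31))
        seed_sel = int(rng.integers(2**31))

        # out-of-fold base predictions (undersampling strictly inside folds)
        n = y.size
        cols = [(m, name) for m in self.modalities_ for name, _ in base_roster]
        oof = np.zeros((n, len(cols)))
        skf = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=seed_oof % 2**31
        )
        for fold_i, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
            sub = tr[self._train_subset(y[tr], seed_oof + fold_i)]
            for j, (m, name) in enumerate(cols):
                est = _seeded_clone(
                    dict(base_roster)[name], (seed_oof + 31 * j + fold_i) % 2**31
                )
                est.fit(arrays[m][sub], y[sub])
                oof[te, j] = est.predict_proba(arrays[m][te])[:, 1]
        self.oof_predictions_ = BasePredictionMatrix(values=oof, column_names=cols)

        # final base models refit on the full (undersampled) training set
        sub_full = self._train_subset(y, seed_refit)
        self.base_models_ = {}
        for j, (m, name) in enumerate(cols):
            est = _seeded_clone(dict(base_roster)[name], (seed_refit + 31 * j) % 2**31)
            est.fit(arrays[m][sub_full], y[sub_full])
            self.base_models_[(m, name)] = est

        # stacker selection by inner CV F_max on the out-of-fold matrix
        self.stacker_cv_fmax_ = {}
        sel = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=seed_sel % 2**31
        )
        splits = list(sel.split(oof, y))
        for name, est in stacker_roster:
            scores = []
            for s_i, (tr, te) in enumerate(splits):
                stk = _seeded_clone(est, (seed_sel + s_i) % 2**31)
                stk.fit(oof[tr], y[tr])
                scores.append(f_max(y[te], stk.predict_proba(oof[te])[:, 1])[0])
            self.stacker_cv_fmax_[name] = float(np.mean(scores))
        best = max(self.stacker_cv_fmax_, key=self.stacker_cv_fmax_.get)
        self.stacker_name_ = best
        self.stacker_ = _seeded_clone(dict(stacker_roster)[best], seed_sel % 2**31)
        self.stacker_.fit(oof, y)

        train_scores = self.stacker_.predict_proba(oof)[:, 1]
        self.train_f_max_, self.threshold_ = f_max(y, train_scores)
        return self

    def base_prediction_matrix(self, X) -> BasePredictionMatrix:
        """Probability columns of the final base models on new data."""
        arrays = self._check_X(X)
        cols = self.oof_predictions_.column_names
        vals = np.column_stack(
            [self.base_models_[(m, name)].predict_proba(arrays[m])[:, 1]
             for m, name in cols]
        )
        return BasePredictionMatrix(values=vals, column_names=cols)

    def decision_scores(self, X) -> np.ndarray:
        """Stacker score in [0, 1] per cell."""
        bp = self.base_prediction_matrix(X)
        return self.stacker_.predict_proba(bp.values)[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        """Binary calls at the training-derived F_max threshold."""
        return (self.decision_scores(X) >= self.threshold_).astype(int)


def fit_base_layer(features, labels, config: EIConfig):
    """Fit the per-modality base layer; returns (base_models, out-of-fold matrix)."""
    clf = config.to_classifier().fit(features, labels)
    return clf.base_models_, clf.oof_predictions_


def fit_stacker(
    base_preds: BasePredictionMatrix, labels, config: EIConfig
) -> tuple[BaseEstimator, str, float, float]:
    """Select and fit a stacker on out-of-fold base predictions.

    Returns (fitted stacker, name, training F_max, threshold).
    """
    roster = (
        config.stacker_roster
        if config.stacker_roster is not None
        else default_stacker_roster()
    )
    if not roster:
        raise ValueError("empty stacker roster")
    y = np.asarray(labels).astype(int)
    oof = base_preds.values
    sel = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                          random_state=config.seed)
    cv_fmax = {}
    splits = list(sel.split(oof, y))
    for name, est in roster:
        scores = []
        for s_i, (tr, te) in enumerate(splits):
            stk = _seeded_clone(est, (config.seed + s_i) % 2**31)
            stk.fit(oof[tr], y[tr])
            scores.append(f_max(y[te], stk.predict_proba(oof[te])[:, 1])[0])
        cv_fmax[name] = float(np.mean(scores))
    best = max(cv_fmax, key=cv_fmax.get)
    stacker = _seeded_clone(dict(roster)[best], config.seed)
    stacker.fit(oof, y)
    fmax_val, thr = f_max(y, stacker.predict_proba(oof)[:, 1])
    return stacker, best, fmax_val, thr
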