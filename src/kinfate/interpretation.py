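"""Permutation-based interpretation of ensemble-integration models.

Maps a fitted multi-modal stacking model's reliance back onto time: every
low-frequency (DWT) coefficient of every modality receives an importance in
[0, 1].  Per base classifier, importance is the mean drop in minority-class
F_max when that feature column is permuted (or neutralized), converted to
fractional ranks.  Ranks are then averaged across a modality's base
classifiers, weighted by the absolute logistic-regression stacker
coefficients of the corresponding base columns, and min-max normalized per
modality.

A complementary descriptive analysis computes, per coefficient, the absolute
difference between the class medians of the transformed courses, and the
Spearman concordance between that difference profile and the model-derived
importance profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .ensemble import EnsembleIntegrationClassifier, MeanAggregator
from .evaluation import f_max
from .preprocess import PreprocessedCohort
from .transforms import FeatureMatrix, TransformSpec, transform_cohort, coefficient_times_hours


@dataclass
class ImportanceProfile:
    """Per-(modality, coefficient) importance scores in [0, 1].

    Scores are min-max normalized within each modality; ``time_anchor`` maps
    a coefficient index to the center (hours) of its time window.
    """

    scores: dict[tuple[str, int], float]
    time_anchor: dict[int, float]
    repeats: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def modality_vector(self, modality: str) -> np.ndarray:
        idx = sorted(i for (m, i) in self.scores if m == modality)
        return np.array([self.scores[(modality, i)] for i in idx])

    def modalities(self) -> list[str]:
        return sorted({m for (m, _i) in self.scores})

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"modality": m, "index": i,
             "time_h": self.time_anchor.get(i, np.nan),
             "score": s}
            for (m, i), s in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows)


def _fm_values(features) -> np.ndarray:
    return features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)


def base_permutation_ranks(
    base_model,
    features,
    labels,
    n_repeats: int = 10,
    seed: int = 0,
    mode: str = "permute",
) -> np.ndarray:
    """Fractional feature ranks in [0, 1] from F_max drops under column shuffling.

    For each feature column, the column is permuted ``n_repeats`` times
    (``mode="permute"``) or replaced once by its mean (``mode="remove"``,
    a removal-style ablation that preserves the model's input shape); the
    mean resulting drop in F_max is recorded.  Drops are converted to
    fractional ranks scaled so the largest drop maps to 1 (ties averaged).
    A constant column yields zero drop and hence a low rank.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = _fm_values(features)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    baseline = f_max(y, base_model.predict_proba(X)[:, 1])[0]
    p = X.shape[1]
    drops = np.zeros(p)
    for j in range(p):
        if mode == "remove":
            Xp = X.copy()
            Xp[:, j] = X[:, j].mean()
            drops[j] = baseline - f_max(y, base_model.predict_proba(Xp)[:, 1])[0]
        elif mode == "permute":
            vals = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(X[:, j])
                vals.append(f_max(y, base_model.predict_proba(Xp)[:, 1])[0])
            drops[j] = baseline - float(np.mean(vals))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if p == 1:
        return np.ones(1)
    ranks = stats.rankdata(drops)  # largest drop -> rank p
    return (ranks - 1.0) / (p - 1.0)


def _stacker_weights(model: EnsembleIntegrationClassifier) -> np.ndarray:
    """Absolute per-base-column weights of a linear stacker."""
    stk = model.stacker_
    n_cols = len(model.oof_predictions_.column_names)
    if isinstance(stk, MeanAggregator):
        return np.ones(n_cols)
    if isinstance(stk, LogisticRegression) or hasattr(stk, "coef_"):
        return np.abs(np.asarray(stk.coef_).ravel())
    raise ValueError(
        f"interpretation requires a linear stacker with accessible weights; "
        f"got {type(stk).__name__}"
    )


def ei_importance(
    model: EnsembleIntegrationClassifier,
    features: dict[str, FeatureMatrix],
    labels,
    n_repeats: int = 10,
    seed: int = 0,
    mode: str = "permute",
) -> ImportanceProfile:
    """Per-(modality, coefficient) importance of a fitted stacking model.

    For each modality, the permutation ranks of that modality's base
    classifiers are averaged with weights proportional to the absolute
    stacker coefficients of the corresponding base columns, then min-max
    normalized to [0, 1] within the modality.
    """
    weights = _stacker_weights(model)
    cols = model.oof_predictions_.column_names
    y = np.asarray(labels).astype(int)
    scores: dict[tuple[str, int], float] = {}
    level = None
    for k, m in enumerate(model.modalities_):
        fm = features[m]
        col_idx = [j for j, (cm, _b) in enumerate(cols) if cm == m]
        w = weights[col_idx]
        w = np.ones_like(w) / w.size if w.sum() == 0 else w / w.sum()
        profile = np.zeros(_fm_values(fm).shape[1])
        for w_j, j in zip(w, col_idx):
            cm, bname = cols[j]
            ranks = base_permutation_ranks(
                model.base_models_[(cm, bname)], fm, y,
                n_repeats=n_repeats, seed=seed + 97 * j, mode=mode,
            )
            profile += w_j * ranks
        span = profile.max() - profile.min()
        if span > 0:
            profile = (profile - profile.min()) / span
        for i, s in enumerate(profile):
            scores[(m, i)] = float(s)
        if isinstance(fm, FeatureMatrix) and fm.feature_names:
            tag = fm.feature_names[0][1]
            if tag.startswith("dwt"):
                level = int(tag[3:])
    n_idx = max(i for (_m, i) in scores) + 1
    anchors = {}
    if level is not None:
        meta = model.__dict__.get("grid_meta_", {})
        interval = meta.get("sampling_interval", 15.0)
        t_start = meta.get("t_start", -1.0)
        times = coefficient_times_hours(n_idx, level, interval, t_start)
        anchors = {i: float(t) for i, t in enumerate(times)}
    return ImportanceProfile(
        scores=scores, time_anchor=anchors, repeats=n_repeats, seed=seed,
        metadata={"mode": mode, "stacker": model.stacker_name_},
    )


def median_class_difference(
    preprocessed: PreprocessedCohort, spec: TransformSpec | None = None
) -> dict[str, np.ndarray]:
    """|median(divided) - median(undivided)| per transformed coefficient.

    With an identity spec this is the per-time-point median C/N difference
    between the fate classes.
    """
    spec = spec or TransformSpec()
    labels = preprocessed.cohort.labels
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("both classes must be present")
    feats = transform_cohort(preprocessed, spec)
    out = {}
    for m, fm in feats.items():
        med_div = np.median(fm.values[labels == 1], axis=0)
        med_und = np.median(fm.values[labels == 0], axis=0)
        out[m] = np.abs(med_div - med_und)
    return out


def importance_concordance(
    profile: ImportanceProfile, diffs: dict[str, np.ndarray]
) -> dict[str, float]:
    """Spearman rank correlation between importance and median-difference profiles."""
    out = {}
    for m in profile.modalities():
        v = profile.modality_vector(m)
        d = np.asarray(diffs[m], dtype=float)
        if v.size != d.size:
            raise ValueError(f"modality {m}: length mismatch {v.size} vs {d.size}")
        out[m] = float(stats.spearmanr(v, d).statistic)
    return out
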