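"""Evaluation for imbalanced division-fate classification.

The primary metric is F_max: the maximum F-measure (harmonic mean of
precision and recall of the minority, divided class) over all score
thresholds.  The threshold attaining F_max on training data is *transferred*
to test data — test labels never touch threshold selection.  AUC is reported
alongside.  A stratified k-fold harness and the full transform x method x
modality comparison grid build on these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels, scores


def f_measure(labels, scores, threshold: float) -> float:
    """F-measure of the positive (divided) class at ``score >= threshold``.

    Returns 0 when no cell is predicted positive.
    """
    labels, scores = _validate(labels, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    if tp == 0:
        return 0.0
    precision = tp / int(np.sum(pred))
    recall = tp / int(np.sum(labels == 1))
    return 2 * precision * recall / (precision + recall)


def f_max(labels, scores) -> tuple[float, float]:
    """Maximum F-measure over all thresholds, and the attaining threshold.

    Candidate thresholds are the observed unique scores plus a +inf sentinel
    (the predict-nothing corner); F is piecewise constant between observed
    scores so this enumeration is exhaustive.  Ties in F are broken toward
    the lowest threshold.
    """
    labels, scores = _validate(labels, scores)
    # descending unique scores: at threshold s_k, positives are the top-k groups
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp_cum = np.cumsum(l_sorted == 1)
    pred_cum = np.arange(1, labels.size + 1)
    # last index of each tied block = counts at threshold == that score
    is_block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp_cum[is_block_end]
    npred = pred_cum[is_block_end]
    npos = int(np.sum(labels == 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(tp > 0, 2 * tp / (npred + npos), 0.0)
    thresholds = s_sorted[is_block_end]
    best = int(np.argmax(f))  # ties: argmax picks first = highest threshold
    # tie-break toward the lowest threshold among equal-F candidates
    ties = np.flatnonzero(f == f[best])
    best = int(ties[-1])  # thresholds are descending, so last tie = lowest
    return float(f[best]), float(thresholds[best])


def auc(labels, scores) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    labels, scores = _validate(labels, scores)
    return float(roc_auc_score(labels, scores))


@dataclass
class EvaluationReport:
    """Per-fold and aggregate metrics from a cross-validation run."""

    fold_f_max: list[float] = field(default_factory=list)
    fold_threshold: list[float] = field(default_factory=list)
    fold_f_transfer: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    seed: int | None = None
    k: int | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def median_f_max(self) -> float:
        return float(np.median(self.fold_f_max))

    @property
    def median_f_transfer(self) -> float:
        return float(np.median(self.fold_f_transfer))

    @property
    def median_auc(self) -> float:
        return float(np.median(self.fold_auc))

    def summary(self) -> dict[str, float]:
        q = lambda v, p: float(np.percentile(v, p))
        return {
            "median_f_max": self.median_f_max,
            "median_f_transfer": self.median_f_transfer,
            "median_auc": self.median_auc,
            "q25_f_max": q(self.fold_f_max, 25),
            "q75_f_max": q(self.fold_f_max, 75),
            "q25_auc": q(self.fold_auc, 25),
            "q75_auc": q(self.fold_auc, 75),
        }


def cross_validate(
    estimator_factory: Callable[[], Any],
    features: dict[str, "FeatureMatrix"],
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold CV with F_max threshold transfer.

    Per fold: fit the estimator (which handles undersampling internally) on
    the k-1 training folds, learn the F_max threshold from training scores,
    then report the held-out fold's F-measure at that transferred threshold,
    the held-out F_max, and the held-out AUC.
    """
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"minority class of size {counts.min()} too small for k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = EvaluationReport(seed=seed, k=k)
    X_any = next(iter(features.values()))
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        f_train = {m: _rows(fm, train_idx) for m, fm in features.items()}
        f_test = {m: _rows(fm, test_idx) for m, fm in features.items()}
        model = estimator_factory()
        model.fit(f_train, labels[train_idx])
        scores_test = model.decision_scores(f_test)
        thr = model.threshold_
        report.fold_f_max.append(f_max(labels[test_idx], scores_test)[0])
        report.fold_threshold.append(thr)
        report.fold_f_transfer.append(f_measure(labels[test_idx], scores_test, thr))
        report.fold_auc.append(auc(labels[test_idx], scores_test))
    return report


def _rows(fm, idx):
    from .transforms import FeatureMatrix

    idx = np.asarray(idx)
    return FeatureMatrix(
        values=fm.values[idx],
        feature_names=fm.feature_names,
        cell_ids=[fm.cell_ids[i] for i in idx],
    )


def comparison_grid(
    transforms: Sequence["TransformSpec"],
    methods: dict[str, Callable[[], Any]],
    preprocessed: "PreprocessedCohort",
    modality_sets: Sequence[Sequence[str]],
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial transform x method x modality-set comparison.

    Returns a tidy DataFrame with one row per combination, carrying median
    F_max / transferred F / AUC across folds.  A failing cell is recorded
    with NaN metrics and the error message rather than aborting the grid.
    """
    from .transforms import transform_cohort

    labels = preprocessed.cohort.labels
    rows = []
    for spec in transforms:
        feats_all = transform_cohort(preprocessed, spec)
        for mset in modality_sets:
            feats = {m: feats_all[m] for m in mset}
            for name, factory in methods.items():
                row = {
                    "transform": _spec_name(spec),
                    "method": name,
                    "modalities": "+".join(mset),
                }
                try:
                    rep = cross_validate(factory, feats, labels, k=k, seed=seed)
                    row.update(rep.summary())
                    row["error"] = ""
                except Exception as exc:  # noqa: BLE001 - grid must not crash
                    row.update({kk: np.nan for kk in (
                        "median_f_max", "median_f_transfer", "median_auc",
                        "q25_f_max", "q75_f_max", "q25_auc", "q75_auc")})
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def _spec_name(spec) -> str:
    if spec.kind == "dwt_approx":
        return f"dwt_l{spec.level}"
    return spec.kind
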