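# kinfate

Predicting single-cell division events from ERK and Akt kinase-activity
dynamics.

## The problem

Live-cell imaging with kinase translocation reporters tracks, for each
individual cell, the cytoplasmic-to-nuclear fluorescence ratio (C/N ratio —
a proxy for ERK or Akt activity) over two days at 15-minute intervals,
together with whether that cell eventually divides. Clonal cells under
identical treatment show heterogeneous dynamics *and* heterogeneous fates,
which raises the question: do the signaling dynamics of a single cell
predict its division fate, and if so, *when* in the time course does the
predictive information live?

Two practical obstacles make this harder than a textbook classification
problem. First, measurement stops at division, so dividing cells have
shorter series — a classifier can trivially read the fate off the series
length unless that artifact is removed. Second, the classes are imbalanced
(~25% divided), so accuracy-style metrics mislead.

`kinfate` is a tested, reusable implementation of the full analysis chain
for anyone working with labeled single-cell signaling time courses:

* **`kinfate.simulate`** — a synthetic cohort generator with the data's
  statistical structure (class imbalance, late division-time truncation,
  correlated ERK/Akt modalities with r ≈ 0.3–0.5, AR(1) noise, a
  low-frequency class effect stronger in ERK than Akt), so every stage is
  testable without downloads.
* **`kinfate.preprocess`** — the anti-artifact pipeline: truncate divided
  cells at division, truncate each undivided cell to a length drawn from
  the divided-length distribution, mean-pad everything back to the grid.
  Plus adapters for foreign cohorts: resampling to the 15-min grid,
  relabeling by division events in the last 49 h, robust affine rescaling.
* **`kinfate.transforms`** — Haar discrete-wavelet approximation cascade
  (level 3: a 197-point course → 25 coefficients ≈ 2 h apart) and DFT
  amplitudes, behind a pluggable transform interface.
* **`kinfate.ensemble`** — `EnsembleIntegrationClassifier`, a
  scikit-learn-style multi-modal stacking ensemble: per-modality
  heterogeneous base classifiers trained with majority-class undersampling,
  out-of-fold stacking, meta-classifier selected by nested CV on
  minority-class F_max, decision threshold learned on training data and
  transferred to test data.
* **`kinfate.evaluation`** — F_max, threshold-transfer F-measure, AUC
  (each verified against brute-force oracles), a stratified k-fold harness
  and a transform × method × modality comparison grid.
* **`kinfate.interpretation`** — permutation importance per DWT
  coefficient, aggregated through the absolute logistic-regression stacker
  weights and normalized to [0, 1] per modality, with a median-difference
  concordance analysis.

## The core quantities

For labels y and scores s, the primary metric is the maximum F-measure of
the minority (divided) class over all thresholds,

    F_max = max_t  2·P(t)·R(t) / (P(t) + R(t)),

with the arg-max threshold transferred unchanged from training to test
data, alongside the ROC AUC (Mann–Whitney form, ties = ½). Importance of
DWT coefficient i in modality m is the |stacker-weight|-weighted average of
per-base-classifier fractional ranks of the F_max drop under permutation of
that coefficient's column, min-max normalized within the modality.

## Worked example

```python
from sklearn.linear_model import LogisticRegression

from kinfate import (
    EnsembleIntegrationClassifier, GeneratorConfig, TransformSpec,
    cross_validate, ei_importance, generate_cohort, importance_concordance,
    median_class_difference, preprocess_cohort, transform_cohort,
)
from kinfate.ensemble import MeanAggregator, compact_base_roster

cohort = generate_cohort(GeneratorConfig(n_cells=1002, exact_counts=True, seed=0))
print(f"cohort: {cohort.n_divided} divided / {cohort.n_undivided} undivided")

pp = preprocess_cohort(cohort, seed=0)
feats = transform_cohort(pp, TransformSpec(kind="dwt_approx", level=3))

def make_model():
    return EnsembleIntegrationClassifier(
        base_roster=compact_base_roster(),
        stacker_roster=[("mean", MeanAggregator()),
                        ("stack_lr", LogisticRegression(max_iter=2000))],
        random_state=0)

report = cross_validate(make_model, feats, pp.cohort.labels, k=10, seed=0)
print(f"10-fold CV: median F_max {report.median_f_max:.3f}, "
      f"median AUC {report.median_auc:.3f}")

model = make_model().fit(feats, pp.cohort.labels)
profile = ei_importance(model, feats, pp.cohort.labels, n_repeats=5, seed=0)
rho = importance_concordance(profile, median_class_difference(pp, TransformSpec()))
print(f"Spearman(importance, median difference): "
      f"ERK {rho['ERK']:.3f}, Akt {rho['Akt']:.3f}")
```

Output:

```
cohort: 246 divided / 756 undivided
10-fold CV: median F_max 0.667, median AUC 0.860
Spearman(importance, median difference): ERK 0.262, Akt 0.358
```

Reading it: the generator produced the canonical 24.6%-divided cohort; the
multi-modal stacking ensemble separates dividing from non-dividing cells
well above chance on out-of-fold data (the exact level depends on the
generator's injected effect sizes, not on any property of real cells); and
the per-coefficient importance profile is positively rank-correlated with
the per-coefficient class median differences.

The same workflow is available from the shell:

```
kinfate run-all --seed 0 --n-cells 300 --out results/demo --roster compact
```

with per-stage subcommands `simulate`, `preprocess`, `transform`, `train`,
`evaluate`, `compare`, `interpret`.

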