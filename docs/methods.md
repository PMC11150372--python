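# Methods

## Problem setting

Live-cell imaging with kinase activity reporters produces, per tracked cell,
a time course of the cytoplasmic-to-nuclear fluorescence ratio (C/N ratio)
of one reporter per kinase "modality" (here ERK and Akt), together with a
binary fate label: did the cell divide within the observation window. The
canonical protocol emulated throughout this package is one baseline hour of
imaging before growth-factor treatment followed by 48 h of imaging at 15-min
intervals — a 197-point grid spanning t = −1 h to t = +48 h. Roughly a
quarter of cells divide; division events concentrate late in the window; a
cell's measurement stops at its division.

The package answers two questions on such data: (i) how well do the
signaling dynamics predict the division fate, once the trivial
series-length artifact is removed; (ii) *when* during the time course the
predictive information lives.

## Synthetic cohort generator

The generator (`kinfate.simulate`) produces cohorts with the statistical
structure the analysis assumes, so every downstream stage is testable
without any external data. Series are generated on the log scale and
exponentiated, guaranteeing positive C/N ratios. Per cell and modality:

    log y(t) = b + s_m(t) + 1[divided] * a_m * g(t) + e_m(t)

* `b` — per-cell baseline offset, N(0, `baseline_sd`=0.08).
* `s_m(t)` — saturating post-treatment step response
  `amp_m (1 − exp(−t/tau))` for t ≥ 0, zero during baseline;
  `erk_step`=0.30, `akt_step`=0.20, `response_tau`=1.5 h. The baseline hour
  thus sits at the pre-treatment level with noise only.
* `g(t)` — the class effect: a smooth bump built from the first three
  half-period sine harmonics (weights 0.6/0.25/0.15, peak-normalized) over
  the post-treatment window, or over an explicit `effect_window` when a
  localized signal is wanted. The effect is deliberately low-frequency so
  that it lives where level-3 wavelet approximation coefficients look.
  Amplitudes: `erk_effect`=0.15 and `akt_effect`=`erk_effect`/2 by default —
  ERK carries the stronger signal, Akt a weaker, partially redundant one.
* `e_m(t)` — AR(1) noise (stationary sd `noise_sd`=0.15, `ar_coef`=0.8).
  Each cell has a shared latent AR(1) series mixed into both modalities'
  noise with weight λ; λ is solved analytically from the target within-cell
  ERK–Akt Pearson correlation (`cross_corr`=0.4, the middle of the
  r ≈ 0.3–0.5 range typical of these reporters), accounting for the
  covariance contributed by the deterministic step responses. With the
  defaults the empirical mean per-cell correlation lands near 0.4.

Class labels are a binomial draw at `divided_fraction`=0.246 (the high-dose
class balance), or exact counts with `exact_counts`. Division times are
truncated-normal, mean 40 h, sd 3 h, bounded to 24–48 h: the published
distribution is graphical only, localized late in the 48-h window and
fairly narrow, so these stand-in parameters are deliberately exposed in
`GeneratorConfig` rather than hard-coded. Divided cells' series are
truncated at the last grid point at or before their division time.

The RPE-like variant emulates an asynchronously cycling cohort: 4-day
courses at 10-min sampling (577 points), a single ERK modality on a
different affine reporter scale (`reporter_scale`, `reporter_offset`),
possibly multiple division events per cell (Poisson with `division_rate`
expected events). Labels are *not* pre-assigned; event times live in cell
metadata so the last-window relabeling rule can derive them.

What the generator does **not** emulate: mechanistic ERK/Akt pathway
dynamics, pulsing/oscillations, mitosis-associated measurement dips,
apoptosis or other fates, batch effects, and tracking errors. Passing tests
therefore demonstrate that the pipeline recovers the kinds of class signal
it was designed for under controlled noise — not that real cohorts carry
such signal.

## Anti-artifact preprocessing

Divided cells stop being imaged at division, so raw divided series are
shorter; a classifier could read the fate off the length. The pipeline
(`kinfate.preprocess`) removes this:

1. **Truncate at division** — idempotent; the retained length is the number
   of grid points at or before the division time.
2. **Match length distributions** — every undivided cell is truncated to a
   length drawn i.i.d. (seeded, with replacement) from the empirical
   divided-length distribution. Straight i.i.d. sampling was chosen over
   quantile matching as the simplest scheme that equalizes the two
   distributions; the residual two-sample KS statistic at n of a few
   hundred cells is ≲ 0.1 and is reported in the preprocessing record.
3. **Mean-pad** — each series is extended back to the full grid with the
   mean of its own retained points (appended at the end, preserving the
   cell's mean exactly).

The package's central structural check: on a *signal-free* cohort, a
classifier given only the retained length is near-perfect (AUC > 0.9)
before step 2 and at chance (AUC ≈ 0.5) after it.

Cross-context adapters for cohorts on other grids/reporters: linear
interpolation onto the 15-min grid (no extrapolation), relabeling by
division events in the trailing 49-h window (cells whose only events
precede the window were committed to division before treatment and are
excluded), and robust affine rescaling that matches pooled median and IQR
to a reference cohort. Median/IQR matching was chosen as the most
defensible default for heavy-tailed ratio data; it is a reconstruction, not
a published procedure, and the affine parameters are recorded in
provenance.

## Feature extraction

`kinfate.transforms` implements the Haar discrete-wavelet approximation
cascade (via PyWavelets) and DFT amplitudes behind one pluggable interface.
Each cascade level convolves with the orthonormal Haar analysis filter
(1/√2, 1/√2) and downsamples by two; odd lengths are ceiling-halved under
symmetric boundary extension (the default of wavelet toolkits; the
197 → 99 → 50 → 25 length sequence pins down ceiling-halving but not the
extension values, so the mode is exposed in `TransformSpec`). At the
default level 3, a 197-point course becomes 25 coefficients, each summarizing
a 2-h window — coefficient *i* is anchored at `t_start + (i + 0.5)·2 h`.
Level 3 balances denoising against temporal resolution for ~15-min
sampling; the level is a tunable hyperparameter. MiniRocket/tsfresh-style
featurizers are supported only as `external_adapter` hooks, never
reimplemented.

## Ensemble integration

`kinfate.ensemble.EnsembleIntegrationClassifier` is a scikit-learn-style
estimator over a mapping modality → feature matrix:

1. Per modality, a heterogeneous roster of base classifiers (default:
   logistic regression, k-NN, calibrated SVC, random forest, gradient
   boosting, Gaussian naive Bayes, decision tree, AdaBoost; a compact
   3-member roster is provided for quick runs) is trained with
   majority-class undersampling applied *strictly inside* each training
   fold, producing out-of-fold probability predictions for every training
   cell via inner 5-fold CV. The exact roster used by the original study is
   not published; this default is the conventional heterogeneous-ensemble
   mix and is fully overridable.
2. The stacker is selected from {mean aggregation, logistic regression,
   random forest} by inner CV on the out-of-fold matrix, scored by
   minority-class F_max, then refit on the full matrix.
3. The decision threshold maximizing training F_max is stored in the model
   and transferred unchanged to any test data.

Determinism: one `random_state` seeds fold shuffling, undersampling, and
every roster member.

## Evaluation

F_max enumerates candidate thresholds at the observed unique scores (F is
piecewise constant between them), ties broken toward the lowest threshold;
F at a threshold predicting no positives is 0 by convention. AUC is the
Mann–Whitney probability with ties counting ½. The CV harness is
stratified k-fold (default 10); per fold the threshold is learned on the
training portion only and the held-out fold reports F at that transferred
threshold plus AUC; folds are aggregated by median with quartiles. The
comparison grid crosses transforms × methods × modality sets
({ERK}, {Akt}, {ERK, Akt}) and flags failing cells instead of aborting.

## Interpretation

For a fitted model with a *linear* stacker (non-linear stackers are
rejected explicitly): per base classifier, each feature column is permuted
(`n_repeats`=10 by default; a mean-substitution "removal" mode is provided
as a sensitivity alternative, since ablation and permutation probe the same
reliance while permutation preserves the model's input contract) and the
mean drop in F_max recorded; drops become fractional ranks in [0, 1]
(largest drop → 1). Per modality, ranks are averaged with weights
proportional to the absolute stacker coefficients of that modality's base
columns, and the profile is min-max normalized per modality so ERK and Akt
profiles share a 0–1 axis. Absolute coefficients are used because the
magnitude, not the sign, encodes the stacker's reliance on a base column.

The descriptive counterpart computes |median(divided) − median(undivided)|
per DWT coefficient, and the Spearman correlation between that difference
profile and the importance profile quantifies their concordance.

## Numerical choices and degenerate inputs

* Truncation index: `floor((t_div − t_start)/Δt + 1e−9) + 1` points; the
  epsilon guards exact grid hits.
* A constant feature column has zero permutation drop and receives the
  lowest (tied) rank; a single-feature matrix gets rank 1.
* If all stacker weights in a modality are zero they fall back to uniform.
* Degenerate importance profiles (all raw scores equal) are left
  unnormalized rather than dividing by zero.
* `undersample_majority` returns sorted indices so base fits see data in a
  stable order.
* Rescaling rejects zero-spread modalities; relabeling rejects windows
  longer than the course span; resampling refuses to extrapolate.

## Problem sizes used in tests

Unit tests run on cohorts of 30–800 cells. The signal-recovery acceptance
tests use 1000-cell cohorts over 10 generator seeds with the compact base
roster and 70/30 stratified hold-outs — large enough that the ERK-vs-Akt
ordering and the chance-level band are stable across seeds, small enough to
keep the suite quick on a laptop. The statistical claims tested (ERK
dominance in ≥8/10 seeds, multi-modal AUC within 0.02 of the best single
modality in ≥9/10, planted-window recovery in ≥8/10, mean zero-effect AUC
in [0.45, 0.55]) were piloted at these sizes before being frozen.

## Known limitations

* **Importance is suppressed late in the course.** Mean-padding makes the
  last DWT coefficients near-constant for most cells, so under a
  signal-free null those coefficients are systematically *less* important
  than earlier ones — the null importance profile is exchangeable only
  across the fully observed region (windows before the truncation bound),
  not across all 25 coefficients. Importance near the course end should be
  read with this in mind.
* **Permutation importance finds used features, not all informative ones.**
  With correlated DWT coefficients, linear base models concentrate weight
  on a few columns of an informative window; permuting the others barely
  moves F_max. The profile therefore reliably places its top coefficients
  inside a planted signal window, but does not flag *every* coefficient of
  the window.

* The generator's division-time and roster defaults are stand-ins where no
  published values exist; both are config-exposed.
* The interpretation algorithm requires a linear stacker; models selected
  with a random-forest stacker must be refit with a linear roster before
  interpretation.
* Mitosis-dip removal and any image-derived corrections are out of scope:
  the generator emits clean series, and real data must arrive already
  cleaned.
* The RPE-like generator ties the class effect to having any division
  event, not specifically to last-window events; it is intended for
  exercising the relabel/resample/rescale adapters, not for benchmarking
  classifier performance on asynchronous cohorts.
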