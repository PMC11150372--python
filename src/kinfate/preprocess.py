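"""Class-artifact-free preprocessing of kinase time courses.

Divided cells stop being imaged at division, so raw divided series are
shorter than undivided ones — a classifier could trivially read the fate off
the series length.  The pipeline here removes that artifact: divided series
are truncated at division (a no-op when the measurement already stopped
there), every undivided series is truncated to a length drawn from the
empirical divided-length distribution, and all series are padded back to the
full grid with the cell's own mean.

Cross-context adapters for asynchronously cycling cohorts on a different
grid/reporter scale (linear resampling, last-window relabeling, robust
affine rescaling) live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import CellTimeCourse, Cohort, DIVIDED, UNDIVIDED

EXCLUDED = "excluded"


@dataclass
class PreprocessedCohort:
    """A cohort with all series padded to the full grid, plus provenance.

    ``truncation_record`` maps cell_id -> number of observed points retained
    before padding; ``pad_value_record`` maps cell_id -> {modality: padding
    value} (the mean of that cell's retained points).
    """

    cohort: Cohort
    truncation_record: dict[str, int] = field(default_factory=dict)
    pad_value_record: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def grid_length(self) -> int:
        return self.cohort.grid_length

    def feature_lengths(self) -> np.ndarray:
        """Retained (pre-padding) lengths in cohort cell order."""
        return np.array(
            [self.truncation_record[c.cell_id] for c in self.cohort.cells]
        )


@dataclass
class ReferenceStats:
    """Per-modality robust location/spread of a reference cohort's pooled values."""

    median: dict[str, float]
    iqr: dict[str, float]

    def __post_init__(self) -> None:
        for m, s in self.iqr.items():
            if s <= 0:
                raise ValueError(f"modality {m}: reference spread must be > 0")

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "ReferenceStats":
        med, iqr = {}, {}
        for m in cohort.modalities:
            pooled = np.concatenate([c.series[m] for c in cohort.cells])
            med[m] = float(np.median(pooled))
            q75, q25 = np.percentile(pooled, [75, 25])
            iqr[m] = float(q75 - q25)
        return cls(median=med, iqr=iqr)


def truncate_at_division(cell: CellTimeCourse) -> CellTimeCourse:
    """Truncate a divided cell's series at the last grid point <= division time.

    Undivided (or unlabeled) cells are returned unchanged; idempotent.
    """
    if cell.label != DIVIDED:
        return cell
    step = cell.sampling_interval / 60.0
    if cell.division_time < cell.t_start + step:
        raise ValueError(
            f"cell {cell.cell_id}: division_time {cell.division_time} precedes "
            "the end of the baseline interval"
        )
    n_keep = int(math.floor((cell.division_time - cell.t_start) / step + 1e-9)) + 1
    if n_keep >= cell.length:
        return cell
    return cell.truncated(n_keep)


def match_length_distributions(cohort: Cohort, seed: int) -> Cohort:
    """Truncate undivided cells so class length distributions coincide.

    Each undivided cell is truncated to a length drawn i.i.d. (seeded, with
    replacement) from the empirical distribution of divided-cell lengths.
    Divided cells are returned unchanged.
    """
    divided_lengths = np.array(
        [c.length for c in cohort.cells if c.label == DIVIDED]
    )
    if divided_lengths.size == 0:
        raise ValueError("cannot match length distributions: no divided cells")
    rng = np.random.default_rng(seed)
    cells = []
    for cell in cohort.cells:
        if cell.label == DIVIDED:
            cells.append(cell)
        else:
            target = int(rng.choice(divided_lengths))
            cells.append(cell.truncated(min(target, cell.length)))
    return replace(cohort, cells=cells)


def pad_with_mean(cell: CellTimeCourse, target_length: int) -> CellTimeCourse:
    """Pad each modality's series to ``target_length`` with its retained mean."""
    if cell.length > target_length:
        raise ValueError(
            f"cell {cell.cell_id}: retained length {cell.length} exceeds "
            f"target {target_length}"
        )
    if cell.length == target_length:
        return cell
    series = {}
    for m, v in cell.series.items():
        pad = np.full(target_length - v.size, v.mean())
        series[m] = np.concatenate([v, pad])
    return replace(cell, series=series, metadata=dict(cell.metadata))


def preprocess_cohort(cohort: Cohort, seed: int = 0) -> PreprocessedCohort:
    """Run the full anti-artifact pipeline.

    Truncates divided cells at division, matches the undivided length
    distribution to the divided one, and mean-pads every series back to the
    cohort grid.  Fully deterministic given ``seed``.
    """
    truncated = replace(
        cohort, cells=[truncate_at_division(c) for c in cohort.cells]
    )
    matched = match_length_distributions(truncated, seed=seed)
    trunc_record = {c.cell_id: c.length for c in matched.cells}
    padded_cells, pad_record = [], {}
    for cell in matched.cells:
        pad_record[cell.cell_id] = {
            m: float(v.mean()) for m, v in cell.series.items()
        }
        padded_cells.append(pad_with_mean(cell, cohort.grid_length))
    return PreprocessedCohort(
        cohort=replace(cohort, cells=padded_cells),
        truncation_record=trunc_record,
        pad_value_record=pad_record,
    )


def length_ks_statistic(preprocessed: PreprocessedCohort) -> float:
    """Two-sample KS statistic between class retained-length distributions."""
    lengths = preprocessed.feature_lengths()
    labels = preprocessed.cohort.labels
    return float(stats.ks_2samp(lengths[labels == 1], lengths[labels == 0]).statistic)


def resample_to_grid(
    cell: CellTimeCourse, target_interval: float
) -> CellTimeCourse:
    """Linearly interpolate a series onto a coarser/finer regular grid.

    Target grid points are placed at ``t_start, t_start + dt, ...`` within the
    observed span only (no extrapolation).
    """
    if cell.length < 2:
        raise ValueError(f"cell {cell.cell_id}: need >= 2 points to interpolate")
    if target_interval <= 0:
        raise ValueError("target_interval must be positive")
    t_src = cell.times_hours()
    dt = target_interval / 60.0
    n_target = int(math.floor((t_src[-1] - t_src[0]) / dt + 1e-9)) + 1
    t_new = t_src[0] + dt * np.arange(n_target)
    series = {m: np.interp(t_new, t_src, v) for m, v in cell.series.items()}
    return replace(
        cell,
        series=series,
        sampling_interval=target_interval,
        metadata=dict(cell.metadata),
    )


def relabel_last_window(cell: CellTimeCourse, window: float) -> str:
    """Assign a fate label from division events within the trailing window.

    A cell is ``divided`` iff any event in ``metadata["division_events"]``
    falls in ``(T_end - window, T_end]`` where ``T_end`` is the last observed
    time.  Cells with events only BEFORE the window were already committed to
    division at treatment and are flagged ``excluded``.
    """
    t_end = float(cell.times_hours()[-1])
    span = t_end - cell.t_start
    if window > span + 1e-9:
        raise ValueError(f"window {window} h exceeds course span {span} h")
    events = [float(e) for e in cell.metadata.get("division_events", [])]
    in_window = [e for e in events if t_end - window < e <= t_end]
    if in_window:
        return DIVIDED
    if events:
        return EXCLUDED
    return UNDIVIDED


def relabel_cohort(cohort: Cohort, window: float) -> Cohort:
    """Apply :func:`relabel_last_window`, dropping excluded cells.

    Divided cells receive their first in-window event as ``division_time``.
    """
    cells = []
    for cell in cohort.cells:
        label = relabel_last_window(cell, window)
        if label == EXCLUDED:
            continue
        division_time = None
        if label == DIVIDED:
            t_end = float(cell.times_hours()[-1])
            division_time = min(
                e for e in cell.metadata["division_events"] if t_end - window < e
            )
        cells.append(replace(cell, label=label, division_time=division_time,
                             metadata=dict(cell.metadata)))
    return replace(cohort, cells=cells)


def rescale_to_reference(cohort: Cohort, ref: ReferenceStats) -> Cohort:
    """Affinely map each modality so pooled median/IQR match the reference.

    Robust (median/IQR) matching; the affine parameters used are recorded in
    the returned cohort's provenance.
    """
    own = ReferenceStats.from_cohort(cohort)
    params = {}
    for m in cohort.modalities:
        if own.iqr[m] <= 0:
            raise ValueError(f"modality {m}: cohort spread is zero, cannot rescale")
        scale = ref.iqr[m] / own.iqr[m]
        offset = ref.median[m] - scale * own.median[m]
        params[m] = (scale, offset)
    cells = [
        replace(
            c,
            series={m: params[m][0] * v + params[m][1] for m, v in c.series.items()},
            metadata=dict(c.metadata),
        )
        for c in cohort.cells
    ]
    provenance = dict(cohort.provenance)
    provenance["rescale_params"] = {m: list(p) for m, p in params.items()}
    return replace(cohort, cells=cells, provenance=provenance)
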