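"""Synthetic single-cell kinase-activity cohort generator.

Emulates the statistical structure of growth-factor-stimulation imaging
screens: cells are serum-starved, imaged for one baseline hour, treated at
t=0, then imaged at a fixed interval for 48 h.  Each cell carries one
C/N-ratio series per modality (ERK, Akt).  Cells that divide stop being
imaged at division, so their series are truncated; division times concentrate
late in the 48-h window.  The two modalities are somewhat correlated within a
cell (target r ~ 0.3-0.5), and the class signal — what separates dividing
from non-dividing cells — is a smooth low-frequency trend spread across the
time course, stronger in ERK than in Akt.

Series are generated on the log scale and exponentiated, so C/N ratios are
strictly positive.  The log-scale model per cell and modality is

    log y(t) = b + s_m(t) + 1[divided] * a_m * g(t) + e_m(t)

with ``b`` a per-cell baseline offset, ``s_m`` a saturating post-treatment
step response, ``g`` a smooth bump built from the first three half-period
sine harmonics over the effect window, and ``e_m`` AR(1) noise sharing a
latent component across modalities.  The latent mixing weight is solved
analytically so that the expected within-cell Pearson correlation between
the two modalities' series equals ``cross_corr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import CellTimeCourse, Cohort, DIVIDED, UNDIVIDED

# first three half-period sine harmonics; weights sum to 1 before peak-normalization
_EFFECT_HARMONIC_WEIGHTS = (0.6, 0.25, 0.15)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the canonical high-dose protocol: 1 h baseline plus
    48 h post-treatment at 15-min intervals (197-point grid), 24.6% of cells
    dividing, division times concentrated around 40 h within a 24-48 h
    window.
    """

    n_cells: int = 1002
    divided_fraction: float = 0.246
    sampling_interval: float = 15.0  # minutes
    duration: float = 49.0  # hours; first `baseline_hours` are pre-treatment
    baseline_hours: float = 1.0
    erk_effect: float = 0.15  # log-scale amplitude of the class trend in ERK
    akt_effect: float | None = None  # default: erk_effect / 2
    effect_window: tuple[float, float] | None = None  # hours post-treatment
    cross_corr: float = 0.4
    noise_sd: float = 0.15  # stationary log-scale AR(1) sd
    ar_coef: float = 0.8
    baseline_sd: float = 0.08  # per-cell log baseline offset
    erk_step: float = 0.30  # post-treatment step-response amplitude (log scale)
    akt_step: float = 0.20
    response_tau: float = 1.5  # hours
    division_time_mean: float = 40.0  # hours post-treatment
    division_time_sd: float = 3.0
    division_window: tuple[float, float] = (24.0, 48.0)
    exact_counts: bool = False
    # RPE-like extras
    reporter_scale: float = 1.0
    reporter_offset: float = 0.0
    division_rate: float = 1.0  # expected division events per course (RPE-like)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.divided_fraction < 1.0:
            raise ValueError("divided_fraction must lie in (0, 1)")
        n_intervals = self.duration * 60.0 / self.sampling_interval
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise ValueError(
                "duration/sampling_interval must yield an integer number of intervals"
            )
        post = self.duration - self.baseline_hours
        lo, hi = self.division_window
        if not (0.0 <= lo < hi <= post):
            raise ValueError(
                f"division_window {self.division_window} must lie within [0, {post}] h"
            )
        if not 0.0 <= self.cross_corr <= 1.0:
            raise ValueError("cross_corr must lie in [0, 1]")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.akt_effect is None:
            self.akt_effect = self.erk_effect / 2.0

    @property
    def grid_length(self) -> int:
        return int(round(self.duration * 60.0 / self.sampling_interval)) + 1

    @property
    def t_start(self) -> float:
        return -self.baseline_hours

    def times_hours(self) -> np.ndarray:
        step = self.sampling_interval / 60.0
        return self.t_start + step * np.arange(self.grid_length)


def _effect_shape(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Smooth low-frequency bump, peak-normalized to max 1, zero outside window."""
    lo, hi = window
    u = np.clip((t - lo) / (hi - lo), 0.0, 1.0)
    shape = sum(
        w * np.sin((k + 1) * np.pi * u)
        for k, w in enumerate(_EFFECT_HARMONIC_WEIGHTS)
    )
    shape = np.where((t >= lo) & (t <= hi), shape, 0.0)
    peak = np.max(np.abs(shape))
    return shape / peak if peak > 0 else shape


def _step_response(t: np.ndarray, amplitude: float, tau: float) -> np.ndarray:
    """Saturating post-treatment response; zero during baseline."""
    return np.where(t >= 0.0, amplitude * (1.0 - np.exp(-np.maximum(t, 0.0) / tau)), 0.0)


def _solve_latent_weight(config: GeneratorConfig, t: np.ndarray) -> float:
    """Mixing weight of the shared latent noise series.

    Solves  r = (C_trend + lam * sd^2) / sqrt((V_e + sd^2)(V_a + sd^2))
    for lam, where V/C are the temporal (co)variances of the deterministic
    step responses over the grid.  Clipped to [0, 1].
    """
    s_e = _step_response(t, config.erk_step, config.response_tau)
    s_a = _step_response(t, config.akt_step, config.response_tau)
    v_e = float(np.var(s_e))
    v_a = float(np.var(s_a))
    c_ea = float(np.mean((s_e - s_e.mean()) * (s_a - s_a.mean())))
    sd2 = config.noise_sd**2
    if sd2 == 0.0:
        return 0.0
    lam = (config.cross_corr * math.sqrt((v_e + sd2) * (v_a + sd2)) - c_ea) / sd2
    return float(np.clip(lam, 0.0, 1.0))


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _draw_division_times(
    rng: np.random.Generator, n: int, config: GeneratorConfig
) -> np.ndarray:
    lo, hi = config.division_window
    a = (lo - config.division_time_mean) / config.division_time_sd
    b = (hi - config.division_time_mean) / config.division_time_sd
    return stats.truncnorm.rvs(
        a, b, loc=config.division_time_mean, scale=config.division_time_sd,
        size=n, random_state=rng,
    )


def _n_divided(rng: np.random.Generator, config: GeneratorConfig) -> int:
    if config.exact_counts:
        return int(round(config.n_cells * config.divided_fraction))
    return int(rng.binomial(config.n_cells, config.divided_fraction))


def _truncation_points(division_time: float, config: GeneratorConfig) -> int:
    """Number of grid points retained up to (and including) division."""
    step = config.sampling_interval / 60.0
    return int(math.floor((division_time - config.t_start) / step + 1e-9)) + 1


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a labeled two-modality (ERK, Akt) cohort.

    Divided cells are truncated at their sampled division time (truncated
    normal within ``division_window``); undivided cells span the full grid.
    Identical config and seed reproduce the cohort element-wise.
    """
    rng = np.random.default_rng(config.seed)
    t = config.times_hours()
    post_end = config.duration - config.baseline_hours
    window = config.effect_window or (0.0, post_end)
    shape = _effect_shape(t, window)
    steps = {
        "ERK": _step_response(t, config.erk_step, config.response_tau),
        "Akt": _step_response(t, config.akt_step, config.response_tau),
    }
    effects = {"ERK": config.erk_effect, "Akt": config.akt_effect}
    lam = _solve_latent_weight(config, t)

    n_div = _n_divided(rng, config)
    division_times = _draw_division_times(rng, n_div, config)
    labels = [DIVIDED] * n_div + [UNDIVIDED] * (config.n_cells - n_div)

    cells = []
    for i, label in enumerate(labels):
        b = rng.normal(0.0, config.baseline_sd)
        shared = _ar1(rng, config.grid_length, config.ar_coef, config.noise_sd)
        series = {}
        for mod in ("ERK", "Akt"):
            own = _ar1(rng, config.grid_length, config.ar_coef, config.noise_sd)
            noise = math.sqrt(lam) * shared + math.sqrt(1.0 - lam) * own
            log_y = b + steps[mod] + noise
            if label == DIVIDED:
                log_y = log_y + effects[mod] * shape
            series[mod] = np.exp(log_y)
        division_time = None
        if label == DIVIDED:
            division_time = float(division_times[i])
            n_keep = _truncation_points(division_time, config)
            series = {m: v[:n_keep] for m, v in series.items()}
        cells.append(
            CellTimeCourse(
                cell_id=f"cell{i:05d}",
                series=series,
                sampling_interval=config.sampling_interval,
                t_start=config.t_start,
                label=label,
                division_time=division_time,
            )
        )

    return Cohort(
        cells=cells,
        modalities=["ERK", "Akt"],
        grid_length=config.grid_length,
        sampling_interval=config.sampling_interval,
        t_start=config.t_start,
        provenance={"generator": "generate_cohort", "config": asdict(config)},
    )


def generate_rpe_like(config: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Generate an RPE-style single-modality (ERK) cohort.

    Emulates asynchronously cycling cells imaged over ~4 days at 10-min
    intervals with a FRET reporter on a different affine scale: cells can
    divide multiple times, series are full-length (not truncated), labels are
    NOT pre-assigned — division event times are stored in each cell's
    ``metadata["division_events"]`` so that
    :func:`kinfate.preprocess.relabel_last_window` can derive them.
    """
    if config is None:
        defaults = dict(
            n_cells=225, sampling_interval=10.0, duration=96.0, baseline_hours=0.0,
            division_window=(0.0, 96.0), division_time_mean=48.0, division_time_sd=24.0,
        )
        defaults.update(overrides)
        config = GeneratorConfig(**defaults)
    rng = np.random.default_rng(config.seed)
    t = config.times_hours()
    step = _step_response(t, config.erk_step, config.response_tau)
    post_end = config.duration - config.baseline_hours
    window = config.effect_window or (0.0, post_end)
    shape = _effect_shape(t, window)

    cells = []
    for i in range(config.n_cells):
        n_events = rng.poisson(config.division_rate)
        events = np.sort(rng.uniform(0.0, post_end, size=n_events))
        b = rng.normal(0.0, config.baseline_sd)
        noise = _ar1(rng, config.grid_length, config.ar_coef, config.noise_sd)
        log_y = b + step + noise
        if n_events > 0:
            log_y = log_y + config.erk_effect * shape
        y = config.reporter_scale * np.exp(log_y) + config.reporter_offset
        if np.any(y <= 0):
            raise ValueError("reporter_scale/offset produced non-positive C/N values")
        cells.append(
            CellTimeCourse(
                cell_id=f"rpe{i:05d}",
                series={"ERK": y},
                sampling_interval=config.sampling_interval,
                t_start=config.t_start,
                label=None,
                metadata={"division_events": [float(e) for e in events]},
            )
        )
    return Cohort(
        cells=cells,
        modalities=["ERK"],
        grid_length=config.grid_length,
        sampling_interval=config.sampling_interval,
        t_start=config.t_start,
        provenance={"generator": "generate_rpe_like", "config": asdict(config)},
    )
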