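"""Low-frequency feature extraction from padded time courses.

The workhorse is the Haar discrete-wavelet-transform approximation cascade:
each level convolves with the orthonormal Haar analysis filter (1/sqrt(2),
1/sqrt(2)) and downsamples by two (ceiling-halving, with boundary extension
for odd lengths), keeping only the approximation branch.  At level 3 a
197-point course sampled every 15 min becomes 25 coefficients spaced roughly
2 h apart — a denoised, low-dimensional representation of the overall
activity trend.  DFT amplitudes of the non-redundant half-spectrum are
provided as an alternative, and arbitrary external featurizers can be
plugged in through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import PreprocessedCohort


@dataclass
class TransformSpec:
    """Specification of a time-course featurizer.

    ``kind`` is one of ``dwt_approx`` (Haar approximation cascade, default
    level 3), ``dft_amplitude``, ``identity`` (raw padded series), or
    ``external_adapter`` (a user-supplied callable mapping a cells x time
    array to a cells x features array, e.g. MiniRocket or tsfresh).
    """

    kind: str = "dwt_approx"
    level: int = 3
    wavelet: str = "haar"
    boundary: str = "symmetric"
    adapter: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        valid = {"dwt_approx", "dft_amplitude", "identity", "external_adapter"}
        if self.kind not in valid:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "dwt_approx" and self.level < 1:
            raise ValueError("dwt_approx requires level >= 1")
        if self.kind == "external_adapter" and self.adapter is None:
            raise ValueError("external_adapter requires an adapter callable")


@dataclass
class FeatureMatrix:
    """Cells x features matrix for one modality with interpretable names.

    ``feature_names`` are (modality, transform, index) triples so downstream
    interpretation can map coefficients back to time windows.
    """

    values: np.ndarray
    feature_names: list[tuple[str, str, int]]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x features)")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("row count must equal number of cell_ids")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal number of feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def haar_dwt_approx(
    series: np.ndarray, level: int = 3, boundary: str = "symmetric",
    wavelet: str = "haar",
) -> np.ndarray:
    """Approximation coefficients of a ``level``-step Haar wavelet cascade.

    Each step halves the length (ceiling, with boundary extension for odd
    lengths) using the orthonormal analysis filters, so a constant series of
    value ``c`` and dyadic length ``2^level`` reduces to the single
    coefficient ``c * 2^(level/2)``.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2**level and boundary == "zero":
        raise ValueError(f"series of length {series.size} too short for level {level}")
    out = series
    for _ in range(level):
        if out.size < 2:
            raise ValueError("series too short for requested level")
        out, _detail = pywt.dwt(out, wavelet, mode=boundary)
    return out


def dft_amplitude(series: np.ndarray) -> np.ndarray:
    """Moduli of the non-redundant half-spectrum DFT coefficients (0..n//2)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return np.abs(np.fft.rfft(series))


class HaarApproxTransform(BaseEstimator, TransformerMixin):
    """Row-wise Haar approximation cascade as an sklearn transformer."""

    def __init__(self, level: int = 3, boundary: str = "symmetric",
                 wavelet: str = "haar"):
        self.level = level
        self.boundary = boundary
        self.wavelet = wavelet

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.n_features_out_ = haar_dwt_approx(
            X[0], self.level, self.boundary, self.wavelet
        ).size
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.vstack(
            [haar_dwt_approx(row, self.level, self.boundary, self.wavelet)
             for row in X]
        )


class DFTAmplitudeTransform(BaseEstimator, TransformerMixin):
    """Row-wise DFT amplitude spectrum as an sklearn transformer."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.n_features_out_ = X.shape[1] // 2 + 1
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.vstack([dft_amplitude(row) for row in X])


def _tag(spec: TransformSpec) -> str:
    if spec.kind == "dwt_approx":
        return f"dwt{spec.level}"
    return {"dft_amplitude": "dft", "identity": "raw",
            "external_adapter": "ext"}[spec.kind]


def _apply_spec(X: np.ndarray, spec: TransformSpec) -> np.ndarray:
    if spec.kind == "dwt_approx":
        return HaarApproxTransform(spec.level, spec.boundary, spec.wavelet).fit(X).transform(X)
    if spec.kind == "dft_amplitude":
        return DFTAmplitudeTransform().fit(X).transform(X)
    if spec.kind == "identity":
        return X.copy()
    return np.asarray(spec.adapter(X), dtype=float)


def transform_cohort(
    preprocessed: PreprocessedCohort, spec: TransformSpec
) -> dict[str, FeatureMatrix]:
    """Featurize every modality of a padded cohort.

    Returns one :class:`FeatureMatrix` per modality; feature names carry
    (modality, transform-tag, coefficient index) so that a level-``L`` DWT
    coefficient ``i`` can be anchored at time
    ``t_start + (i + 0.5) * interval * 2**L / 60`` hours.
    """
    cohort = preprocessed.cohort
    out = {}
    for m in cohort.modalities:
        X = np.vstack([c.series[m] for c in cohort.cells])
        if X.shape[1] != cohort.grid_length:
            raise ValueError("cohort series not padded to grid_length")
        if not np.all(np.isfinite(X)):
            raise ValueError(f"modality {m}: non-finite input values")
        F = _apply_spec(X, spec)
        names = [(m, _tag(spec), j) for j in range(F.shape[1])]
        out[m] = FeatureMatrix(values=F, feature_names=names,
                               cell_ids=cohort.cell_ids)
    return out


def coefficient_times_hours(
    n_coeffs: int, level: int, sampling_interval: float, t_start: float
) -> np.ndarray:
    """Centers (hours) of the time windows covered by DWT approximation coefficients."""
    width_h = sampling_interval * 2**level / 60.0
    return t_start + (np.arange(n_coeffs) + 0.5) * width_h
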