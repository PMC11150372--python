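"""In-memory containers for single-cell kinase-activity time courses.

A :class:`CellTimeCourse` holds one cell's C/N-ratio series per modality
(e.g. ``"ERK"``, ``"Akt"``) on a regular sampling grid, its fate label and,
for divided cells, the division time.  A :class:`Cohort` is an ordered set of
cells sharing grid conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

DIVIDED = "divided"
UNDIVIDED = "undivided"
VALID_LABELS = (DIVIDED, UNDIVIDED)


@dataclass
class CellTimeCourse:
    """One cell's per-modality activity series on a regular time grid.

    Parameters
    ----------
    cell_id : str
        Unique identifier within a cohort.
    series : dict[str, np.ndarray]
        Modality name -> ordered positive C/N-ratio values.  All modalities
        must have equal length; divided cells' series end at the grid point
        at/just before ``division_time``.
    sampling_interval : float
        Minutes between consecutive grid points.
    t_start : float
        Time (hours) of the first grid point; -1.0 for the canonical protocol
        with one baseline hour before growth-factor treatment at t=0.
    label : str or None
        ``"divided"`` / ``"undivided"``; ``None`` when fate has not been
        assigned yet (e.g. RPE-like cohorts before window relabeling).
    division_time : float or None
        Hours; required when label is ``"divided"``.
    metadata : dict
        Free-form (condition, replicate, division_events, ...).
    """

    cell_id: str
    series: dict[str, np.ndarray]
    sampling_interval: float
    t_start: float = -1.0
    label: str | None = None
    division_time: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.series = {m: np.asarray(v, dtype=float) for m, v in self.series.items()}
        lengths = {v.size for v in self.series.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"cell {self.cell_id}: modalities have unequal lengths {lengths}"
            )
        for m, v in self.series.items():
            if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
                raise ValueError(
                    f"cell {self.cell_id}, modality {m}: values must be finite and > 0"
                )
        if self.label == DIVIDED and self.division_time is None:
            raise ValueError(f"cell {self.cell_id}: divided cell lacks division_time")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"cell {self.cell_id}: invalid label {self.label!r}")

    @property
    def length(self) -> int:
        """Number of observed grid points (equal across modalities)."""
        return next(iter(self.series.values())).size

    @property
    def modalities(self) -> list[str]:
        return list(self.series)

    def times_hours(self) -> np.ndarray:
        """Hour stamps of the observed grid points."""
        step = self.sampling_interval / 60.0
        return self.t_start + step * np.arange(self.length)

    def truncated(self, n_points: int) -> "CellTimeCourse":
        """Copy retaining only the first ``n_points`` grid points."""
        if n_points > self.length:
            raise ValueError(
                f"cannot truncate cell {self.cell_id} of length {self.length} "
                f"to {n_points} points"
            )
        return replace(
            self,
            series={m: v[:n_points].copy() for m, v in self.series.items()},
            metadata=dict(self.metadata),
        )


@dataclass
class Cohort:
    """An ordered collection of cells sharing grid conventions."""

    cells: list[CellTimeCourse]
    modalities: list[str]
    grid_length: int
    sampling_interval: float
    t_start: float = -1.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.cells:
            if c.modalities != self.modalities:
                raise ValueError(
                    f"cell {c.cell_id} modalities {c.modalities} != cohort "
                    f"{self.modalities}"
                )
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell_ids in cohort")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    @property
    def labels(self) -> np.ndarray:
        """Binary label vector: 1 = divided (minority/positive class)."""
        return np.array([1 if c.label == DIVIDED else 0 for c in self.cells])

    @property
    def n_divided(self) -> int:
        return sum(1 for c in self.cells if c.label == DIVIDED)

    @property
    def n_undivided(self) -> int:
        return sum(1 for c in self.cells if c.label == UNDIVIDED)

    def subset(self, indices) -> "Cohort":
        return replace(self, cells=[self.cells[i] for i in indices])

    def grid_times_hours(self) -> np.ndarray:
        step = self.sampling_interval / 60.0
        return self.t_start + step * np.arange(self.grid_length)
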