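"""Readers and writers for cohorts, features, configs and reports.

Cohorts are exchanged in plain-text formats:

* one *wide* CSV per modality — rows are cells, columns are grid time points
  (hour-stamped headers); grid points past a cell's truncation are empty,
* a *labels* CSV (``cell_id,label,division_time_h``),
* an equivalent *long* TSV (``cell_id,modality,time_h,value``).

Every written artifact carries provenance: wide/labels CSVs start with
``# key: value`` comment lines recording the generator seed and config hash,
and JSON reports embed the same fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cohort import CellTimeCourse, Cohort, VALID_LABELS
from .transforms import FeatureMatrix

_TIME_FMT = "t{:+.4f}h"


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance_lines(cohort: Cohort) -> list[str]:
    prov = cohort.provenance or {}
    cfg = prov.get("config", {})
    lines = [
        f"# generator: {prov.get('generator', 'unknown')}",
        f"# seed: {cfg.get('seed', 'unknown')}",
        f"# config_hash: {config_hash(cfg)}",
    ]
    return lines


def write_cohort(cohort: Cohort, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
    """Write wide CSVs (one per modality), a labels CSV and a long TSV.

    Returns the mapping of artifact name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    times = cohort.grid_times_hours()
    cols = [_TIME_FMT.format(t) for t in times]
    paths: dict[str, Path] = {}
    header = "\n".join(_provenance_lines(cohort)) + "\n"

    for m in cohort.modalities:
        rows = []
        for c in cohort.cells:
            v = np.full(cohort.grid_length, np.nan)
            v[: c.length] = c.series[m]
            rows.append(v)
        df = pd.DataFrame(rows, index=cohort.cell_ids, columns=cols)
        df.index.name = "cell_id"
        p = outdir / f"{prefix}_{m}.csv"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh)
        paths[f"wide_{m}"] = p

    labels = pd.DataFrame(
        {
            "cell_id": cohort.cell_ids,
            "label": [c.label if c.label is not None else "" for c in cohort.cells],
            "division_time_h": [
                c.division_time if c.division_time is not None else ""
                for c in cohort.cells
            ],
            "division_events": [
                ";".join(f"{e:g}" for e in c.metadata.get("division_events", []))
                for c in cohort.cells
            ],
        }
    )
    p = outdir / f"{prefix}_labels.csv"
    with open(p, "w") as fh:
        fh.write(header)
        labels.to_csv(fh, index=False)
    paths["labels"] = p

    long_rows = []
    for c in cohort.cells:
        t = c.times_hours()
        for m in cohort.modalities:
            for ti, vi in zip(t, c.series[m]):
                long_rows.append((c.cell_id, m, ti, vi))
    long_df = pd.DataFrame(long_rows, columns=["cell_id", "modality", "time_h", "value"])
    p = outdir / f"{prefix}_long.tsv"
    long_df.to_csv(p, sep="\t", index=False)
    paths["long"] = p
    return paths


def _check_regular(times: np.ndarray, context: str) -> float:
    steps = np.diff(times)
    if steps.size == 0:
        raise ValueError(f"{context}: single time point")
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError(f"{context}: irregular time grid")
    return float(steps[0])


def read_cohort_wide(
    modality_paths: dict[str, str | Path], labels_path: str | Path
) -> Cohort:
    """Read a cohort from per-modality wide CSVs plus a labels CSV.

    Validates grid regularity, duplicate ids, label vocabulary and rejects
    NaNs occurring mid-series (only trailing NaNs — truncation — are legal),
    reporting the offending cell and position.
    """
    labels_df = pd.read_csv(labels_path, comment="#", dtype={"cell_id": str})
    if labels_df["cell_id"].duplicated().any():
        dup = labels_df["cell_id"][labels_df["cell_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate cell_id {dup!r} in labels file")
    label_map, dt_map, ev_map = {}, {}, {}
    for i, row in labels_df.iterrows():
        lab = row.get("label")
        lab = None if pd.isna(lab) or lab == "" else str(lab)
        if lab is not None and lab not in VALID_LABELS:
            raise ValueError(f"labels row {i}: invalid label {lab!r}")
        label_map[row["cell_id"]] = lab
        dt = row.get("division_time_h")
        dt_map[row["cell_id"]] = None if pd.isna(dt) or dt == "" else float(dt)
        ev = row.get("division_events")
        ev_map[row["cell_id"]] = (
            [float(x) for x in str(ev).split(";") if x]
            if isinstance(ev, str) and ev else []
        )

    frames = {}
    times = None
    for m, p in modality_paths.items():
        df = pd.read_csv(p, comment="#", index_col="cell_id")
        t = np.array([float(c[1:-1]) for c in df.columns])
        step = _check_regular(t, f"modality {m}")
        if times is None:
            times, interval = t, step * 60.0
        elif not np.allclose(t, times, atol=1e-6):
            raise ValueError(f"modality {m}: grid differs from other modalities")
        if df.index.duplicated().any():
            raise ValueError(f"modality {m}: duplicate cell_ids")
        frames[m] = df

    modalities = list(modality_paths)
    cell_ids = list(frames[modalities[0]].index)
    cells = []
    for cid in cell_ids:
        series = {}
        n_keep = None
        for m in modalities:
            v = frames[m].loc[cid].to_numpy(dtype=float)
            finite = np.isfinite(v)
            n_obs = int(finite.sum())
            if not finite[:n_obs].all():
                bad = int(np.flatnonzero(~finite)[0])
                raise ValueError(
                    f"cell {cid}, modality {m}: non-finite value mid-series "
                    f"at column {bad} (t={times[bad]:+.2f} h)"
                )
            if n_keep is None:
                n_keep = n_obs
            elif n_obs != n_keep:
                raise ValueError(f"cell {cid}: modalities have unequal lengths")
            series[m] = v[:n_obs]
        meta = {}
        if ev_map.get(cid):
            meta["division_events"] = ev_map[cid]
        cells.append(
            CellTimeCourse(
                cell_id=str(cid),
                series=series,
                sampling_interval=interval,
                t_start=float(times[0]),
                label=label_map.get(cid),
                division_time=dt_map.get(cid),
                metadata=meta,
            )
        )
    return Cohort(
        cells=cells,
        modalities=modalities,
        grid_length=len(times),
        sampling_interval=interval,
        t_start=float(times[0]),
        provenance={"source": {m: str(p) for m, p in modality_paths.items()}},
    )


def read_cohort_long(long_path: str | Path, labels_path: str | Path) -> Cohort:
    """Read a cohort from a long TSV plus a labels CSV (equivalent to wide)."""
    df = pd.read_csv(long_path, sep="\t", dtype={"cell_id": str})
    modalities = sorted(df["modality"].unique())
    all_times = np.sort(df["time_h"].unique())
    step = _check_regular(all_times, "long cohort")
    outdir_frames = {}
    for m in modalities:
        sub = df[df["modality"] == m].pivot(
            index="cell_id", columns="time_h", values="value"
        )
        sub = sub.reindex(columns=all_times)
        sub.columns = [_TIME_FMT.format(t) for t in all_times]
        outdir_frames[m] = sub
    import tempfile, os

    with tempfile.TemporaryDirectory() as tmp:
        paths = {}
        for m, frame in outdir_frames.items():
            p = Path(tmp) / f"{m}.csv"
            frame.index.name = "cell_id"
            frame.to_csv(p)
            paths[m] = p
        cohort = read_cohort_wide(paths, labels_path)
    return cohort


def write_features(features: dict[str, FeatureMatrix], outdir: str | Path,
                   prefix: str = "features") -> dict[str, Path]:
    """Serialize per-modality feature matrices as CSV with name-encoded headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for m, fm in features.items():
        cols = [f"{mm}:{tt}:{ii}" for mm, tt, ii in fm.feature_names]
        df = pd.DataFrame(fm.values, index=fm.cell_ids, columns=cols)
        df.index.name = "cell_id"
        p = outdir / f"{prefix}_{m}.csv"
        df.to_csv(p)
        paths[m] = p
    return paths


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="cell_id")
    names = []
    for c in df.columns:
        m, t, i = c.split(":")
        names.append((m, t, int(i)))
    return FeatureMatrix(values=df.to_numpy(dtype=float),
                         feature_names=names,
                         cell_ids=[str(i) for i in df.index])


def write_json_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration (generator / preprocess / transform /
    ensemble / evaluation / interpretation sections, all optional)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg
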