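"""Long-format CSV readers/writers for track tables and JSON config loading.

The exchange format is a single long CSV with one row per sample:
``cell_id, replicate_id, condition, channel, time_h, intensity,
mitosis_times, sphase_times, release_time``.  The last three are optional
event columns; event lists are semicolon-joined hours, empty = none.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DT_TOL,
    AnalysisConfig,
    Cohort,
    DuplicationError,
    SamplingError,
    SchemaError,
    Trace,
)

MANDATORY = ["cell_id", "replicate_id", "condition", "channel", "time_h", "intensity"]
EVENT_COLS = ["mitosis_times", "sphase_times", "release_time"]


def _join_hours(values) -> str:
    return ";".join(repr(float(v)) for v in values)


def _split_hours(cell) -> np.ndarray:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return np.array([])
    return np.array([float(x) for x in str(cell).split(";")])


def write_tracks(cohort: Cohort, path) -> Path:
    """Serialize a cohort to long-format CSV (deterministic row order)."""
    path = Path(path)
    rows = []
    order = sorted(range(len(cohort.traces)),
                   key=lambda i: (cohort.traces[i].replicate_id,
                                  cohort.traces[i].cell_id,
                                  cohort.traces[i].channel))
    for i in order:
        tr = cohort.traces[i]
        mit = _join_hours(tr.mitosis_times)
        sph = _join_hours(tr.sphase_times)
        rel = "" if tr.release_time is None else repr(float(tr.release_time))
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.cell_id, tr.replicate_id, tr.condition, tr.channel,
                         repr(float(t)), repr(float(v)), mit, sph, rel))
    df = pd.DataFrame(rows, columns=MANDATORY + EVENT_COLS)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_tracks(path) -> Cohort:
    """Parse a long-format CSV into a cohort (one trace per cell × channel).

    Raises :class:`SchemaError` on missing mandatory columns,
    :class:`DuplicationError` on duplicate (cell, channel, time) rows and
    :class:`SamplingError` on non-uniform time steps.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "replicate_id": str,
                                  "mitosis_times": str, "sphase_times": str})
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    traces: list[Trace] = []
    if len(df):
        for (rep, cell, chan), grp in df.groupby(
                ["replicate_id", "cell_id", "channel"], sort=True):
            grp = grp.sort_values("time_h")
            times = grp["time_h"].to_numpy(dtype=float)
            if len(np.unique(times)) != len(times):
                raise DuplicationError(
                    f"duplicate (cell={cell}, channel={chan}) time points")
            if len(times) >= 3:
                steps = np.diff(times)
                if np.max(np.abs(steps - steps[0])) > DT_TOL:
                    raise SamplingError(
                        f"cell={cell}, channel={chan}: non-uniform time step")
            first = grp.iloc[0]
            rel = first.get("release_time", None)
            rel = None if rel is None or (isinstance(rel, float) and np.isnan(rel)) \
                or str(rel) == "" else float(rel)
            traces.append(Trace(
                cell_id=str(cell), replicate_id=str(rep),
                condition=str(first["condition"]), channel=str(chan),
                times=times, values=grp["intensity"].to_numpy(dtype=float),
                mitosis_times=_split_hours(first.get("mitosis_times")),
                sphase_times=_split_hours(first.get("sphase_times")),
                release_time=rel,
            ))
    if traces:
        dt = traces[0].dt if len(traces[0].times) >= 2 else 0.0
        duration = max(tr.span for tr in traces)
    else:
        dt, duration = 0.0, 0.0
    return Cohort(traces=traces, dt=dt, duration=duration,
                  provenance={"source": str(path)})


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from JSON; unknown keys rejected."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    try:
        return AnalysisConfig(**payload)
    except Exception as exc:
        raise SchemaError(f"{path}: invalid config: {exc}") from exc
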