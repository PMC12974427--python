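"""Event detection and phase/reentry/intensity statistics.

Covers prominence-based peak/dip detection, peak–dip amplitudes, the
post-release dip fold-change, event phase relations (e.g. HES1 dip vs
S-phase onset with a coincidence tolerance), reentry timing after drug
release, division fractions, and raw intensity-level summaries between
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import find_peaks

from .datamodel import AnnotationError, Cohort, ParameterError, Trace
from .preprocess import DetrendedTrace

TraceLike = Union[Trace, DetrendedTrace]

__all__ = ["EventRecord", "PhasePair", "detect_extrema", "peak_dip_amplitudes",
           "release_dip_foldchange", "post_release_dip", "phase_pairs",
           "reentry_stats", "division_fractions", "intensity_stats"]


@dataclass
class EventRecord:
    trace_id: str
    kind: str        # peak | dip | sphase_onset | mitosis | p21_decline | cdk2_max
    time: float      # hours
    value: float     # a.u. or z-units
    prominence: float = np.nan


@dataclass
class PhasePair:
    cell_id: str
    kind_a: str
    time_a: float
    kind_b: str
    time_b: float
    offset: float             # time_b - time_a, hours
    coincidence_class: str    # a_first | coincident | b_first


def detect_extrema(trace: TraceLike, prominence: float) -> list[EventRecord]:
    """Alternating peaks and dips by prominence-filtered extremum search.

    When two same-kind extrema are adjacent after merging, the more
    prominent one is kept (ties break toward the earlier event).  May
    return an empty list (e.g. monotone input).
    """
    values = np.asarray(trace.values, dtype=float)
    times = np.asarray(trace.times, dtype=float)
    if len(values) < 5:
        raise ParameterError("detect_extrema needs >= 5 samples")
    trace_id = getattr(trace, "cell_id", "?")
    peaks, pprop = find_peaks(values, prominence=prominence)
    dips, dprop = find_peaks(-values, prominence=prominence)
    events = (
        [EventRecord(trace_id, "peak", float(times[i]), float(values[i]), float(pr))
         for i, pr in zip(peaks, pprop["prominences"])]
        + [EventRecord(trace_id, "dip", float(times[i]), float(values[i]), float(pr))
           for i, pr in zip(dips, dprop["prominences"])]
    )
    events.sort(key=lambda e: e.time)
    # enforce alternation
    cleaned: list[EventRecord] = []
    for ev in events:
        if cleaned and cleaned[-1].kind == ev.kind:
            if ev.prominence > cleaned[-1].prominence:
                cleaned[-1] = ev
        else:
            cleaned.append(ev)
    return cleaned


def peak_dip_amplitudes(events: list[EventRecord]) -> np.ndarray:
    """Amplitude of every adjacent peak -> dip pair.

    Raises on non-alternating event lists.
    """
    for a, b in zip(events[:-1], events[1:]):
        if a.kind == b.kind:
            raise ParameterError("events must alternate between peaks and dips")
    amps = [a.value - b.value for a, b in zip(events[:-1], events[1:])
            if a.kind == "peak" and b.kind == "dip"]
    return np.array(amps)


def _release_window(trace: TraceLike, window: float = 15.0):
    """[release, min(first mitosis, release + window)] as sample indices."""
    rel = trace.release_time
    times = np.asarray(trace.times, dtype=float)
    if rel is None:
        raise AnnotationError(f"trace {getattr(trace, 'cell_id', '?')}: no release_time")
    if rel > times[-1]:
        raise ParameterError("release time beyond trace end")
    later = trace.mitosis_times[trace.mitosis_times > rel]
    end = float(later[0]) if len(later) else min(rel + window, times[-1])
    dt = times[1] - times[0]
    i_rel = int(np.ceil((rel - times[0]) / dt - 0.5))
    i_end = int(np.ceil((min(end, times[-1]) - times[0]) / dt - 0.5))
    return i_rel, max(i_end, i_rel + 1)


def release_dip_foldchange(trace: TraceLike, window: float = 15.0) -> float:
    """Intensity at release / minimum before the first mitosis.

    The minimum window runs from the release sample (inclusive) to the
    first mitosis, or ``window`` hours (default 15) for cells with no
    mitosis, so the fold-change is always >= 1.
    """
    i_rel, i_end = _release_window(trace, window)
    values = np.asarray(trace.values, dtype=float)
    v_rel = values[i_rel]
    v_min = values[i_rel:i_end + 1].min()
    return float(v_rel / v_min)


def post_release_dip(trace: TraceLike, window: float = 15.0,
                     smooth: float = 1.0) -> Optional[EventRecord]:
    """The post-release HES1 dip: minimum between release and first mitosis.

    The dip is located on a lightly smoothed trace (centered moving
    average of width ``smooth`` hours) so its timing is robust to
    sample-level noise; the reported value is the raw intensity there.
    Returns None when the minimum sits on the window boundary (no genuine
    interior dip).
    """
    from .preprocess import moving_average

    i_rel, i_end = _release_window(trace, window)
    values = np.asarray(trace.values, dtype=float)
    times = np.asarray(trace.times, dtype=float)
    smoothed = moving_average(values, smooth, times[1] - times[0]) if smooth else values
    seg = smoothed[i_rel:i_end + 1]
    k = int(np.argmin(seg))
    if k == 0 or k == len(seg) - 1:
        return None
    return EventRecord(getattr(trace, "cell_id", "?"), "dip",
                       float(times[i_rel + k]), float(values[i_rel + k]))


def _classify(offset: float, tol: float) -> str:
    if abs(offset) <= tol:
        return "coincident"
    return "a_first" if offset > 0 else "b_first"


def _events_for(trace: TraceLike, kind: str) -> list[float]:
    """Event times of a given kind for one trace (annotations or detection)."""
    if kind == "mitosis":
        return list(trace.mitosis_times)
    if kind == "sphase_onset":
        return list(trace.sphase_times)
    if kind == "dip" and trace.release_time is not None:
        ev = post_release_dip(trace)
        return [ev.time] if ev is not None else []
    raise ParameterError(f"no event source for kind {kind!r}; "
                         "pass explicit events via phase_pairs(events_a=...)")


def phase_pairs(cohort: Cohort, kind_a: str, kind_b: str, tol: float = 1.0,
                events_a: Optional[dict[str, list[float]]] = None,
                events_b: Optional[dict[str, list[float]]] = None) -> dict:
    """Per-cell event-pair offsets and coincidence-class fractions.

    Each a-event pairs with the nearest b-event of the same cell; the
    offset is t_b - t_a and the pair is coincident when |offset| <= tol.
    Cells lacking either event kind are excluded but counted.  For the
    HES1-dip vs S-phase relation the headline number is the fraction of
    pairs classified dip-first or coincident.

    ``events_a``/``events_b`` allow supplying detected events explicitly,
    keyed by cell id.
    """
    pairs: list[PhasePair] = []
    excluded = 0
    for tr in cohort.traces:
        ta = events_a.get(tr.cell_id, []) if events_a is not None else _events_for(tr, kind_a)
        tb = events_b.get(tr.cell_id, []) if events_b is not None else _events_for(tr, kind_b)
        if not ta or not tb:
            excluded += 1
            continue
        tb_arr = np.asarray(tb, dtype=float)
        for a in ta:
            b = float(tb_arr[np.argmin(np.abs(tb_arr - a))])
            off = b - a
            pairs.append(PhasePair(tr.cell_id, kind_a, float(a), kind_b, b,
                                   float(off), _classify(off, tol)))
    n = len(pairs)
    frac = {cls: (sum(p.coincidence_class == cls for p in pairs) / n if n else np.nan)
            for cls in ("a_first", "coincident", "b_first")}
    frac["a_first_or_coincident"] = (frac["a_first"] + frac["coincident"]) if n else np.nan
    return {"pairs": pairs, "fractions": frac, "n_pairs": n,
            "n_excluded_cells": excluded}


def reentry_stats(cohort: Cohort, window: float = 30.0) -> dict:
    """Fraction of cells with a mitosis within ``window`` hours of release,
    plus the first-mitosis-time histogram (1 h bins, hours post-release)."""
    n_div = 0
    first_times = []
    n = 0
    for tr in cohort.traces:
        if tr.channel not in ("hes1_endo", "control"):
            continue
        if tr.release_time is None:
            raise AnnotationError(f"trace {tr.cell_id}: missing release_time")
        n += 1
        later = tr.mitosis_times[tr.mitosis_times > tr.release_time]
        if len(later):
            dt_first = float(later[0] - tr.release_time)
            first_times.append(dt_first)
            if dt_first <= window:
                n_div += 1
    if n == 0:
        raise ParameterError("reentry_stats needs >= 1 trace with release_time")
    edges = np.arange(0.0, np.ceil(window) + 1.0, 1.0)
    counts, _ = np.histogram([t for t in first_times if t <= window], bins=edges)
    return {"fraction": n_div / n, "n_cells": n, "first_mitosis_times":
            np.array(first_times), "hist": (counts, edges)}


def division_fractions(cohort: Cohort, window: float, k: int = 1) -> float:
    """Fraction of cells with >= k mitoses within ``window`` h of trace start."""
    traces = [tr for tr in cohort.traces if tr.channel in ("hes1_endo", "control")]
    if not traces:
        return np.nan
    count = 0
    for tr in traces:
        start = tr.times[0]
        m = tr.mitosis_times[(tr.mitosis_times > start) & (tr.mitosis_times <= start + window)]
        if len(m) >= k:
            count += 1
    return count / len(traces)


def intensity_stats(cohort: Cohort, reference: Cohort) -> dict:
    """Per-cell raw-intensity summaries and fold-changes vs a reference.

    For each cohort the per-cell mean/max/min of the raw trace is taken;
    fold-changes are ratios of cohort medians to reference medians, and
    ``normalized`` holds per-cell values divided by the reference median
    (the study's display convention).
    """
    def per_cell(c: Cohort) -> dict[str, np.ndarray]:
        vals = {"mean": [], "max": [], "min": []}
        for tr in c.traces:
            vals["mean"].append(float(tr.values.mean()))
            vals["max"].append(float(tr.values.max()))
            vals["min"].append(float(tr.values.min()))
        return {k: np.array(v) for k, v in vals.items()}

    if len(reference.traces) == 0:
        raise ParameterError("reference cohort is empty")
    stats_c = per_cell(cohort)
    stats_r = per_cell(reference)
    medians_c = {k: float(np.median(v)) for k, v in stats_c.items()}
    medians_r = {k: float(np.median(v)) for k, v in stats_r.items()}
    folds = {k: medians_c[k] / medians_r[k] for k in medians_c}
    normalized = {k: stats_c[k] / medians_r[k] for k in stats_c}
    return {"per_cell": stats_c, "medians": medians_c,
            "reference_medians": medians_r, "folds": folds,
            "normalized": normalized}
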