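"""Cell cycle segmentation, pseudo-time warping, and dip-timing extraction.

Asynchronously cycling cells average to a flat population trace in real
time; rescaling each mitosis-to-mitosis segment to percent-of-cycle
("pseudo-synchronization") aligns the cycle-locked oscillation so the
population mean shows the characteristic peak–dip–peak profile.  The dip
statistic is the per-cell time of minimum (z-scored, circadian-isolated)
intensity in the daughter generation, in hours before the final mitosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde

from .datamodel import AnalysisConfig, Cohort, ParameterError, Trace
from .preprocess import isolate_band, zscore_values

__all__ = ["CycleSegment", "AlignedMatrix", "segment_cycles",
           "warp_pseudotime", "population_mean", "dip_timing"]

#: plausibility window for a cell cycle length, hours
CYCLE_LENGTH_BOUNDS = (6.0, 80.0)


@dataclass
class CycleSegment:
    """A mitosis-to-mitosis slice of a trace."""

    trace_id: str
    start_mitosis: float
    end_mitosis: float
    cycle_length: float
    times: np.ndarray
    values: np.ndarray
    flagged: bool = False     # cycle length outside plausibility bounds


@dataclass
class AlignedMatrix:
    """Two-generation traces aligned so the final mitosis is t = 0."""

    cell_ids: list[str] = field(default_factory=list)
    rows: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    dip_times: np.ndarray = field(default_factory=lambda: np.array([]))
    density_grid: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None


def segment_cycles(trace: Trace) -> list[CycleSegment]:
    """One segment per consecutive mitosis pair (< 2 mitoses -> empty list).

    Segments whose length falls outside the 6–80 h plausibility window
    are flagged, not dropped.
    """
    mitoses = trace.mitosis_times
    segments: list[CycleSegment] = []
    for m0, m1 in zip(mitoses[:-1], mitoses[1:]):
        i0, i1 = trace.nearest_index(m0), trace.nearest_index(m1)
        T = float(m1 - m0)
        segments.append(CycleSegment(
            trace_id=trace.cell_id, start_mitosis=float(m0), end_mitosis=float(m1),
            cycle_length=T, times=trace.times[i0:i1 + 1],
            values=trace.values[i0:i1 + 1],
            flagged=not (CYCLE_LENGTH_BOUNDS[0] <= T <= CYCLE_LENGTH_BOUNDS[1])))
    return segments


def warp_pseudotime(segment: CycleSegment, n_bins: int = 100) -> np.ndarray:
    """Resample a segment onto ``n_bins + 1`` equally spaced cycle fractions.

    Linear interpolation; endpoints equal the boundary samples.
    """
    if len(segment.times) < 4:
        raise ParameterError("warp_pseudotime needs a segment with >= 4 samples")
    fracs = np.linspace(0.0, 1.0, n_bins + 1)
    target = segment.times[0] + fracs * (segment.times[-1] - segment.times[0])
    return np.interp(target, segment.times, segment.values)


def population_mean(cohort: Cohort, mode: str, n_bins: int = 100) -> dict:
    """Population mean ± sd profile of z-scored traces.

    ``real_time``: average across traces at each shared time point.
    ``pseudo_time``: average across warped mitosis-to-mitosis segments.
    """
    if mode == "real_time":
        if len(cohort.traces) < 5:
            raise ParameterError("population_mean needs >= 5 traces")
        n = min(len(tr.values) for tr in cohort.traces)
        stack = np.vstack([zscore_values(tr.values)[:n] for tr in cohort.traces])
        axis = cohort.traces[0].times[:n]
        return {"axis": axis, "mean": stack.mean(axis=0), "sd": stack.std(axis=0),
                "n": stack.shape[0]}
    if mode == "pseudo_time":
        warped = []
        for tr in cohort.traces:
            ztr = Trace(cell_id=tr.cell_id, replicate_id=tr.replicate_id,
                        condition=tr.condition, channel=tr.channel,
                        times=tr.times, values=zscore_values(tr.values),
                        mitosis_times=tr.mitosis_times)
            for seg in segment_cycles(ztr):
                if not seg.flagged and len(seg.times) >= 4:
                    warped.append(warp_pseudotime(seg, n_bins))
        if len(warped) < 5:
            raise ParameterError("population_mean needs >= 5 segments")
        stack = np.vstack(warped)
        axis = np.linspace(0.0, 100.0, n_bins + 1)  # percent of cycle
        return {"axis": axis, "mean": stack.mean(axis=0), "sd": stack.std(axis=0),
                "n": stack.shape[0]}
    raise ParameterError(f"unknown mode {mode!r}")


def dip_timing(cohort: Cohort, config: Optional[AnalysisConfig] = None) -> AlignedMatrix:
    """Daughter-generation dip times relative to the final mitosis.

    Uses cells with >= 3 annotated mitoses (their last three): the trace
    is circadian-isolated and z-scored, the daughter generation is the
    final mitosis-to-mitosis segment, and the dip is its interior
    minimum.  Cells whose minimum falls on a segment boundary are
    excluded (boundary minima are mitotic-signal artifacts).  Dip times
    are negative hours before the final mitosis; a Gaussian kernel
    density over cells summarizes the distribution.
    """
    config = config or AnalysisConfig()
    out = AlignedMatrix()
    dips = []
    for tr in cohort.traces:
        if len(tr.mitosis_times) < 3:
            continue
        m1, m2, m3 = tr.mitosis_times[-3:]
        iso = isolate_band(tr, "circadian_isolated", config)
        z = zscore_values(iso.values)
        i0, i1, i2 = (tr.nearest_index(m) for m in (m1, m2, m3))
        seg = z[i1:i2 + 1]
        if len(seg) < 3:
            continue
        k = int(np.argmin(seg))
        if k == 0 or k == len(seg) - 1:
            continue  # boundary minimum: excluded
        t_min = tr.times[i1 + k]
        dips.append(float(t_min - m3))
        out.cell_ids.append(tr.cell_id)
        out.rows.append((tr.times[i0:i2 + 1] - m3, z[i0:i2 + 1]))
    out.dip_times = np.array(dips)
    if len(dips) >= 2 and np.ptp(dips) > 0:
        kde = gaussian_kde(out.dip_times)
        grid = np.linspace(min(dips) - 2.0, max(dips) + 2.0, 256)
        out.density_grid = grid
        out.density = kde(grid)
    return out
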