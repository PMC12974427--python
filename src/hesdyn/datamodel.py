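"""Core data types for single-cell fluorescence track analysis.

A :class:`Trace` is one cell × one channel: a uniformly sampled intensity
series (hours, arbitrary fluorescence units) plus event annotations
(mitoses, S-phase onsets, drug-release time).  A :class:`Cohort` groups
traces that share a condition/replicate design and sampling interval, and
carries free-form provenance (generator parameters, seed, version).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: allowed experimental conditions
CONDITIONS = ("proliferative", "arrested", "released", "misexpression", "control_nls")

#: allowed reporter channels
CHANNELS = ("hes1_endo", "hes1_exo", "hes1_total", "cdk2", "p21", "control")

#: tolerance on the uniformity of the time step, in hours
DT_TOL = 1e-9


class SchemaError(ValueError):
    """A table or config is missing/violating required structure."""


class SamplingError(ValueError):
    """Time points of a trace are not uniformly spaced."""


class DuplicationError(ValueError):
    """Duplicate (cell, channel, time) rows."""


class ParameterError(ValueError):
    """An operation was called with out-of-range parameters."""


class AnnotationError(ValueError):
    """A required event annotation is missing."""


@dataclass
class Trace:
    """One cell × one channel uniformly sampled intensity series.

    Times are hours with a constant step ``dt``; values are intensities in
    arbitrary units on a linear scale.  Event times are real-valued hours
    (not sample indices); ``mitosis_times`` and ``sphase_times`` are sorted
    and must fall within the sampled span.
    """

    cell_id: str
    replicate_id: str
    condition: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    mitosis_times: np.ndarray = field(default_factory=lambda: np.array([]))
    sphase_times: np.ndarray = field(default_factory=lambda: np.array([]))
    release_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mitosis_times = np.sort(np.asarray(self.mitosis_times, dtype=float))
        self.sphase_times = np.sort(np.asarray(self.sphase_times, dtype=float))

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ParameterError(f"trace {self.cell_id}: need >= 2 samples for dt")
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def nearest_index(self, t: float) -> int:
        """Snap an event time (hours) to the nearest sample index.

        Exact midpoints break toward the earlier sample.
        """
        x = (t - self.times[0]) / self.dt
        idx = int(np.ceil(x - 0.5))
        return min(max(idx, 0), len(self.times) - 1)

    def violations(self) -> list[str]:
        """Invariant violations for this trace (empty list = valid)."""
        out: list[str] = []
        tag = f"trace {self.cell_id}/{self.channel}"
        if self.condition not in CONDITIONS:
            out.append(f"{tag}: unknown condition {self.condition!r}")
        if self.channel not in CHANNELS:
            out.append(f"{tag}: unknown channel {self.channel!r}")
        if len(self.times) != len(self.values):
            out.append(f"{tag}: times and values length mismatch")
            return out
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                out.append(f"{tag}: times not strictly increasing")
            elif np.any(np.abs(steps - steps[0]) > DT_TOL):
                out.append(f"{tag}: non-uniform time step")
        if not np.all(np.isfinite(self.values)):
            out.append(f"{tag}: non-finite intensity values")
        elif np.any(self.values < 0):
            out.append(f"{tag}: negative intensity values")
        if len(self.times) > 0:
            lo, hi = self.times[0], self.times[-1]
            for name, ev in (("mitosis", self.mitosis_times), ("sphase", self.sphase_times)):
                if len(ev) and (ev[0] < lo - DT_TOL or ev[-1] > hi + DT_TOL):
                    out.append(f"{tag}: {name} time outside sampled span")
            if self.release_time is not None and not (lo - DT_TOL <= self.release_time <= hi + DT_TOL):
                out.append(f"{tag}: release time outside sampled span")
        return out

    def equal_to(self, other: "Trace", tol: float = 1e-9) -> bool:
        """Field-by-field equality (times/values to ``tol``)."""
        if (self.cell_id, self.replicate_id, self.condition, self.channel) != (
            other.cell_id, other.replicate_id, other.condition, other.channel
        ):
            return False
        for a, b in ((self.times, other.times), (self.values, other.values),
                     (self.mitosis_times, other.mitosis_times),
                     (self.sphase_times, other.sphase_times)):
            if len(a) != len(b) or (len(a) and np.max(np.abs(a - b)) > tol):
                return False
        if (self.release_time is None) != (other.release_time is None):
            return False
        if self.release_time is not None and abs(self.release_time - other.release_time) > tol:
            return False
        return True


@dataclass
class Cohort:
    """A set of traces sharing a sampling design, with provenance."""

    traces: list[Trace]
    dt: float
    duration: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    def select(self, channel: Optional[str] = None,
               condition: Optional[str] = None) -> "Cohort":
        """Sub-cohort restricted to a channel and/or condition."""
        kept = [tr for tr in self.traces
                if (channel is None or tr.channel == channel)
                and (condition is None or tr.condition == condition)]
        return Cohort(kept, self.dt, self.duration, dict(self.provenance))

    def equal_to(self, other: "Cohort", tol: float = 1e-9) -> bool:
        if len(self) != len(other):
            return False
        return all(a.equal_to(b, tol) for a, b in zip(self.traces, other.traces))


def validate(cohort: Cohort) -> list[str]:
    """Report every invariant violation in a cohort.

    Total: never raises on arbitrary well-typed input; returns an empty
    list iff all trace invariants hold and all traces share the cohort dt.
    """
    out: list[str] = []
    for tr in cohort.traces:
        try:
            out.extend(tr.violations())
            if len(tr.times) >= 2 and abs(tr.dt - cohort.dt) > DT_TOL:
                out.append(f"trace {tr.cell_id}/{tr.channel}: dt differs from cohort dt")
        except Exception as exc:  # totality: report, never throw
            out.append(f"trace {getattr(tr, 'cell_id', '?')}: unreadable ({exc})")
    return out


class AnalysisConfig(BaseModel):
    """Analysis parameters (hours unless noted); unknown keys are rejected.

    ``circadian_band``/``ultradian_band`` are the period bands used for
    band-power summaries (the 20–30 h circadian-level and 4–8 h ultradian
    ranges); ``detrend_window_long``/``short`` are the moving-average
    windows that isolate them; ``coincidence_tol`` is the window within
    which two events count as coincident; ``dip_prominence`` is in z-units.
    """

    model_config = ConfigDict(extra="forbid")

    circadian_band: tuple[float, float] = (20.0, 30.0)
    ultradian_band: tuple[float, float] = (4.0, 8.0)
    period_search: tuple[float, float] = (3.0, 40.0)
    detrend_window_long: float = 40.0
    detrend_window_short: float = 12.0
    coincidence_tol: float = 1.0
    dip_prominence: float = 0.5
    seed: int = 0

    @field_validator("circadian_band", "ultradian_band", "period_search")
    @classmethod
    def _band_ordered(cls, v, info):
        lo, hi = v
        if not (0 < lo < hi):
            raise ValueError(f"{info.field_name}: need 0 < low < high, got {v}")
        return v

    @model_validator(mode="after")
    def _positive(self):
        if self.coincidence_tol <= 0:
            raise ValueError("coincidence_tol must be > 0")
        if self.detrend_window_long <= 0 or self.detrend_window_short <= 0:
            raise ValueError("detrend windows must be > 0")
        return self
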