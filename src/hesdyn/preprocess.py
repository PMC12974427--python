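"""Normalization and band-isolating detrending.

Detrending is centered moving-average subtraction, chosen for linearity
and a closed-form sinusoid attenuation: a moving average of width W
passes a sinusoid of period T with gain sinc(W/T) = sin(piW/T)/(piW/T),
so the detrended residual keeps amplitude 1 - sinc(W/T).  A long window
(default 40 h) isolates circadian-level oscillations by removing slower
drift; a short window (default 12 h) additionally removes the
circadian-level component, isolating ultradian oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AnalysisConfig, ParameterError, Trace

__all__ = ["DetrendedTrace", "zscore", "zscore_values", "detrend",
           "moving_average", "isolate_band"]


@dataclass
class DetrendedTrace:
    """A band-isolated view of a parent trace (same sampling)."""

    parent: Trace
    band_label: str          # circadian_isolated | ultradian_isolated | raw
    times: np.ndarray
    values: np.ndarray
    window_used: float       # hours; 0 for raw

    # annotation passthrough so downstream event logic works on either type
    @property
    def cell_id(self) -> str:
        return self.parent.cell_id

    @property
    def replicate_id(self) -> str:
        return self.parent.replicate_id

    @property
    def mitosis_times(self) -> np.ndarray:
        return self.parent.mitosis_times

    @property
    def sphase_times(self) -> np.ndarray:
        return self.parent.sphase_times

    @property
    def release_time(self):
        return self.parent.release_time

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def zscore_values(values: np.ndarray) -> np.ndarray:
    """Z-score an array with the population sd; constant input -> zeros."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ParameterError("zscore needs at least 2 samples")
    sd = values.std()  # population sd (ddof=0)
    # constant up to float representation (e.g. an array of 1.9 has a
    # ~1e-16 sd from rounding) counts as zero-variance
    if sd == 0 or sd < 1e-12 * max(np.abs(values).max(), 1.0):
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def zscore(trace: Trace) -> Trace:
    """Z-score-normalized copy of a trace (mean 0, population sd 1)."""
    out = Trace(cell_id=trace.cell_id, replicate_id=trace.replicate_id,
                condition=trace.condition, channel=trace.channel,
                times=trace.times.copy(), values=zscore_values(trace.values),
                mitosis_times=trace.mitosis_times.copy(),
                sphase_times=trace.sphase_times.copy(),
                release_time=trace.release_time)
    return out


def moving_average(values: np.ndarray, window: float, dt: float) -> np.ndarray:
    """Centered moving average of width ``window`` hours.

    Edge windows are truncated symmetrically to the available span, so
    the filter stays centered (and exact on linear ramps) everywhere.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = int(round(window / (2.0 * dt)))
    idx = np.arange(n)
    k = np.minimum(half, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate([[0.0], np.cumsum(values)])
    return (cs[idx + k + 1] - cs[idx - k]) / (2 * k + 1)


def detrend(trace: Trace, window: float) -> DetrendedTrace:
    """Subtract a centered moving average of width ``window`` hours.

    Linear in the input; requires window >= 3*dt and a trace longer than
    the window.
    """
    dt = trace.dt
    if window < 3.0 * dt:
        raise ParameterError(f"window {window} h too small (need >= {3 * dt} h)")
    if trace.span <= window:
        raise ParameterError(
            f"trace span {trace.span} h must exceed window {window} h")
    resid = trace.values - moving_average(trace.values, window, dt)
    return DetrendedTrace(parent=trace, band_label="raw", times=trace.times,
                          values=resid, window_used=window)


def isolate_band(trace: Trace, band_label: str,
                 config: AnalysisConfig | None = None) -> DetrendedTrace:
    """Band-isolate a trace.

    ``circadian_isolated`` removes drift slower than the circadian band
    (long window); ``ultradian_isolated`` removes circadian-level and
    slower components (short window); ``raw`` passes through.
    """
    config = config or AnalysisConfig()
    if band_label == "raw":
        return DetrendedTrace(parent=trace, band_label="raw", times=trace.times,
                              values=trace.values.copy(), window_used=0.0)
    if band_label == "circadian_isolated":
        out = detrend(trace, config.detrend_window_long)
    elif band_label == "ultradian_isolated":
        out = detrend(trace, config.detrend_window_short)
    else:
        raise ParameterError(f"unknown band label {band_label!r}")
    out.band_label = band_label
    return out
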