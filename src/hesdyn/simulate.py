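"""Synthetic single-cell HES1 trace generator.

Emulates the four experimental regimes of the MCF-7 dormancy/reactivation
study design, with the statistical structure the downstream analysis
assumes:

* **proliferative** — a cell cycle-locked ~24 h oscillation (biphasic:
  high after mitosis, a dip 10–14 h before the next mitosis, high again
  into mitosis) nested with a weak 4–8 h ultradian component; a
  spontaneously nondividing (SND) subpopulation behaves like arrested
  cells.
* **arrested** — CDK4/6-inhibited cells: no mitoses, the cycle-locked
  component removed, baseline elevated 1.4-fold, ultradian component
  relatively enhanced.
* **released** — arrested until the release time, then a synchronous dip
  (mean fold-change 2.2, bottom 8–10 h post-release), S-phase onset just
  after the dip, first mitosis at release + lognormal reentry time
  (median 19 h), and proliferative dynamics thereafter.
* **misexpression** — released cells carrying a Tet-inducible exogenous
  HES1 channel that oscillates in anti-phase with the endogenous
  reporter, flattening the total-HES1 signal; in the 24 h assay a cell
  divides only if its total trace dips below a threshold fraction of its
  value at release.
* **control_nls** — constitutive nuclear reporter: constant + drift +
  noise, no periodic terms.

All stochastic terms flow from one integer seed; identical seeds and
parameters produce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import Cohort, ParameterError, Trace

__all__ = ["RegimeParams", "calibrate_defaults", "simulate_cohort",
           "simulate_release_assay", "cycle_waveform"]

#: second-harmonic fraction of the cycle-locked waveform.  1/4 is the
#: largest value for which the interior minimum at u_dip stays unique
#: (quartic bottom); it yields dip excursion 0.6x the peak excursion,
#: which is what reproduces the asymmetric arrest fold-changes (max
#: ~1.1x, min ~1.6x) alongside the 1.4x mean.
CC_SECOND_HARMONIC = 0.25

#: dip excursion of the normalized waveform (peak excursion is 1)
CC_DIP_FRACTION = (1.0 - CC_SECOND_HARMONIC) / (1.0 + CC_SECOND_HARMONIC)


def cycle_waveform(u: np.ndarray, u_dip: np.ndarray) -> np.ndarray:
    """Cycle-locked waveform on cycle fraction ``u`` with minimum at ``u_dip``.

    Zero-mean over a full cycle, maximum +1 near both mitoses, unique
    interior minimum of depth ``-CC_DIP_FRACTION`` exactly at ``u_dip``.
    """
    theta = 2.0 * np.pi * (np.asarray(u) - u_dip)
    h = CC_SECOND_HARMONIC
    return (-np.cos(theta) + h * np.cos(2.0 * theta)) / (1.0 + h)


@dataclass
class RegimeParams:
    """Generator parameters for one condition regime.

    Units: hours for times/periods, arbitrary fluorescence units (a.u.)
    for intensities, relative fractions for amplitudes.  Shipped defaults
    are the study conditions; amplitude and gate constants were fixed once
    by simulation search against the printed population statistics (see
    :func:`calibrate_defaults`).
    """

    regime: str = "proliferative"
    baseline: float = 100.0                      # B, a.u.
    cc_amplitude: float = 0.45                   # peak excursion of cycle component
    ultradian_amplitude: float = 0.06            # cycling-cell ultradian (relative)
    ultradian_amplitude_arrested: float = 0.22   # arrest-enhanced ultradian (relative)
    ultradian_period_range: tuple[float, float] = (5.5, 7.5)  # per-cell Uniform
    cycle_length_median: float = 23.3
    cycle_length_sigma_log: float = 0.15
    dip_lead_range: tuple[float, float] = (10.0, 14.0)  # L_dip, per-cell Uniform
    snd_fraction: float = 0.25                   # spontaneously nondividing cells
    arrest_level_factor: float = 1.4
    release_time: float = 24.0
    release_dip_foldchange: float = 2.2          # mean per-cell dip fold
    release_dip_sigma_log: float = 0.15          # per-cell fold dispersion
    release_dip_time_range: tuple[float, float] = (8.0, 10.0)  # per-cell Uniform
    reentry_median: float = 19.0
    reentry_sigma_log: float = 0.44
    sphase_delay_mean: float = 1.0               # S-phase onset = dip + N(mean, sd)
    sphase_delay_sd: float = 1.6
    p21_decline_delay_mean: float = 1.5          # p21 decline = dip + N(mean, sd)
    p21_decline_delay_sd: float = 1.0
    dip_gate_threshold: float = 0.524            # theta, fraction of release value
    assay_gate_window: float = 15.0              # gate looks within this post-release
    assay_window: float = 24.0                   # division scored within this window
    exo_level_frac: float = 0.10                 # exogenous level / arrested level
    exo_antiphase_gain: float = 0.24             # anti-phase coupling of exo channel
    ultradian_damp_tau: float = 3.0              # post-release ultradian decay
    noise_sd: float = 1.5                        # white measurement noise, a.u.
    ou_sd: float = 1.5                           # slow biological noise, a.u.
    ou_tau: float = 3.0                          # OU correlation time
    drift_slope: float = 0.05                    # control reporter drift, a.u./h
    include_cochannels: bool = False             # emit CDK2 / p21 channels

    def validated(self) -> "RegimeParams":
        if self.regime not in ("proliferative", "arrested", "released",
                               "misexpression", "control_nls"):
            raise ParameterError(f"unknown regime {self.regime!r}")
        for name in ("baseline", "cc_amplitude", "ultradian_amplitude",
                     "ultradian_amplitude_arrested", "noise_sd", "ou_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 < self.dip_gate_threshold < 1.0):
            raise ParameterError("dip_gate_threshold must be in (0, 1)")
        if self.cycle_length_median <= self.dip_lead_range[1]:
            raise ParameterError("median cycle length must exceed max dip lead")
        return self


def calibrate_defaults() -> dict[str, RegimeParams]:
    """Shipped default parameter set, one :class:`RegimeParams` per regime.

    Anchored constants: 23.3 h median cycle length, dip lead uniform on
    10–14 h, 1.4-fold arrest level, 2.2-fold release dip bottoming 8–10 h
    post-release, lognormal reentry with median 19 h (mode ~18 h, 85%
    within 30 h).  The free amplitude/threshold constants (arrested
    ultradian amplitude 0.22, dip gate threshold 0.524, exogenous level
    fraction 0.10 with anti-phase gain 0.24) were obtained once by
    simulation search so that the end-to-end pipeline reproduces the
    printed population statistics: arrested/proliferative max-intensity
    ratio ~1.1 and min-intensity ratio ~1.6, ~75%/~14% division fractions
    in the 24 h assay, and ~89% dip-before-or-at-S-phase.
    """
    return {
        "proliferative": RegimeParams(regime="proliferative"),
        "arrested": RegimeParams(regime="arrested"),
        "released": RegimeParams(regime="released"),
        "misexpression": RegimeParams(regime="misexpression"),
        "control_nls": RegimeParams(regime="control_nls"),
    }


# ---------------------------------------------------------------------------
# per-cell building blocks

def _ou(rng: np.random.Generator, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path (exact discretization)."""
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    a = np.exp(-dt / tau)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i - 1]
    return x


def _draw_mitoses(rng, p: RegimeParams, start: float, end: float,
                  synchronized: bool = False) -> np.ndarray:
    """Successive lognormal cycle lengths covering [start, end].

    Unsynchronized cells start mid-cycle: the first mitosis is offset
    uniformly within one cycle length before ``start`` so the population
    is asynchronous.
    """
    mu = np.log(p.cycle_length_median)
    draw = lambda: float(rng.lognormal(mu, p.cycle_length_sigma_log))
    first = start if synchronized else start - rng.uniform(0.0, 1.0) * draw()
    mitoses = [first]
    while mitoses[-1] < end:
        mitoses.append(mitoses[-1] + draw())
    return np.array(mitoses)


def _cycle_component(t: np.ndarray, mitoses: np.ndarray, dip_lead: float) -> np.ndarray:
    """Evaluate the cycle-locked waveform along ``t`` given mitosis times."""
    idx = np.clip(np.searchsorted(mitoses, t, side="right") - 1, 0, len(mitoses) - 2)
    t0 = mitoses[idx]
    T = mitoses[idx + 1] - mitoses[idx]
    u = (t - t0) / T
    u_dip = 1.0 - np.minimum(dip_lead / T, 0.95)
    return cycle_waveform(u, u_dip)


def _sphase_onsets(rng, p: RegimeParams, mitoses: np.ndarray,
                   dip_lead: float) -> np.ndarray:
    """One S-phase onset per cycle, just after the cycle's dip."""
    onsets = []
    for m0, m1 in zip(mitoses[:-1], mitoses[1:]):
        dip = m1 - dip_lead
        s = dip + rng.normal(p.sphase_delay_mean, p.sphase_delay_sd)
        onsets.append(float(np.clip(s, m0 + 0.5, m1 - 0.5)))
    return np.array(onsets)


def _within(events: np.ndarray, lo: float, hi: float) -> np.ndarray:
    events = np.asarray(events, dtype=float)
    return events[(events >= lo) & (events <= hi)]


# ---------------------------------------------------------------------------
# regime simulators (deterministic signal + annotations, noise added later)

def _make_proliferative(rng, p: RegimeParams, t: np.ndarray) -> dict:
    B = p.baseline
    if rng.random() < p.snd_fraction:
        out = _make_arrested_core(rng, p, t, p.ultradian_amplitude_arrested)
        out["snd"] = True
        return out
    dip_lead = rng.uniform(*p.dip_lead_range)
    T_u = rng.uniform(*p.ultradian_period_range)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    mitoses = _draw_mitoses(rng, p, t[0], t[-1])
    det = B * (1.0
               + p.cc_amplitude * _cycle_component(t, mitoses, dip_lead)
               + p.ultradian_amplitude * np.sin(2.0 * np.pi * t / T_u + phi))
    sph = _sphase_onsets(rng, p, mitoses, dip_lead)
    return {"det": det, "mitoses": _within(mitoses, t[0], t[-1]),
            "sphase": _within(sph, t[0], t[-1]), "release": None,
            "dip_lead": dip_lead, "snd": False,
            "dips": np.array([m - dip_lead for m in mitoses[1:]])}


def _make_arrested_core(rng, p: RegimeParams, t: np.ndarray,
                        amp: float) -> dict:
    level = p.arrest_level_factor * p.baseline
    T_u = rng.uniform(*p.ultradian_period_range)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    det = level * (1.0 + amp * np.sin(2.0 * np.pi * t / T_u + phi))
    return {"det": det, "mitoses": np.array([]), "sphase": np.array([]),
            "release": None, "snd": False, "dips": np.array([])}


def _make_arrested(rng, p: RegimeParams, t: np.ndarray) -> dict:
    return _make_arrested_core(rng, p, t, p.ultradian_amplitude_arrested)


def _half_cosine(t, t0, t1, v0, v1):
    """Smooth monotone interpolation with zero slope at both ends."""
    frac = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * frac))


def _make_released(rng, p: RegimeParams, t: np.ndarray,
                   gated: bool, exogenous: bool,
                   noise_ou: np.ndarray, noise_w: np.ndarray) -> dict:
    """Released / misexpression cell.

    The deterministic endogenous trajectory is the arrested level until the
    release time, then a smooth dip to level/fold at the per-cell dip time,
    a smooth recovery, and (for dividers) the proliferative waveform from
    the first mitosis onward.  The arrest-enhanced ultradian component
    decays exponentially after release (ultradian power drops on release),
    and the cycling-cell ultradian ramps in, so the trace is continuous at
    the release time.

    When ``gated`` (24 h misexpression assay), division requires the
    *measured* total trace to fall below ``dip_gate_threshold`` x its value
    at release within ``assay_gate_window`` hours; dividers draw a reentry
    time from the lognormal truncated to the assay window.
    """
    B = p.baseline
    rel = p.release_time
    V0 = p.arrest_level_factor * B
    T_u = rng.uniform(*p.ultradian_period_range)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    t_dip = rng.uniform(*p.release_dip_time_range)
    s_log = p.release_dip_sigma_log
    fold = float(rng.lognormal(np.log(p.release_dip_foldchange) - 0.5 * s_log ** 2, s_log))
    fold = max(fold, 1.05)
    dip_lead = rng.uniform(*p.dip_lead_range)
    reentry = float(rng.lognormal(np.log(p.reentry_median), p.reentry_sigma_log))

    post = t >= rel
    sin_term = np.sin(2.0 * np.pi * t / T_u + phi)
    decay = np.where(post, np.exp(-(t - rel) / p.ultradian_damp_tau), 1.0)
    arr_ultradian = V0 * p.ultradian_amplitude_arrested * decay * sin_term

    def cycling_ultradian(m1: Optional[float]) -> np.ndarray:
        # the weak cycling-cell ultradian returns with reentry (first mitosis)
        if m1 is None:
            return np.zeros_like(t)
        ramp = np.where(t >= m1, 1.0 - np.exp(-(t - m1) / p.ultradian_damp_tau), 0.0)
        return B * p.ultradian_amplitude * ramp * sin_term

    dip_time = rel + t_dip
    dip_value = V0 / fold

    def level_curve(m1: Optional[float], recover_to: float) -> np.ndarray:
        lvl = np.full_like(t, V0)
        end_rise = m1 if m1 is not None else t[-1] + 1.0
        if m1 is not None and m1 <= dip_time:
            # rare very early reentry: truncated descent
            lvl[post] = _half_cosine(t[post], rel, dip_time, V0, dip_value)
            lvl[t >= m1] = recover_to
            return lvl
        down = post & (t <= dip_time)
        up = (t > dip_time) & (t < end_rise)
        lvl[down] = _half_cosine(t[down], rel, dip_time, V0, dip_value)
        lvl[up] = _half_cosine(t[up], dip_time, end_rise, dip_value, recover_to)
        return lvl

    # decide division
    if gated:
        # gate on the measured (noisy) trace over the assay gate window,
        # using the nondivider continuation (the dip region is identical)
        lvl_nd = level_curve(None, V0)
        endo_nd = lvl_nd + arr_ultradian
        if exogenous:
            exo_nd = p.exo_level_frac * V0 + p.exo_antiphase_gain * (V0 - endo_nd)
            total_nd = endo_nd + exo_nd
        else:
            total_nd = endo_nd
        meas = total_nd + noise_ou + noise_w
        i_rel = int(np.ceil((rel - t[0]) / (t[1] - t[0]) - 0.5))
        win = (t > rel) & (t <= rel + p.assay_gate_window)
        divides = bool(np.min(meas[win]) < p.dip_gate_threshold * meas[i_rel])
        if divides:
            for _ in range(1000):
                if reentry <= p.assay_window:
                    break
                reentry = float(rng.lognormal(np.log(p.reentry_median),
                                              p.reentry_sigma_log))
            reentry = min(reentry, p.assay_window)
            m1 = rel + max(reentry, t_dip + 2.0)
        else:
            m1 = None
    else:
        # reentry mitosis cannot precede the G1/S dip plus S/G2 progression
        m1 = rel + max(reentry, t_dip + 2.0)

    if m1 is not None:
        mitoses = np.concatenate([[m1], _draw_mitoses(rng, p, m1, t[-1],
                                                      synchronized=True)[1:]]) \
            if m1 < t[-1] else np.array([m1])
        # proliferative waveform value at a mitosis (recovery target)
        next_T = mitoses[1] - mitoses[0] if len(mitoses) > 1 else p.cycle_length_median
        u_dip0 = 1.0 - min(dip_lead / next_T, 0.95)
        P_m = B * (1.0 + p.cc_amplitude * float(cycle_waveform(np.array([0.0]), u_dip0)[0]))
        lvl = level_curve(float(m1), P_m)
        after = t >= m1
        if np.any(after) and len(mitoses) > 1:
            lvl[after] = B * (1.0 + p.cc_amplitude
                              * _cycle_component(t[after], mitoses, dip_lead))
        sph_later = _sphase_onsets(rng, p, mitoses, dip_lead) if len(mitoses) > 1 \
            else np.array([])
        dips_later = np.array([m - dip_lead for m in mitoses[1:]])
    else:
        mitoses = np.array([])
        lvl = level_curve(None, V0)
        sph_later = np.array([])
        dips_later = np.array([])

    endo = lvl + arr_ultradian + cycling_ultradian(m1)

    # first post-release S-phase onset follows the cell's realized
    # biological trough (deterministic dip plus slow biological noise;
    # measurement noise is not part of the cell's state)
    bio = endo + noise_ou
    win_end = min(m1 if m1 is not None else t[-1], rel + 15.0)
    in_win = (t > rel) & (t <= win_end)
    t_trough = float(t[in_win][np.argmin(bio[in_win])])
    s0 = t_trough + rng.normal(p.sphase_delay_mean, p.sphase_delay_sd)
    hi = (m1 - 0.5) if m1 is not None else t[-1]
    s0 = float(np.clip(s0, rel + 0.5, hi))
    sphase = np.concatenate([[s0], sph_later])

    out = {"det": endo, "mitoses": _within(mitoses, t[0], t[-1]),
           "sphase": _within(np.sort(sphase), t[0], t[-1]), "release": rel,
           "snd": False, "dip_lead": dip_lead,
           "dips": np.concatenate([[dip_time], dips_later])}
    if exogenous:
        out["exo_det"] = p.exo_level_frac * V0 + p.exo_antiphase_gain * (V0 - endo)
    return out


def _make_control(rng, p: RegimeParams, t: np.ndarray) -> dict:
    det = p.baseline + p.drift_slope * (t - t[0])
    return {"det": det, "mitoses": np.array([]), "sphase": np.array([]),
            "release": None, "snd": False, "dips": np.array([])}


# ---------------------------------------------------------------------------
# co-channels

def _cdk2_channel(rng, p: RegimeParams, t: np.ndarray, sphase: np.ndarray,
                  noise: np.ndarray) -> np.ndarray:
    """CDK2 activity pulse with maximum exactly at each S-phase onset."""
    v = np.full_like(t, 0.2)
    for s in sphase:
        v = v + 0.8 * np.exp(-0.5 * ((t - s) / 1.5) ** 2)
    return np.maximum(v + noise, 0.0)


def _p21_channel(rng, p: RegimeParams, t: np.ndarray, mitoses: np.ndarray,
                 dips: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """p21: high in G1, sigmoidal decline shortly after the HES1 dip,
    resetting at each mitosis."""
    v = np.full_like(t, 1.0)
    bounds = np.concatenate([[t[0]], mitoses, [t[-1] + 1.0]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_seg = (t >= lo) & (t < hi)
        if not np.any(in_seg):
            continue
        seg_dips = dips[(dips >= lo) & (dips < hi)]
        if len(seg_dips) == 0:
            continue
        d = seg_dips[0] + rng.normal(p.p21_decline_delay_mean, p.p21_decline_delay_sd)
        drop = 1.0 / (1.0 + np.exp(-(t[in_seg] - d) / 0.4))
        v[in_seg] = 1.0 - 0.8 * drop
    return np.maximum(v + noise, 0.0)


# ---------------------------------------------------------------------------
# public API

_MAKERS = {
    "proliferative": _make_proliferative,
    "arrested": _make_arrested,
    "control_nls": _make_control,
}


def simulate_cohort(regime: RegimeParams, n_cells: int, n_replicates: int,
                    duration: float, dt: float, seed: int,
                    gated: Optional[bool] = None) -> Cohort:
    """Simulate a cohort of ``n_replicates`` x ``n_cells`` traces.

    ``gated`` overrides the division rule for released-type regimes: when
    True, division is decided by the dip-gate threshold (24 h assay rule)
    instead of the unconditional reentry lognormal.  Misexpression is
    always gated.

    Raises :class:`ParameterError` for negative counts or dt <= 0.
    """
    p = regime.validated()
    if n_cells < 0 or n_replicates < 0:
        raise ParameterError("n_cells and n_replicates must be >= 0")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    n_samples = int(round(duration / dt)) + 1
    if n_samples < 2:
        raise ParameterError("duration/dt must give at least 2 samples")

    t = np.arange(n_samples) * dt
    ss = np.random.SeedSequence([int(seed), n_cells, n_replicates])
    children = ss.spawn(max(n_replicates * n_cells, 1))
    traces: list[Trace] = []
    channel_cond = p.regime if p.regime in ("proliferative", "arrested",
                                            "released", "misexpression") else "control_nls"
    main_channel = "control" if p.regime == "control_nls" else "hes1_endo"

    for r in range(n_replicates):
        rep_id = f"R{r + 1}"
        for c in range(n_cells):
            rng = np.random.default_rng(children[r * n_cells + c])
            cell_id = f"{rep_id}C{c + 1:04d}"
            ou = _ou(rng, n_samples, dt, p.ou_sd, p.ou_tau)
            white = rng.normal(0.0, p.noise_sd, size=n_samples) if p.noise_sd else np.zeros(n_samples)
            if p.regime in ("released", "misexpression"):
                is_gated = (p.regime == "misexpression") if gated is None else gated
                info = _make_released(rng, p, t, gated=is_gated,
                                      exogenous=(p.regime == "misexpression"),
                                      noise_ou=ou, noise_w=white)
            else:
                info = _MAKERS[p.regime](rng, p, t)
            vals = np.maximum(info["det"] + ou + white, 0.0)
            common = dict(cell_id=cell_id, replicate_id=rep_id,
                          condition=channel_cond, times=t,
                          mitosis_times=info["mitoses"],
                          sphase_times=info["sphase"],
                          release_time=info["release"])
            traces.append(Trace(channel=main_channel, values=vals, **common))
            if "exo_det" in info:
                exo_ou = _ou(rng, n_samples, dt, p.ou_sd, p.ou_tau)
                exo_w = rng.normal(0.0, p.noise_sd, size=n_samples)
                exo_vals = np.maximum(info["exo_det"] + exo_ou + exo_w, 0.0)
                traces.append(Trace(channel="hes1_exo", values=exo_vals, **common))
                traces.append(Trace(channel="hes1_total",
                                    values=vals + exo_vals, **common))
            if p.include_cochannels and len(info["sphase"]):
                n1 = rng.normal(0.0, 0.02, size=n_samples)
                traces.append(Trace(channel="cdk2",
                                    values=_cdk2_channel(rng, p, t, info["sphase"], n1),
                                    **common))
                n2 = rng.normal(0.0, 0.02, size=n_samples)
                traces.append(Trace(channel="p21",
                                    values=_p21_channel(rng, p, t, info["mitoses"],
                                                        info["dips"], n2),
                                    **common))

    provenance = {"generator": "hesdyn.simulate", "seed": int(seed),
                  "regime": p.regime, "n_cells": n_cells,
                  "n_replicates": n_replicates, "duration": duration, "dt": dt,
                  "params": dataclasses.asdict(p)}
    return Cohort(traces=traces, dt=dt, duration=duration, provenance=provenance)


def simulate_release_assay(n_cells: int, n_replicates: int, seed: int,
                           duration: float = 48.0, dt: float = 0.25,
                           release_time: float = 12.0) -> tuple[Cohort, Cohort]:
    """Simulate the 24 h misexpression release assay.

    Returns ``(control, misexpression)`` cohorts: released-regime control
    cells without the exogenous channel, and Tet-positive cells with the
    anti-phase exogenous channel added — both with division gated on the
    dip-threshold rule.
    """
    defaults = calibrate_defaults()
    ctrl = dataclasses.replace(defaults["released"], release_time=release_time)
    mis = dataclasses.replace(defaults["misexpression"], release_time=release_time)
    control = simulate_cohort(ctrl, n_cells, n_replicates, duration, dt,
                              seed=seed, gated=True)
    tet = simulate_cohort(mis, n_cells, n_replicates, duration, dt,
                          seed=seed + 10_000)
    return control, tet
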