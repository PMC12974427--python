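"""Generator structure: waveform geometry, regime calibration anchors,
annotation consistency, determinism."""

import dataclasses

import numpy as np
import pytest

from hesdyn import ParameterError, simulate_cohort, validate
from hesdyn.simulate import (CC_DIP_FRACTION, RegimeParams, calibrate_defaults,
                             cycle_waveform)


def noise_free(regime="proliferative", **overrides):
    return dataclasses.replace(
        RegimeParams(regime=regime), noise_sd=0.0, ou_sd=0.0,
        ultradian_amplitude=0.0, ultradian_amplitude_arrested=0.0,
        snd_fraction=0.0, **overrides)


class TestWaveform:
    def test_minimum_at_u_dip_with_known_depth(self):
        u = np.linspace(0.0, 1.0, 100_001)
        for u_dip in (0.4, 0.5, 0.6):
            w = cycle_waveform(u, u_dip)
            k = np.argmin(w)
            assert abs(u[k] - u_dip) < 1e-4
            assert w[k] == pytest.approx(-CC_DIP_FRACTION, abs=1e-8)
            assert w.max() == pytest.approx(1.0, abs=1e-6)

    def test_single_interior_minimum(self):
        u = np.linspace(0.0, 1.0, 10_001)[1:-1]
        w = cycle_waveform(u, 0.5)
        interior_minima = np.flatnonzero((w[1:-1] < w[:-2]) & (w[1:-1] <= w[2:]))
        assert len(interior_minima) == 1

    def test_zero_mean_over_cycle(self):
        u = (np.arange(10_000) + 0.5) / 10_000
        assert abs(cycle_waveform(u, 0.47).mean()) < 1e-6


class TestDefaults:
    def test_paper_anchored_constants(self):
        d = calibrate_defaults()
        assert d["proliferative"].cycle_length_median == 23.3
        assert d["released"].release_dip_foldchange == 2.2
        assert d["released"].reentry_median == 19.0
        assert d["released"].release_dip_time_range == (8.0, 10.0)
        assert d["proliferative"].dip_lead_range == (10.0, 14.0)
        assert d["arrested"].arrest_level_factor == 1.4

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            RegimeParams(regime="nonsense").validated()
        with pytest.raises(ParameterError):
            RegimeParams(dip_gate_threshold=1.5).validated()
        with pytest.raises(ParameterError):
            simulate_cohort(RegimeParams(), -1, 1, 48.0, 0.25, seed=1)
        with pytest.raises(ParameterError):
            simulate_cohort(RegimeParams(), 1, 1, 48.0, -0.25, seed=1)


class TestStructure:
    def test_empty_cohort_keeps_provenance(self):
        c = simulate_cohort(RegimeParams(), 0, 3, 48.0, 0.25, seed=5)
        assert len(c) == 0
        assert c.provenance["seed"] == 5
        assert c.provenance["regime"] == "proliferative"

    def test_simulated_cohorts_pass_validation(self):
        for regime in ("proliferative", "arrested", "released",
                       "misexpression", "control_nls"):
            c = simulate_cohort(calibrate_defaults()[regime], 5, 1, 72.0, 0.25, seed=2)
            assert validate(c) == [], regime

    def test_same_seed_is_byte_identical(self):
        p = RegimeParams(regime="released")
        a = simulate_cohort(p, 4, 2, 72.0, 0.25, seed=11)
        b = simulate_cohort(p, 4, 2, 72.0, 0.25, seed=11)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.values, tb.values)
            assert np.array_equal(ta.mitosis_times, tb.mitosis_times)

    def test_different_seeds_differ(self):
        p = RegimeParams()
        a = simulate_cohort(p, 2, 1, 48.0, 0.25, seed=1)
        b = simulate_cohort(p, 2, 1, 48.0, 0.25, seed=2)
        assert not np.array_equal(a.traces[0].values, b.traces[0].values)

    def test_sphase_onsets_lie_between_mitoses_or_after_release(self):
        for regime in ("proliferative", "released"):
            c = simulate_cohort(calibrate_defaults()[regime], 20, 1, 96.0, 0.25, seed=3)
            for tr in c.traces:
                for s in tr.sphase_times:
                    lo = tr.release_time if tr.release_time is not None else tr.times[0]
                    bounds = np.concatenate([[lo], tr.mitosis_times, [tr.times[-1]]])
                    k = np.searchsorted(bounds, s)
                    assert 0 < k <= len(bounds) - 1
                    assert bounds[k - 1] < s < bounds[k] + 1e-9


class TestNoiseFreeGeometry:
    def test_minimum_exactly_dip_lead_before_later_mitosis(self):
        p = noise_free(cycle_length_median=24.0, cycle_length_sigma_log=0.0,
                       dip_lead_range=(12.0, 12.0))
        c = simulate_cohort(p, 5, 1, 96.0, 0.25, seed=9)
        checked = 0
        for tr in c.traces:
            for m0, m1 in zip(tr.mitosis_times[:-1], tr.mitosis_times[1:]):
                sel = (tr.times > m0) & (tr.times < m1)
                seg_t = tr.times[sel]
                t_min = seg_t[np.argmin(tr.values[sel])]
                # sampled minimum is the grid point nearest the true dip
                assert abs(t_min - (m1 - 12.0)) <= 0.125 + 1e-9
                checked += 1
        assert checked >= 10

    def test_noise_free_minimum_value_is_baseline_times_dip_depth(self):
        p = noise_free(cycle_length_median=24.0, cycle_length_sigma_log=0.0)
        c = simulate_cohort(p, 3, 1, 96.0, 0.05, seed=4)
        expected = p.baseline * (1.0 - p.cc_amplitude * CC_DIP_FRACTION)
        for tr in c.traces:
            inner = (tr.times > tr.mitosis_times[0]) & (tr.times < tr.mitosis_times[-1])
            assert tr.values[inner].min() == pytest.approx(expected, abs=0.01)

    def test_released_trace_continuous_at_release(self):
        p = noise_free("released")
        c = simulate_cohort(p, 8, 1, 96.0, 0.25, seed=6)
        for tr in c.traces:
            i = tr.nearest_index(p.release_time)
            jump = abs(tr.values[i + 1] - tr.values[i])
            # bounded by the steepest deterministic dip slope over one sample
            assert jump < 4.0

    def test_arrested_level_is_scaled_baseline(self):
        p = noise_free("arrested")
        c = simulate_cohort(p, 3, 1, 48.0, 0.25, seed=8)
        for tr in c.traces:
            assert np.allclose(tr.values, 140.0)
            assert len(tr.mitosis_times) == 0


class TestCalibrationAnchors:
    def test_arrest_raises_mean_level_14_fold_over_cycling_cells(self):
        d = calibrate_defaults()
        pro = simulate_cohort(d["proliferative"], 90, 3, 96.0, 0.25, seed=1)
        arr = simulate_cohort(d["arrested"], 90, 3, 96.0, 0.25, seed=1)
        cycling = np.concatenate([tr.values for tr in pro.traces
                                  if len(tr.mitosis_times) > 0])
        arrested = np.concatenate([tr.values for tr in arr.traces])
        assert arrested.mean() / cycling.mean() == pytest.approx(1.4, abs=0.05)

    def test_misexpression_total_channel_less_variable_than_endogenous(self):
        c = simulate_cohort(calibrate_defaults()["misexpression"], 30, 1,
                            48.0, 0.25, seed=2)
        endo = {tr.cell_id: tr for tr in c.traces if tr.channel == "hes1_endo"}
        total = {tr.cell_id: tr for tr in c.traces if tr.channel == "hes1_total"}
        var_endo = np.mean([endo[k].values.std() for k in endo])
        var_total = np.mean([total[k].values.std() for k in endo])
        assert var_total < var_endo

    def test_exogenous_channel_antiphase_with_endogenous(self):
        c = simulate_cohort(calibrate_defaults()["misexpression"], 20, 1,
                            48.0, 0.25, seed=3)
        endo = {tr.cell_id: tr for tr in c.traces if tr.channel == "hes1_endo"}
        exo = {tr.cell_id: tr for tr in c.traces if tr.channel == "hes1_exo"}
        corrs = [np.corrcoef(endo[k].values, exo[k].values)[0, 1] for k in endo]
        assert np.mean(corrs) < -0.3
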