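"""Extremum detection, fold-changes, phase relations, reentry and levels."""

import numpy as np
import pytest

from hesdyn import (AnnotationError, ParameterError, detect_extrema,
                    division_fractions, intensity_stats, peak_dip_amplitudes,
                    phase_pairs, reentry_stats, release_dip_foldchange)
from hesdyn.events import EventRecord
from hesdyn.preprocess import isolate_band
from hesdyn.report import _pooled

from conftest import as_cohort, make_trace, sinusoid_trace


class TestDetectExtrema:
    def test_sinusoid_four_peaks_four_dips_alternating(self):
        tr = sinusoid_trace(period=24.0, duration=96.0)
        events = detect_extrema(tr, prominence=0.5)
        kinds = [e.kind for e in events]
        assert kinds.count("peak") == 4 and kinds.count("dip") == 4
        assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))

    def test_monotone_ramp_has_no_events(self):
        assert detect_extrema(make_trace(np.arange(100.0)), 0.5) == []

    def test_small_noise_keeps_event_count(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 96.0, 0.25)
        clean = make_trace(np.sin(2 * np.pi * t / 24) + 5)
        noisy = make_trace(clean.values + rng.normal(0, 0.05, len(t)))
        assert len(detect_extrema(noisy, 0.5)) == len(detect_extrema(clean, 0.5))


class TestAmplitudes:
    def test_sinusoid_amplitudes_are_twice_amplitude(self):
        tr = sinusoid_trace(period=24.0, duration=96.0, amplitude=1.5)
        amps = peak_dip_amplitudes(detect_extrema(tr, 0.5))
        assert len(amps) >= 3
        assert np.allclose(amps, 3.0, atol=0.01)

    def test_empty_event_list_gives_empty_amplitudes(self):
        assert len(peak_dip_amplitudes([])) == 0

    def test_non_alternating_events_rejected(self):
        evs = [EventRecord("c", "peak", 1.0, 2.0), EventRecord("c", "peak", 2.0, 2.5)]
        with pytest.raises(ParameterError):
            peak_dip_amplitudes(evs)

    def test_arrest_amplitude_ordering(self, prolif_cohort, arrested_cohort, config):
        """Arrest enhances ultradian dip amplitudes, but they stay smaller
        than the G1/S-associated dips of cycling cells.

        Extrema are detected on z-scored band-isolated traces (so the
        prominence threshold scales with each trace) and amplitudes are
        read off the detrended traces in a.u.
        """
        from hesdyn.preprocess import zscore_values

        def median_amp(traces, band):
            amps = []
            for tr in traces:
                iso = isolate_band(tr, band, config)
                au = iso.values.copy()
                iso.values = zscore_values(iso.values)
                evs = detect_extrema(iso, config.dip_prominence)
                idx = {e.time: tr.nearest_index(e.time) for e in evs}
                amps.extend(au[idx[a.time]] - au[idx[b.time]]
                            for a, b in zip(evs[:-1], evs[1:])
                            if a.kind == "peak" and b.kind == "dip")
            return np.median(amps)

        cycling = [tr for tr in prolif_cohort.traces if len(tr.mitosis_times) > 0]
        ultra_arr = median_amp(arrested_cohort.traces, "ultradian_isolated")
        ultra_pro = median_amp(cycling, "ultradian_isolated")
        circ_pro = median_amp(cycling, "circadian_isolated")
        assert ultra_arr > ultra_pro
        assert circ_pro > ultra_arr


class TestReleaseFoldChange:
    def test_constructed_two_fold_dip(self):
        vals = np.concatenate([np.full(20, 200.0),
                               np.linspace(200, 100, 20),
                               np.linspace(100, 210, 20)])
        tr = make_trace(vals, release_time=0.25 * 19, mitosis_times=[0.25 * 55])
        assert release_dip_foldchange(tr) == pytest.approx(2.0)

    def test_monotone_increasing_trace_gives_one(self):
        tr = make_trace(np.linspace(100, 200, 80), release_time=2.0)
        assert release_dip_foldchange(tr) == 1.0

    def test_fold_is_at_least_one(self, released_cohort):
        folds = [release_dip_foldchange(tr) for tr in released_cohort.traces]
        assert min(folds) >= 1.0

    def test_release_beyond_trace_end_rejected(self):
        tr = make_trace(np.ones(40), release_time=100.0)
        with pytest.raises(ParameterError):
            release_dip_foldchange(tr)

    def test_missing_release_annotation_rejected(self):
        with pytest.raises(AnnotationError):
            release_dip_foldchange(make_trace(np.ones(40)))


class TestPhasePairs:
    def test_identical_times_fully_coincident(self):
        tr = make_trace(np.ones(200), mitosis_times=[10.0], sphase_times=[10.0])
        res = phase_pairs(as_cohort([tr]), "mitosis", "sphase_onset", tol=1.0)
        assert res["fractions"]["coincident"] == 1.0

    def test_normal_offsets_match_closed_form(self):
        # offsets ~ N(1.0, 1.6); P(a first or |offset|<=1) = Phi(2/1.6)
        rng = np.random.default_rng(7)
        n = 4000
        traces, ea, eb = [], {}, {}
        for i in range(n):
            cid = f"c{i}"
            traces.append(make_trace(np.ones(8), cell_id=cid))
            ea[cid] = [10.0]
            eb[cid] = [10.0 + rng.normal(1.0, 1.6)]
        res = phase_pairs(as_cohort(traces), "dip", "sphase_onset", tol=1.0,
                          events_a=ea, events_b=eb)
        from scipy.stats import norm
        expected = norm.cdf(2.0 / 1.6)
        assert res["fractions"]["a_first_or_coincident"] == pytest.approx(
            expected, abs=0.02)

    def test_classification_symmetric_under_swap(self):
        tr = make_trace(np.ones(100), mitosis_times=[5.0], sphase_times=[8.0])
        c = as_cohort([tr])
        ab = phase_pairs(c, "mitosis", "sphase_onset", tol=1.0)
        ba = phase_pairs(c, "sphase_onset", "mitosis", tol=1.0)
        assert ab["pairs"][0].offset == -ba["pairs"][0].offset
        assert ab["fractions"]["a_first"] == ba["fractions"]["b_first"]

    def test_cells_missing_events_counted_not_paired(self):
        with_s = make_trace(np.ones(50), cell_id="a", mitosis_times=[2.0],
                            sphase_times=[3.0])
        without = make_trace(np.ones(50), cell_id="b", mitosis_times=[2.0])
        res = phase_pairs(as_cohort([with_s, without]), "mitosis", "sphase_onset")
        assert res["n_pairs"] == 1 and res["n_excluded_cells"] == 1

    def test_detected_dip_precedes_sphase_in_released_cells(self, released_cohort):
        res = phase_pairs(released_cohort, "dip", "sphase_onset", tol=1.0)
        assert res["n_pairs"] > 100
        assert res["fractions"]["a_first_or_coincident"] > 0.8


class TestReentry:
    def test_all_cells_dividing_at_18h(self):
        traces = [make_trace(np.ones(300), cell_id=f"c{i}", release_time=10.0,
                             mitosis_times=[28.0]) for i in range(10)]
        res = reentry_stats(as_cohort(traces), window=30.0)
        assert res["fraction"] == 1.0
        counts, edges = res["hist"]
        assert counts[18] == 10 and counts.sum() == 10

    def test_fraction_monotone_in_window(self, released_cohort):
        fracs = [reentry_stats(released_cohort, window=w)["fraction"]
                 for w in (12.0, 18.0, 24.0, 30.0, 40.0)]
        assert all(a <= b for a, b in zip(fracs[:-1], fracs[1:]))

    def test_missing_release_time_rejected(self):
        with pytest.raises(AnnotationError):
            reentry_stats(as_cohort([make_trace(np.ones(50))]), window=30.0)


class TestDivisionFractions:
    def test_no_mitoses_gives_zero(self):
        c = as_cohort([make_trace(np.ones(100), cell_id=f"c{i}") for i in range(4)])
        assert division_fractions(c, window=20.0, k=1) == 0.0

    def test_every_cell_twice_gives_one_for_both_k(self):
        c = as_cohort([make_trace(np.ones(300), cell_id=f"c{i}",
                                  mitosis_times=[10.0, 30.0]) for i in range(4)])
        assert division_fractions(c, window=70.0, k=1) == 1.0
        assert division_fractions(c, window=70.0, k=2) == 1.0

    def test_default_cohort_quarter_nondividing(self, defaults):
        cohort = _pooled(defaults["proliferative"], 80, 100.0, 0.25, [1, 2, 3])
        frac = division_fractions(cohort, window=100.0, k=1)
        assert frac == pytest.approx(0.75, abs=0.08)


class TestIntensityStats:
    def test_cohort_vs_itself_gives_unit_folds(self, prolif_cohort):
        res = intensity_stats(prolif_cohort, prolif_cohort)
        assert all(v == 1.0 for v in res["folds"].values())

    def test_arrest_fold_changes(self, arrested_cohort, prolif_cohort):
        res = intensity_stats(arrested_cohort, prolif_cohort)
        assert res["folds"]["mean"] == pytest.approx(1.4, abs=0.1)
        assert res["folds"]["max"] == pytest.approx(1.1, abs=0.1)
        assert res["folds"]["min"] == pytest.approx(1.6, abs=0.1)

    def test_empty_reference_rejected(self, prolif_cohort):
        from hesdyn import Cohort
        with pytest.raises(ParameterError):
            intensity_stats(prolif_cohort, Cohort([], 0.25, 0.0))
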