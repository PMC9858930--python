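"""Beat metrics, arrhythmia detectors, Welch test, synthetic fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sparkcell.analysis import (SyntheticSpec, apd, beat_table,
                                detect_alternans, detect_eads,
                                generate_synthetic_trace, segment_beats,
                                spark_statistics, transient_stats,
                                welch_ttest)


def synth(**kw):
    return generate_synthetic_trace(SyntheticSpec(**kw))


class TestSegmentation:
    def test_ten_windows_at_1hz(self):
        trace, _ = synth(n_beats=10)
        windows = segment_beats(trace)
        assert len(windows) == 10
        for w in windows[:-1]:
            assert w.t_end - w.t_stim == pytest.approx(1.0, abs=1e-6)

    def test_missing_upstroke_flagged(self):
        trace, _ = synth(n_beats=6, skipped_beats=(2,))
        windows = segment_beats(trace)
        assert [w.captured for w in windows] == [True, True, False, True,
                                                 True, True]

    def test_empty_trace_rejected(self):
        trace, _ = synth(n_beats=2)
        trace.df = trace.df.iloc[0:0]
        with pytest.raises(ValueError):
            segment_beats(trace)


class TestAPD:
    def test_trapezoid_closed_form(self):
        """Instant rise to +40, 200 ms plateau, linear fall to −85 over
        100 ms: APD90 = 200 + fraction of the ramp down to the 90% level."""
        dt = 0.5
        t = np.arange(0, 400, dt)
        v = np.full_like(t, -85.0)
        v[(t >= 10) & (t < 210)] = 40.0
        ramp = (t >= 210) & (t < 310)
        v[ramp] = 40.0 - (t[ramp] - 210.0) / 100.0 * 125.0
        # level = 40 − 0.9·125 = −72.5 → crossing 90 ms into the ramp
        expect = (210.0 + 90.0) - 10.0
        assert apd(t * 1e-3, v) == pytest.approx(expect, abs=2 * dt)

    def test_constant_voltage_undefined(self):
        t = np.arange(0, 100) * 1e-3
        assert np.isnan(apd(t, np.full(100, -85.0)))

    def test_synthetic_apd_recovered(self):
        trace, truth = synth(n_beats=4, apd_ms=150.0)
        windows = segment_beats(trace)
        for w, expected in zip(windows, truth.apd_per_beat):
            sl = w.slice_
            got = apd(trace.time_s[sl], trace.v[sl])
            assert got == pytest.approx(expected, abs=3.0)

    @settings(deadline=None, max_examples=30)
    @given(shift_ms=st.floats(-50, 50), offset_mv=st.floats(-20, 20))
    def test_time_shift_and_voltage_offset_invariance(self, shift_ms,
                                                      offset_mv):
        trace, _ = synth(n_beats=1, apd_ms=160.0)
        w = segment_beats(trace)[0]
        t = trace.time_s[w.slice_]
        v = trace.v[w.slice_]
        base = apd(t, v)
        # invariance holds to sample resolution (1 ms): an offset can flip a
        # floating-point tie at the crossing sample
        assert apd(t + shift_ms * 1e-3, v + offset_mv) == \
            pytest.approx(base, abs=1.1)


class TestTransients:
    def test_constant_trace(self):
        out = transient_stats(np.full(50, 0.2))
        assert out["ca_max"] == out["ca_diastolic"] == pytest.approx(0.2)

    def test_raised_cosine_peak_exact(self):
        trace, truth = synth(n_beats=3, ca_amplitude=0.5, ca_diastolic=0.12)
        windows = segment_beats(trace)
        ca = trace.df["ca_myo"].to_numpy()
        for w, peak in zip(windows, truth.ca_peak_per_beat):
            out = transient_stats(ca[w.slice_])
            assert out["ca_max"] == pytest.approx(peak, abs=1e-9)
            assert out["ca_diastolic"] == pytest.approx(0.12, abs=1e-9)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            transient_stats(np.array([]))


class TestEADs:
    def test_monotone_repolarization_clean(self):
        trace, _ = synth(n_beats=3)
        for w in segment_beats(trace):
            assert detect_eads(trace.time_s[w.slice_],
                               trace.v[w.slice_]) == []

    def test_injected_bump_detected_once(self):
        trace, _ = synth(n_beats=5, ead_beats=(2,), ead_rise_mv=5.0)
        counts = []
        for w in segment_beats(trace):
            evs = detect_eads(trace.time_s[w.slice_], trace.v[w.slice_])
            counts.append(len(evs))
        assert counts == [0, 0, 1, 0, 0]

    def test_bump_below_min_rise_ignored(self):
        trace, _ = synth(n_beats=3, ead_beats=(1,), ead_rise_mv=1.0)
        w = segment_beats(trace)[1]
        assert detect_eads(trace.time_s[w.slice_], trace.v[w.slice_],
                           min_rise=2.0) == []


class TestAlternans:
    def test_constant_sequence_not_detected(self):
        rep = detect_alternans([150.0] * 8)
        assert not rep.detected

    def test_printed_alternans_durations(self):
        """Alternating long/short APDs (157, 131, 156, 132, 156, 139 ms) are
        detected; the mean |Δ| over the five consecutive differences is
        23.2 ms (direct computation)."""
        seq = [157.0, 131.0, 156.0, 132.0, 156.0, 139.0]
        diffs = np.abs(np.diff(seq))
        rep = detect_alternans(seq)
        assert rep.detected
        assert rep.magnitude == pytest.approx(diffs.mean())
        assert rep.magnitude == pytest.approx(23.2)

    def test_monotone_ramp_not_detected(self):
        rep = detect_alternans(np.linspace(100, 200, 10))
        assert not rep.detected

    def test_threshold_gates_detection(self):
        seq = [100.0, 101.0, 100.0, 101.0, 100.0, 101.0]
        assert not detect_alternans(seq, rel_threshold=0.05).detected
        assert detect_alternans(seq, rel_threshold=0.005).detected

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            detect_alternans([1.0, 2.0, 1.0])


class TestSparkStatistics:
    def test_no_events(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["cru_id", "start_s", "end_s",
                                      "peak_open_ryr", "peak_ca_ds"])
        st_ = spark_statistics(empty, n_cru=100, t_window=(0.0, 1.0))
        assert st_.n_events == 0
        assert st_.rate_per_s == 0.0

    def test_rescaling_arithmetic(self):
        import pandas as pd
        ev = pd.DataFrame({"cru_id": np.zeros(100, dtype=int),
                           "start_s": np.linspace(0, 9.99, 100),
                           "end_s": np.linspace(0.01, 10.0, 100),
                           "peak_open_ryr": 5,
                           "peak_ca_ds": 50.0})
        st_ = spark_statistics(ev, n_cru=2000, t_window=(0.0, 10.0))
        assert st_.rate_per_s == pytest.approx(10.0)
        assert st_.full_scale_rate_per_s == pytest.approx(100.0)


class TestWelch:
    def test_identical_samples(self):
        r = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        va = np.var(a, ddof=1) / 4
        vb = np.var(b, ddof=1) / 4
        t_expect = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
        df_expect = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
        r = welch_ttest(a, b)
        assert r.t == pytest.approx(t_expect, rel=1e-12)
        assert r.df == pytest.approx(df_expect, rel=1e-12)

    def test_matches_reference_implementation(self, rng):
        from scipy import stats
        for _ in range(20):
            a = rng.normal(0.0, 1.0, size=rng.integers(5, 40))
            b = rng.normal(0.3, 2.0, size=rng.integers(5, 40))
            ref = stats.ttest_ind(a, b, equal_var=False)
            r = welch_ttest(a, b)
            assert r.t == pytest.approx(float(ref.statistic), rel=1e-10)
            assert r.p == pytest.approx(float(ref.pvalue), rel=1e-10)

    def test_zero_variance_convention(self):
        r = welch_ttest([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])


class TestSyntheticSpec:
    def test_contradictory_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(ead_beats=(3,), skipped_beats=(3,))

    def test_clean_spec_all_detectors_negative(self):
        trace, _ = synth(n_beats=8)
        beats = beat_table(trace)
        assert all(b.captured for b in beats)
        assert sum(b.ead_count for b in beats) == 0
        apds = [b.apd90 for b in beats]
        assert not detect_alternans(apds).detected

    def test_injected_alternans_magnitude(self):
        trace, _ = synth(n_beats=8, apd_ms=150.0, alternans_delta_ms=20.0)
        beats = beat_table(trace)
        rep = detect_alternans([b.apd90 for b in beats])
        assert rep.detected
        assert rep.magnitude == pytest.approx(20.0, abs=1.0)

    def test_skipped_indices_recovered(self):
        trace, _ = synth(n_beats=8, skipped_beats=(3, 5))
        windows = segment_beats(trace)
        assert [w.index for w in windows if not w.captured] == [3, 5]
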