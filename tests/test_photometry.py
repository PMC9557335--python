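import numpy as np
import pytest

from treadscore.photometry import (
    PeakParams,
    PhotometryProcessor,
    ProcessedTrace,
    RawPhotometry,
    SignalQualityError,
    acceleration_triggered_average,
    detect_events,
    downsample,
    epoch_stats,
    isosbestic_correct,
    normalize_dff,
    peri_event_average,
    process,
)
from treadscore.synthetic import transient_train


def bruteforce_prominences(x):
    """Independent prominence scan: walk to higher ground on both sides."""
    peaks, proms = [], []
    for i in range(1, len(x) - 1):
        if not (x[i] > x[i - 1] and x[i] > x[i + 1]):
            continue
        h = x[i]
        higher_left = np.flatnonzero(x[:i] > h)
        lo = higher_left[-1] + 1 if higher_left.size else 0
        left_base = x[lo : i + 1].min()
        higher_right = np.flatnonzero(x[i + 1 :] > h)
        hi = i + 1 + higher_right[0] if higher_right.size else len(x)
        right_base = x[i:hi].min()
        peaks.append(i)
        proms.append(h - max(left_base, right_base))
    return np.array(peaks), np.array(proms)


def bruteforce_events(x, prominence_min=0.02, min_sep=60):
    """Greedy suppression oracle: highest prominence first, earlier on ties."""
    peaks, proms = bruteforce_prominences(x)
    keep = proms > prominence_min
    peaks, proms = peaks[keep], proms[keep]
    order = sorted(range(len(peaks)), key=lambda k: (-proms[k], peaks[k]))
    accepted = []
    for k in order:
        if all(abs(peaks[k] - a) >= min_sep for a, _ in accepted):
            accepted.append((peaks[k], proms[k]))
    return sorted(accepted)


def make_trace(dff, rate=30.0):
    return ProcessedTrace(
        time=np.arange(len(dff)) / rate, dff=np.asarray(dff, float), params=PeakParams()
    )


class TestDownsample:
    def test_constant_preserved(self):
        out = downsample(np.full(3000, 4.2), 300.0)
        assert len(out) == 300
        np.testing.assert_allclose(out, 4.2)

    def test_sample_counting(self):
        assert len(downsample(np.zeros(300), 300.0)) == 30

    def test_slow_sinusoid_amplitude_within_one_percent(self):
        t = np.arange(0, 20, 1 / 300)
        s = np.sin(2 * np.pi * 0.2 * t)
        out = downsample(s, 300.0)
        assert out.max() == pytest.approx(1.0, abs=0.01)

    def test_fractional_rate_ratio(self):
        out = downsample(np.ones(1001), 100.1)
        assert len(out) == int(np.floor(1001 / 100.1 * 30))
        np.testing.assert_allclose(out, 1.0)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            downsample(np.zeros(100), 10.0)


class TestNormalizeDff:
    def test_constant_maps_to_zero(self):
        np.testing.assert_allclose(normalize_dff(np.full(200, 7.0)), 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = 10 + rng.normal(0, 0.5, 400)
        np.testing.assert_allclose(normalize_dff(x), normalize_dff(3.7 * x), atol=1e-12)

    def test_impulse_matches_direct_formula(self):
        x = np.full(300, 2.0)
        x[150] = 3.0
        got = normalize_dff(x, baseline_window=125)
        # sample-by-sample evaluation of (F - B)/B with a centered,
        # edge-truncated window
        for i in [0, 80, 149, 150, 151, 250, 299]:
            lo = max(0, i - 62)
            hi = min(300, i + 63)
            b = x[lo:hi].mean()
            assert got[i] == pytest.approx((x[i] - b) / b)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            normalize_dff(np.ones(100), baseline_window=125)

    def test_nonpositive_baseline_rejected(self):
        x = np.concatenate([np.full(100, 1.0), np.full(100, -1.5)])
        with pytest.raises(SignalQualityError):
            normalize_dff(x, baseline_window=50)


class TestIsosbesticCorrect:
    def test_identical_channels_cancel(self):
        x = np.random.default_rng(1).normal(size=100)
        np.testing.assert_allclose(isosbestic_correct(x, x), 0.0)

    def test_zero_reference_is_identity(self):
        x = np.random.default_rng(1).normal(size=100)
        np.testing.assert_array_equal(isosbestic_correct(x, np.zeros(100)), x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            isosbestic_correct(np.zeros(5), np.zeros(6))

    def test_common_mode_artifact_cancels_post_normalization(self):
        rng = np.random.default_rng(2)
        artifact = np.zeros(900)
        artifact[300:330] = 0.3
        signal = transient_train(30.0, [10.0], [0.05])
        dff465 = normalize_dff(100 * (1 + signal + artifact))
        dff405 = normalize_dff(80 * (1 + artifact))
        clean465 = normalize_dff(100 * (1 + signal))
        corrected = isosbestic_correct(dff465, dff405)
        assert np.abs(corrected - clean465).max() < 5e-3


class TestDetectEvents:
    def test_flat_trace_no_events(self):
        assert detect_events(np.zeros(1000)) == []

    def test_templated_transients_recovered_exactly(self):
        times = np.arange(5.0, 55.0, 5.0)
        tr = transient_train(60, times, np.full(10, 0.05))
        events = detect_events(tr)
        assert len(events) == 10
        np.testing.assert_allclose([e.t_peak for e in events], times, atol=1 / 30)
        assert all(e.prominence > 0.02 for e in events)

    def test_close_pair_keeps_higher_prominence(self):
        tr = transient_train(20, [8.0, 9.0], [0.05, 0.03])
        events = detect_events(tr)
        assert len(events) == 1
        assert events[0].t_peak == pytest.approx(8.0, abs=1 / 30)
        assert events[0].prominence == pytest.approx(0.05, rel=0.05)

    def test_prominence_floor_is_strict(self):
        tr = transient_train(40, [10.0, 30.0], [0.019, 0.05])
        events = detect_events(tr)
        assert len(events) == 1

    def test_matches_bruteforce_oracle_on_random_traces(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(120, 1200))
            x = np.convolve(rng.normal(0, 0.03, n), np.ones(7) / 7, mode="same")
            got = [(e.index, e.prominence) for e in detect_events(x)]
            expected = bruteforce_events(x)
            assert [g[0] for g in got] == [e[0] for e in expected]
            np.testing.assert_allclose(
                [g[1] for g in got], [e[1] for e in expected], rtol=1e-10
            )

    def test_separation_and_floor_hold_on_any_output(self):
        rng = np.random.default_rng(10)
        x = np.cumsum(rng.normal(0, 0.01, 5000))
        events = detect_events(x)
        idx = np.array(sorted(e.index for e in events))
        assert np.all(np.diff(idx) >= 60)
        assert all(e.prominence > 0.02 for e in events)


class TestPipelineScaleInvariance:
    def test_gain_change_leaves_events_unchanged(self):
        from treadscore.synthetic import SyntheticPhotometryConfig, simulate_photometry

        raw, _ = simulate_photometry(
            SyntheticPhotometryConfig(seed=5), duration=120.0
        )
        scaled = RawPhotometry(
            time=raw.time, f465=17.0 * raw.f465, f405=17.0 * raw.f405, rate=raw.rate
        )
        ev1 = detect_events(process(raw).dff)
        ev2 = detect_events(process(scaled).dff)
        assert [e.index for e in ev1] == [e.index for e in ev2]
        np.testing.assert_allclose(
            [e.amplitude for e in ev1], [e.amplitude for e in ev2], atol=1e-12
        )


class TestEpochStats:
    def _events(self, times, amp=0.05):
        from treadscore.photometry import CalciumEvent

        return [CalciumEvent(t, amp, amp) for t in times]

    def test_rate_arithmetic(self):
        trace = make_trace(np.zeros(360 * 30))
        ev = self._events(np.linspace(35, 320, 10))
        stats = epoch_stats(ev, trace, {"on_time": [(30.0, 330.0)]})
        assert stats[0].n_events == 10
        assert stats[0].rate == pytest.approx(2.0)

    def test_pooled_windows(self):
        trace = make_trace(np.zeros(360 * 30))
        ev = self._events([10.0])
        stats = epoch_stats(ev, trace, {"off_time": [(0.0, 30.0), (330.0, 360.0)]})
        assert stats[0].rate == pytest.approx(1.0)

    def test_counts_conserve_across_partition(self, schedule):
        rng = np.random.default_rng(11)
        trace = make_trace(np.zeros(360 * 30))
        ev = self._events(rng.uniform(0, 360, 40))
        stats = epoch_stats(ev, trace, schedule.intervals_by_label())
        assert sum(s.n_events for s in stats) == 40

    def test_empty_pool_rate_zero_amplitude_missing(self):
        trace = make_trace(np.zeros(3600))
        stats = epoch_stats([], trace, {"on_time": [(0.0, 60.0)]})
        assert stats[0].rate == 0.0
        assert stats[0].mean_amplitude is None

    def test_zero_duration_pool_rejected(self):
        trace = make_trace(np.zeros(3600))
        with pytest.raises(ValueError):
            epoch_stats([], trace, {"on_time": []})


class TestPeriEventAverage:
    def test_single_event_returns_window(self):
        rng = np.random.default_rng(12)
        trace = make_trace(rng.normal(0, 1, 600))
        avg = peri_event_average(trace, [10.0], half_window=2.0)
        c = 300
        np.testing.assert_allclose(avg.mean_trace, trace.dff[c - 60 : c + 61])
        assert avg.n_events == 1

    def test_flat_trace_flat_average(self):
        trace = make_trace(np.full(3600, 0.7))
        avg = peri_event_average(trace, [20.0, 50.0, 80.0], half_window=3.0)
        np.testing.assert_allclose(avg.mean_trace, 0.7)

    def test_partial_windows_excluded_and_reported(self):
        trace = make_trace(np.zeros(600))
        avg = peri_event_average(trace, [0.5, 10.0], half_window=2.0)
        assert avg.n_events == 1 and avg.n_excluded == 1

    def test_no_complete_window_rejected(self):
        trace = make_trace(np.zeros(60))
        with pytest.raises(ValueError):
            peri_event_average(trace, [1.0], half_window=5.0)

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(13)
        dff = rng.normal(0, 1, 900)
        a = peri_event_average(make_trace(dff), [10.0, 20.0], 2.0)
        shifted = ProcessedTrace(
            time=100.0 + np.arange(900) / 30.0, dff=dff, params=PeakParams()
        )
        b = peri_event_average(shifted, [110.0, 120.0], 2.0)
        np.testing.assert_allclose(a.mean_trace, b.mean_trace)

    def test_acceleration_average_peaks_on_locked_transients(self, schedule):
        times = schedule.acceleration_times()
        dff = transient_train(360, times, np.full(len(times), 0.05))
        avg = acceleration_triggered_average(make_trace(dff), times, half_window=4.0)
        assert avg.n_events == len(times)
        assert abs(avg.lags[np.argmax(avg.mean_trace)]) <= 2 / 30
        assert avg.mean_trace.max() == pytest.approx(0.05, rel=0.05)


def test_processor_sklearn_interface():
    from sklearn.base import clone

    proc = PhotometryProcessor(prominence_min=0.03)
    other = clone(proc)
    assert other.get_params()["prominence_min"] == 0.03
    raw, _ = __import__("treadscore").synthetic.simulate_photometry(
        __import__("treadscore").SyntheticPhotometryConfig(seed=1), duration=60.0
    )
    trace = proc.fit().transform(raw)
    assert len(trace.dff) == 60 * 30
    events = proc.detect(raw)
    assert all(e.prominence > 0.03 for e in events)
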