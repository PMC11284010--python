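"""Pullback pipeline: smoothing, normalization, deviations, exceedance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coromix.errors import TraceError
from coromix.pullback import (
    DeviationProfile,
    NormalizedTrace,
    PullbackTrace,
    analyze_pullback,
    exceedance_fraction,
    read_trace_csv,
    relative_deviation_profile,
    resample_to_n,
    rolling_mean,
)


def _trace(temps, duration=20.0, rate=None):
    temps = np.asarray(temps, dtype=float)
    n = temps.size
    t = np.linspace(0.0, duration, n)
    rate = rate or (n - 1) / duration
    return PullbackTrace(
        time=t,
        position_cm=6.0 * (1.0 - t / duration),
        temperature=temps,
        sample_rate_hz=rate,
    )


class TestTraceValidation:
    def test_position_must_not_increase(self):
        with pytest.raises(TraceError):
            PullbackTrace(
                time=np.array([0.0, 10.0, 20.0]),
                position_cm=np.array([0.0, 3.0, 6.0]),
                temperature=np.array([36.0, 36.0, 36.0]),
                sample_rate_hz=0.1,
            )

    def test_duration_plausibility_window(self):
        with pytest.raises(TraceError):
            _trace(np.full(50, 36.0), duration=5.0)
        # explicit opt-out for unit-scale traces
        short = PullbackTrace(
            time=np.array([0.0, 1.0]),
            position_cm=np.array([6.0, 0.0]),
            temperature=np.array([36.0, 36.0]),
            sample_rate_hz=1.0,
            duration_bounds=None,
        )
        assert short.duration == 1.0


class TestRollingMean:
    def test_constant_trace_unchanged(self):
        tr = _trace(np.full(201, 36.0))
        out = rolling_mean(tr, 2.0)
        assert np.allclose(out.temperature, 36.0)
        assert np.array_equal(out.position_cm, tr.position_cm)

    def test_step_becomes_ramp(self):
        # convolution oracle: a unit step smoothed by a 2 s box becomes a
        # linear ramp of 2 s width
        rate = 10.0
        temps = np.concatenate([np.full(100, 30.0), np.full(100, 37.0)])
        tr = _trace(temps, duration=(temps.size - 1) / rate, rate=rate)
        n_win = int(2.0 * rate) | 1
        kernel = np.ones(n_win) / n_win
        oracle = np.convolve(temps, kernel, mode="same")
        out = rolling_mean(tr, 2.0)
        inner = slice(n_win // 2, -(n_win // 2))
        assert np.allclose(out.temperature[inner], oracle[inner], atol=1e-9)
        ramp = out.temperature[95:106]
        assert np.all(np.diff(ramp) > 0)

    def test_noise_variance_reduced_by_window_size(self):
        # statistical oracle: averaging n_win iid samples divides the
        # variance by n_win; averaged over realizations to beat the strong
        # autocorrelation of the smoothed series
        rate, dur = 50.0, 30.0
        n_win = int(2.0 * rate) | 1
        inner = slice(n_win, -n_win)
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0.0, 1.0, int(rate * dur) + 1)
            tr = _trace(36.0 + noise, duration=dur, rate=rate)
            out = rolling_mean(tr, 2.0)
            ratios.append(
                np.var(noise[inner]) / np.var(out.temperature[inner] - 36.0)
            )
        assert np.mean(ratios) == pytest.approx(n_win, rel=0.3)

    def test_window_must_fit_trace(self):
        tr = _trace(np.full(100, 36.0))
        with pytest.raises(TraceError):
            rolling_mean(tr, 25.0)
        with pytest.raises(TraceError):
            rolling_mean(tr, 0.0)


class TestResample:
    def test_constant_trace(self):
        out = resample_to_n(_trace(np.full(77, 35.5)))
        assert out.n_points == 1000
        assert np.allclose(out.temperature, 35.5)

    def test_linear_ramp_preserved_with_exact_endpoints(self):
        temps = np.linspace(30.0, 37.0, 61)
        out = resample_to_n(_trace(temps), 500)
        assert out.temperature[0] == pytest.approx(30.0)
        assert out.temperature[-1] == pytest.approx(37.0)
        assert np.allclose(np.diff(out.temperature), np.diff(out.temperature)[0])

    def test_pullback_speed_independence(self):
        # the same spatial profile recorded over 15 s and 30 s normalizes
        # to the same 1000-point profile
        profile = lambda pos: 36.0 - 3.0 * np.exp(-pos)
        for n_a, n_b, d_a, d_b in [(151, 301, 15.0, 30.0)]:
            ta = _trace(np.zeros(n_a), duration=d_a)
            tb = _trace(np.zeros(n_b), duration=d_b)
            ta = PullbackTrace(ta.time, ta.position_cm, profile(ta.position_cm), ta.sample_rate_hz)
            tb = PullbackTrace(tb.time, tb.position_cm, profile(tb.position_cm), tb.sample_rate_hz)
            a = resample_to_n(ta).temperature
            b = resample_to_n(tb).temperature
            assert np.abs(a - b).max() < 1e-3

    def test_degenerate_trace_rejected(self):
        tr = PullbackTrace(
            time=np.array([0.0]),
            position_cm=np.array([6.0]),
            temperature=np.array([36.0]),
            sample_rate_hz=1.0,
            duration_bounds=None,
        )
        with pytest.raises(TraceError):
            resample_to_n(tr)


class TestDeviations:
    def test_constant_trace_gives_zero_deviation(self):
        prof = relative_deviation_profile(resample_to_n(_trace(np.full(100, 36.0))))
        assert np.allclose(prof.relative_deviation, 0.0)
        assert prof.mean_temperature == pytest.approx(36.0)

    def test_alternating_trace_closed_form(self):
        temps = np.tile([36.0, 38.0], 500)
        prof = relative_deviation_profile(
            NormalizedTrace(np.linspace(6, 0, 1000), temps, 1000)
        )
        assert prof.mean_temperature == pytest.approx(37.0)
        assert np.allclose(np.abs(prof.relative_deviation), 100.0 / 37.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_mean_deviation_is_zero(self, seed):
        rng = np.random.default_rng(seed)
        temps = rng.uniform(25.0, 38.0, 1000)
        prof = relative_deviation_profile(
            NormalizedTrace(np.linspace(6, 0, 1000), temps, 1000)
        )
        assert prof.relative_deviation.mean() == pytest.approx(0.0, abs=1e-9)
        assert prof.exceedance_20 <= prof.exceedance_15

    def test_zero_mean_rejected(self):
        with pytest.raises(TraceError):
            relative_deviation_profile(
                NormalizedTrace(np.linspace(6, 0, 10), np.zeros(10), 10)
            )


class TestExceedance:
    def test_zero_profile(self):
        assert exceedance_fraction(np.zeros(1000), 15.0) == 0.0

    def test_counted_fraction(self):
        dev = np.zeros(1000)
        dev[:110] = 25.0
        assert exceedance_fraction(dev, 15.0) == pytest.approx(11.0)
        assert exceedance_fraction(dev, 20.0) == pytest.approx(11.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        dev = rng.normal(0.0, 15.0, 500)
        fracs = [exceedance_fraction(dev, th) for th in (5.0, 10.0, 15.0, 20.0, 30.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_threshold_must_be_positive(self):
        with pytest.raises(TraceError):
            exceedance_fraction(np.zeros(10), 0.0)


class TestPipelineOrder:
    def test_normalized_trace_cannot_be_smoothed_or_resampled(self):
        norm = resample_to_n(_trace(np.full(100, 36.0)))
        with pytest.raises(TraceError):
            rolling_mean(norm, 2.0)
        with pytest.raises(TraceError):
            resample_to_n(norm)

    def test_raw_trace_cannot_skip_normalization(self):
        with pytest.raises(TraceError):
            relative_deviation_profile(_trace(np.full(100, 36.0)))

    def test_full_pipeline_runs(self):
        rng = np.random.default_rng(3)
        prof = analyze_pullback(_trace(36.0 + 0.1 * rng.normal(size=401)))
        assert isinstance(prof, DeviationProfile)
        assert prof.n_points == 1000


class TestCsvIngestion:
    def test_round_trip_with_assumed_constant_speed(self, tmp_path):
        import pandas as pd

        path = tmp_path / "pullback.csv"
        t = np.linspace(0.0, 18.0, 181)
        pd.DataFrame({"time_s": t, "temperature_C": 36.0 + 0.01 * t}).to_csv(
            path, index=False
        )
        tr = read_trace_csv(path)
        assert tr.position_cm[0] == pytest.approx(6.0)
        assert tr.position_cm[-1] == pytest.approx(0.0)
        prof = analyze_pullback(tr)
        assert prof.exceedance_15 == 0.0

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(TraceError):
            read_trace_csv(path)
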