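"""ABR metrics: baseline statistics, the mean±2SD response criterion,
threshold calling, wave measurement and shift tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from efferentquant.abr import (
    ABRSeries,
    Waveform,
    bandpass_filter,
    baseline_stats,
    detect_response,
    estimate_threshold,
    threshold_shift_table,
    wave_metrics,
)
from efferentquant.synthetic import ABRSimConfig, simulate_abr_series


def _wf(v, fs=24.4, level=50.0):
    v = np.asarray(v, dtype=float)
    return Waveform(time_ms=np.arange(v.size) / fs, voltage_uv=v, level_db=level)


class TestBaselineStats:
    def test_constant_trace(self):
        b = baseline_stats(_wf(np.full(245, 5.0)))
        assert b.mean == 5.0 and b.sd == 0.0

    def test_two_point_sample_sd(self):
        # only the first two samples (t < 1 ms at fs=2/ms) are in-window
        w = _wf([1.0, -1.0, 0.0, 0.0], fs=2.0)
        b = baseline_stats(w)
        assert b.mean == pytest.approx(0.0)
        assert b.sd == pytest.approx(np.sqrt(2.0))

    def test_monte_carlo_unit_sd(self):
        rng = np.random.default_rng(0)
        w = _wf(rng.normal(0, 1, 10_000), fs=1000.0)
        b = baseline_stats(w, window_ms=(0.0, 10.0))
        assert 0.97 < b.sd < 1.03

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            baseline_stats(_wf(np.zeros(245)), window_ms=(0.0, 0.01))


class TestDetectResponse:
    def test_flat_trace_is_negative(self, flat_waveform):
        b = baseline_stats(flat_waveform)
        b = type(b)(mean=0.0, sd=1.0, window_ms=b.window_ms, n_samples=b.n_samples)
        assert not detect_response(flat_waveform, b)

    def test_window_gating_of_single_excursion(self, flat_waveform):
        from efferentquant.abr import BaselineStats

        b = BaselineStats(mean=0.0, sd=1.0, window_ms=(0.0, 1.0), n_samples=24)
        v = flat_waveform.voltage_uv.copy()
        idx_in = np.argmin(np.abs(flat_waveform.time_ms - 2.0))
        v[idx_in] = 3.0
        w = _wf(v)
        assert detect_response(w, b, min_run=1)
        v2 = flat_waveform.voltage_uv.copy()
        idx_out = np.argmin(np.abs(flat_waveform.time_ms - 1.0))
        v2[idx_out] = 3.0
        assert not detect_response(_wf(v2), b, min_run=1)

    def test_two_sided(self, flat_waveform):
        from efferentquant.abr import BaselineStats

        b = BaselineStats(mean=0.0, sd=1.0, window_ms=(0.0, 1.0), n_samples=24)
        v = flat_waveform.voltage_uv.copy()
        sl = slice(60, 70)
        v[sl] = -5.0  # negative excursion counts too
        assert detect_response(_wf(v), b)

    def test_min_run_gate(self, flat_waveform):
        from efferentquant.abr import BaselineStats

        b = BaselineStats(mean=0.0, sd=1.0, window_ms=(0.0, 1.0), n_samples=24)
        v = flat_waveform.voltage_uv.copy()
        v[60:63] = 5.0  # 3 consecutive samples
        assert detect_response(_wf(v), b, min_run=3)
        assert not detect_response(_wf(v), b, min_run=4)

    def test_degenerate_baseline_flagged(self, flat_waveform):
        from efferentquant.abr import BaselineStats

        b = BaselineStats(mean=0.0, sd=0.0, window_ms=(0.0, 1.0), n_samples=24)
        call = detect_response(flat_waveform, b)
        assert not call and call.degenerate_baseline
        v = flat_waveform.voltage_uv.copy()
        v[80] = 0.001
        call = detect_response(_wf(v), b)
        assert call and call.degenerate_baseline

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_raising_k_never_creates_a_response(self, seed):
        rng = np.random.default_rng(seed)
        w = _wf(rng.normal(0, 1, 245))
        b = baseline_stats(w)
        k1, k2 = sorted(rng.uniform(0.5, 4.0, size=2))
        if bool(detect_response(w, b, k=k2)):
            assert bool(detect_response(w, b, k=k1))


class TestEstimateThreshold:
    def test_lowest_responding_level(self):
        series, _ = simulate_abr_series(
            ABRSimConfig(true_threshold_db=30.0, noise_sd_uv=0.01, seed=1)
        )
        res = estimate_threshold(series)
        assert res.threshold_db == 30.0 and not res.censored
        assert res.calls[30.0] and not res.calls[20.0]

    def test_signal_free_series_is_censored(self):
        # noiseless and signal-free: censoring must hold by construction
        series, _ = simulate_abr_series(
            ABRSimConfig(
                true_threshold_db=100.0,
                amplitude_growth_uv_per_db=0.0,
                noise_sd_uv=0.0,
                seed=2,
            )
        )
        res = estimate_threshold(series)
        assert res.censored and res.threshold_db is None
        assert res.value_or_censor == 90.0

    def test_monotone_policy_skips_spurious_low_call(self):
        series, _ = simulate_abr_series(
            ABRSimConfig(true_threshold_db=40.0, noise_sd_uv=0.001, seed=3)
        )
        # inject a spurious supra-criterion blip at 10 dB only
        w10 = series[10.0]
        v = w10.voltage_uv.copy()
        v[60:70] = 1.0
        series.waveforms[10.0] = Waveform(
            time_ms=w10.time_ms, voltage_uv=v, level_db=10.0
        )
        assert estimate_threshold(series, policy="minimal").threshold_db == 10.0
        assert estimate_threshold(series, policy="monotone").threshold_db == 40.0

    def test_thresholds_nondecreasing_in_k(self):
        series, _ = simulate_abr_series(ABRSimConfig(true_threshold_db=40.0, seed=4))
        prev = -np.inf
        for k in (1.0, 2.0, 3.0, 5.0):
            res = estimate_threshold(series, k=k)
            thr = res.value_or_censor + (10.0 if res.censored else 0.0)
            assert thr >= prev
            prev = thr


class TestWaveMetrics:
    def test_constructed_biphasic_transient(self):
        fs = 100.0
        t = np.arange(int(6 * fs)) / fs
        v = 3.0 * np.exp(-0.5 * ((t - 2.5) / 0.1) ** 2) - 2.0 * np.exp(
            -0.5 * ((t - 2.0) / 0.1) ** 2
        )
        w = Waveform(time_ms=t, voltage_uv=v, level_db=80.0)
        (m,) = wave_metrics(w, search_window_ms=(1.4, 5.0), prominence_uv=0.5)
        assert m.latency_ms == pytest.approx(2.5, abs=1.5 / fs)
        assert m.amplitude_uv == pytest.approx(5.0, abs=0.05)
        assert m.trough_time_ms < m.peak_time_ms

    def test_pure_noise_yields_empty(self):
        rng = np.random.default_rng(5)
        w = _wf(rng.normal(0, 0.1, 245))
        assert wave_metrics(w, prominence_uv=2.0) == []

    def test_simulator_ground_truth_recovery(self):
        cfg = ABRSimConfig(true_threshold_db=30.0, noise_sd_uv=0.02, seed=6)
        series, truth = simulate_abr_series(cfg)
        w = series[90.0]
        found = wave_metrics(w, search_window_ms=(1.4, 5.0))
        lats = truth.wave_latencies_by_level[90.0]
        amps = truth.wave_amplitudes_by_level[90.0]
        dt = w.dt_ms
        for tau, amp in zip(lats, amps):
            best = min(found, key=lambda m: abs(m.latency_ms - tau))
            assert abs(best.latency_ms - tau) <= dt + 1e-9
            assert abs(best.amplitude_uv - amp) <= 2 * cfg.noise_sd_uv + 0.05 * amp


class TestShiftTable:
    def _table(self):
        return pd.DataFrame(
            [
                {"animal": "a1", "timepoint_day": 0, "threshold_db": 10.0, "censored": False},
                {"animal": "a1", "timepoint_day": 13, "threshold_db": 40.0, "censored": False},
                {"animal": "a2", "timepoint_day": 0, "threshold_db": 20.0, "censored": False},
                {"animal": "a2", "timepoint_day": 13, "threshold_db": 90.0, "censored": True},
                {"animal": "a3", "timepoint_day": 13, "threshold_db": 30.0, "censored": False},
            ]
        )

    def test_shift_arithmetic_and_baseline_zero(self):
        with pytest.warns(UserWarning, match="no day-0 baseline"):
            out = threshold_shift_table(self._table())
        a1 = out[out.animal == "a1"].set_index("timepoint_day")
        assert a1.loc[13, "shift_db"] == 30.0
        assert a1.loc[0, "shift_db"] == 0.0

    def test_censored_propagates_and_missing_baseline_drops(self):
        with pytest.warns(UserWarning):
            out = threshold_shift_table(self._table())
        a2 = out[(out.animal == "a2") & (out.timepoint_day == 13)].iloc[0]
        assert a2["censored"] and np.isnan(a2["shift_db"])
        assert "a3" not in set(out.animal)


def test_bandpass_preserves_passband_and_rejects_drift():
    fs = 24.4  # samples per ms -> 24.4 kHz
    t = np.arange(2440) / fs
    in_band = np.sin(2 * np.pi * 1.5 * t)  # 1.5 kHz
    drift = np.sin(2 * np.pi * 0.05 * t)  # 50 Hz
    w = Waveform(time_ms=t, voltage_uv=in_band + drift, level_db=70.0)
    out = bandpass_filter(w).voltage_uv
    mid = slice(500, -500)
    assert np.corrcoef(out[mid], in_band[mid])[0, 1] > 0.98
    assert np.std(out[mid] - in_band[mid]) < 0.2 * np.std(drift)
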