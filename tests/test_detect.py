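"""Spike and seizure detection on constructed and synthetic signals."""

import numpy as np
import pytest

from conftest import render_burst
from szjitter.detect import (
    DetectParams,
    detect_seizures,
    detect_spikes,
    estimate_background,
    raster_counts,
    seizures_to_table,
    table_to_seizures,
)
from szjitter.errors import EstimationError, ParameterError
from szjitter.io import Recording, as_event_table
from szjitter.synthetic import SimConfig, simulate_recording


def _rec(x, rate=6000.0):
    return Recording(np.asarray(x, dtype=float), rate)


def _half_sine(rate, width_s, amp):
    n = int(width_s * rate)
    return amp * np.sin(np.pi * (np.arange(n) + 0.5) / n)


class TestDetectSpikes:
    def test_single_excursion_peak_time(self):
        rate = 6000.0
        x = np.zeros(6000)
        pulse = _half_sine(rate, 0.020, 1.2e-3)  # 20 ms, 0 -> 1.2 mV -> 0
        start = 3000
        x[start : start + pulse.size] = pulse
        train = detect_spikes(_rec(x), DetectParams())
        assert len(train) == 1
        expected_peak = (start + pulse.size / 2) / rate
        assert train.times_s[0] == pytest.approx(expected_peak, abs=1.5 / rate)
        assert train.peak_amp_v[0] == pytest.approx(1.2e-3, rel=1e-3)

    def test_biphasic_merge_keeps_larger_peak(self):
        # two super-threshold peaks 50 ms apart -> one spike at the 1.5 mV peak
        rate = 6000.0
        x = np.zeros(6000)
        p1 = _half_sine(rate, 0.02, 1.2e-3)
        p2 = _half_sine(rate, 0.02, 1.5e-3)
        x[1000 : 1000 + p1.size] = p1
        start2 = 1000 + int(0.050 * rate)
        x[start2 : start2 + p2.size] = p2
        train = detect_spikes(_rec(x), DetectParams())
        assert len(train) == 1
        assert train.peak_amp_v[0] == pytest.approx(1.5e-3, rel=1e-3)
        assert train.times_s[0] == pytest.approx(
            (start2 + p2.size / 2) / rate, abs=1.5 / rate
        )

    def test_plateau_too_long_rejected(self):
        x = np.zeros(6000)
        x[1000 : 1000 + 1200] = 1.2e-3  # 200 ms super-threshold plateau
        assert len(detect_spikes(_rec(x), DetectParams())) == 0

    def test_too_short_excursion_rejected(self):
        rate = 6000.0
        x = np.zeros(6000)
        p = _half_sine(rate, 0.003, 1.2e-3)  # 3 ms < 5 ms minimum
        x[1000 : 1000 + p.size] = p
        assert len(detect_spikes(_rec(x), DetectParams())) == 0

    def test_sub_upper_threshold_rejected(self):
        rate = 6000.0
        x = np.zeros(6000)
        p = _half_sine(rate, 0.02, 0.8e-3)  # never reaches 1 mV
        x[1000 : 1000 + p.size] = p
        assert len(detect_spikes(_rec(x), DetectParams())) == 0

    def test_polarity_invariance(self):
        wave = render_burst(np.arange(12) * 0.35 + 1.0, duration_s=8.0)
        up = detect_spikes(_rec(wave), DetectParams())
        down = detect_spikes(_rec(-wave), DetectParams())
        assert np.allclose(up.times_s, down.times_s)
        assert np.allclose(up.peak_amp_v, down.peak_amp_v)


class TestBackground:
    def test_gaussian_sigma_recovered(self, rng):
        x = rng.normal(0, 10e-6, 60_000)
        est = estimate_background(_rec(x))
        assert est == pytest.approx(10e-6, rel=0.15)

    def test_constant_trace_zero(self):
        assert estimate_background(_rec(np.zeros(12_000))) == 0.0

    def test_exclusion_removes_burst_influence(self, rng):
        x = rng.normal(0, 10e-6, 120_000)
        base = estimate_background(_rec(x))
        x2 = x.copy()
        x2[30_000:60_000] += 2e-3  # large excluded burst
        excl = as_event_table(
            [dict(channel_id="*", start_s=5.0, end_s=10.0, kind="seizure",
                  value=np.nan)]
        )
        est = estimate_background(_rec(x2), exclusion=excl)
        assert est == pytest.approx(base, rel=0.05)

    def test_everything_excluded_errors(self, rng):
        x = rng.normal(0, 10e-6, 12_000)
        excl = as_event_table(
            [dict(channel_id="*", start_s=0.0, end_s=2.0, kind="seizure",
                  value=np.nan)]
        )
        with pytest.raises(EstimationError):
            estimate_background(_rec(x), exclusion=excl)


class TestRaster:
    def test_silent_trace_all_zero(self):
        starts, counts = raster_counts(
            _rec(np.zeros(120_000)), DetectParams(seizure_thresh_v=100e-6)
        )
        assert np.all(counts == 0)

    def test_saturated_trace_counts_full_window(self):
        x = 1e-3 * np.sin(2 * np.pi * 50 * np.arange(120_000) / 6000.0)
        starts, counts = raster_counts(
            _rec(x), DetectParams(seizure_thresh_v=100e-6)
        )
        assert np.all(counts == 20)  # 10 s window / 0.5 s bins

    def test_one_second_burst_max_count(self):
        x = np.zeros(120_000)
        x[60_000:66_000] = 1e-3  # exactly bins 20 and 21
        _, counts = raster_counts(_rec(x), DetectParams(seizure_thresh_v=100e-6))
        assert counts.max() == 2

    def test_short_recording_rejected(self):
        with pytest.raises(ParameterError):
            raster_counts(_rec(np.zeros(6000)), DetectParams())


class TestDetectSeizures:
    def _burst_rec(self, duration_s, rate_hz, seed=0):
        times = 30.0 + np.arange(int(duration_s * rate_hz)) / rate_hz
        wave = render_burst(times, duration_s=duration_s + 60.0,
                            noise_sd_v=20e-6, seed=seed)
        return _rec(wave)

    def test_12s_3hz_burst_is_one_seizure(self):
        rec = self._burst_rec(12.0, 3.0)
        seizures = detect_seizures(rec, DetectParams())
        assert len(seizures) == 1
        sz = seizures[0]
        assert 29.0 <= sz.start_s <= 30.5
        assert sz.mean_event_rate_hz >= 2.0
        assert len(sz.spikes) == 36

    def test_8s_burst_too_short(self):
        rec = self._burst_rec(8.0, 3.0)
        assert detect_seizures(rec, DetectParams()) == []

    def test_15s_1hz_too_sparse(self):
        rec = self._burst_rec(15.0, 1.0)
        assert detect_seizures(rec, DetectParams()) == []

    def test_quiescent_input_empty(self, rng):
        rec = _rec(rng.normal(0, 20e-6, 360_000))
        assert detect_seizures(rec, DetectParams()) == []

    def test_boundaries_match_ground_truth(self):
        cfg = SimConfig(duration_s=200.0, seizure_times_s=[30.0, 120.0], seed=7)
        rec, events, _ = simulate_recording(cfg)
        params = DetectParams()
        seizures = detect_seizures(rec, params)
        truth = events[events["kind"] == "seizure"]
        assert len(seizures) == len(truth) == 2
        tol = params.bin_s + params.gap_tol_s
        for sz, (_, row) in zip(seizures, truth.iterrows()):
            assert abs(sz.start_s - row["start_s"]) <= tol
            assert abs(sz.end_s - row["end_s"]) <= tol


class TestOverridesAndTables:
    def test_override_add_and_remove(self):
        cfg = SimConfig(duration_s=120.0, seizure_times_s=[30.0], seed=3)
        rec, events, _ = simulate_recording(cfg)
        base = detect_seizures(rec, DetectParams())[0]
        n0 = len(base.spikes)
        kill = base.spikes.times_s[5]
        overrides = as_event_table(
            [
                dict(channel_id="*", start_s=kill, end_s=kill, kind="spike",
                     value=-1.0),
                dict(channel_id="*", start_s=base.end_s - 0.05,
                     end_s=base.end_s - 0.05, kind="spike", value=1.1e-3),
            ]
        )
        fixed = detect_seizures(rec, DetectParams(), overrides=overrides)[0]
        assert len(fixed.spikes) == n0  # one removed, one added
        assert not np.any(np.isclose(fixed.spikes.times_s, kill))
        assert np.any(np.isclose(fixed.spikes.times_s, base.end_s - 0.05))

    def test_event_table_round_trip(self):
        cfg = SimConfig(duration_s=200.0, seizure_times_s=[30.0, 120.0], seed=5)
        rec, _, _ = simulate_recording(cfg)
        seizures = detect_seizures(rec, DetectParams())
        back = table_to_seizures(seizures_to_table(seizures))
        assert len(back) == len(seizures)
        for a, b in zip(seizures, back):
            assert a.start_s == pytest.approx(b.start_s)
            assert np.allclose(a.spikes.times_s, b.spikes.times_s)
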