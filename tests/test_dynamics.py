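"""Windowed jitter, transition calling, Fano factors, correlations."""

import numpy as np
import pytest

from conftest import make_train
from szjitter.detect import Seizure, SpikeTrain
from szjitter.dynamics import (
    JitterTrace,
    TransitionEvent,
    bin_trace,
    detect_transitions,
    event_windowed_jitter,
    fano,
    jitter_variability_correlation,
    state_vs_transition_jitter,
    windowed_jitter,
)
from szjitter.errors import ParameterError
from szjitter.jitter import jitter, pairwise_jitter
from szjitter.synthetic import (
    SimConfig,
    abrupt_onset_template,
    ramping_template,
    sample_spike_times,
    simulate_seizure_trains,
)


def _seizure(onset, iv, amp=1.2e-3):
    times = onset + np.concatenate([[0.0], np.cumsum(iv)])
    return Seizure("ch0", times[0], times[-1] + 0.02,
                   SpikeTrain(times, np.full(times.size, amp)),
                   times.size / (times[-1] - times[0] + 0.02))


IV_A = [0.30, 0.35, 0.40, 0.45]
IV_B = [0.20, 0.50, 0.25, 0.55]


class TestWindowedJitter:
    def test_two_seizure_window_equals_pair_jitter(self):
        s1, s2 = _seizure(10.0, IV_A), _seizure(100.0, IV_B)
        trace = windowed_jitter([s1, s2], window_s=200.0, step_s=50.0)
        expected = jitter(s1.spikes, s2.spikes).jitter_pct
        assert trace.jitter_pct[0] == pytest.approx(expected)
        assert trace.n_seizures_in_window[0] == 2

    def test_identical_seizures_zero_trace(self):
        szs = [_seizure(100.0 * k, IV_A) for k in range(4)]
        trace = windowed_jitter(szs, window_s=500.0, step_s=100.0)
        ok = ~np.isnan(trace.jitter_pct)
        assert ok.any()
        assert np.allclose(trace.jitter_pct[ok], 0.0)

    def test_three_seizure_window_mean_of_pairs(self):
        szs = [_seizure(10.0, IV_A), _seizure(60.0, IV_B),
               _seizure(110.0, [0.25, 0.45, 0.33, 0.52])]
        trace = windowed_jitter(szs, window_s=200.0, step_s=200.0)
        m = pairwise_jitter([s.spikes for s in szs])
        expected = np.mean(m[np.triu_indices(3, 1)])
        assert trace.jitter_pct[0] == pytest.approx(expected)

    def test_sparse_windows_missing(self):
        s1, s2 = _seizure(10.0, IV_A), _seizure(5000.0, IV_B)
        trace = windowed_jitter([s1, s2], window_s=100.0, step_s=100.0)
        assert np.isnan(trace.jitter_pct[0])

    def test_invalid_window(self):
        with pytest.raises(ParameterError):
            windowed_jitter([_seizure(0.0, IV_A)], window_s=-1.0)


class TestEventWindowedJitter:
    def test_run_count(self):
        szs = [_seizure(60.0 * k, IV_A) for k in range(5)]
        trace = event_windowed_jitter(szs, events_per_window=2)
        assert len(trace) == 4
        assert np.allclose(trace.jitter_pct, 0.0)

    def test_alternating_templates(self):
        szs = [
            _seizure(60.0 * k, IV_A if k % 2 == 0 else IV_B) for k in range(6)
        ]
        trace = event_windowed_jitter(szs, events_per_window=2)
        expected = jitter(szs[0].spikes, szs[1].spikes).jitter_pct
        assert np.allclose(trace.jitter_pct, expected)

    def test_too_few_seizures(self):
        with pytest.raises(ParameterError):
            event_windowed_jitter([_seizure(0.0, IV_A)], events_per_window=2)


class TestBinTrace:
    def test_one_point_per_bin(self):
        trace = JitterTrace([0.0, 300.0, 600.0], [1.0, 2.0, 3.0], [2, 2, 2])
        df = bin_trace(trace, bin_s=300.0)
        assert list(df["median"]) == [1.0, 2.0, 3.0]
        assert (df["q75"] - df["q25"] == 0).all()

    def test_known_three_point_bin(self):
        trace = JitterTrace([0.0, 100.0, 200.0], [3.0, 1.0, 2.0], [2, 2, 2])
        df = bin_trace(trace, bin_s=300.0)
        assert len(df) == 1
        assert df.loc[0, "median"] == 2.0
        assert df.loc[0, "q25"] == pytest.approx(1.5)
        assert df.loc[0, "q75"] == pytest.approx(2.5)
        assert df.loc[0, "low"] == 1.0 and df.loc[0, "high"] == 3.0


class TestDetectTransitions:
    def test_constant_trace_no_transitions(self):
        trace = JitterTrace(np.arange(10) * 600.0, np.full(10, 5.0),
                            np.full(10, 3), 3600.0, 600.0)
        assert detect_transitions(trace) == []

    def test_isolated_peak_called(self):
        vals = np.full(20, 2.0)
        vals[10] = 50.0  # way beyond mean + 2 SD
        trace = JitterTrace(np.arange(20) * 600.0, vals, np.full(20, 3),
                            3600.0, 600.0)
        events = detect_transitions(trace, k_sd=2.0)
        assert len(events) == 1
        assert events[0].onset_s == 10 * 600.0
        assert events[0].offset_s == 10 * 600.0 + 3600.0
        assert events[0].peak_jitter_pct == 50.0

    def test_interrupted_run_gives_two_events(self):
        vals = np.full(20, 2.0)
        vals[[8, 10]] = 60.0  # sub-threshold point in between
        trace = JitterTrace(np.arange(20) * 600.0, vals, np.full(20, 3),
                            3600.0, 600.0)
        assert len(detect_transitions(trace, k_sd=2.0)) == 2

    def test_all_missing_errors(self):
        trace = JitterTrace(np.arange(5) * 600.0, np.full(5, np.nan),
                            np.zeros(5), 3600.0, 600.0)
        with pytest.raises(ParameterError):
            detect_transitions(trace)


class TestStateVsTransition:
    def _two_state(self, seed=0):
        cfg = SimConfig(
            duration_s=4 * 3600.0,
            templates=[abrupt_onset_template(), ramping_template()],
            state_schedule=[(2 * 3600.0, 1)],
            isi_mean_s=300.0,
            seed=seed,
        )
        return simulate_seizure_trains(cfg)

    def test_cross_exceeds_within(self):
        wins = 0
        for seed in range(10):
            szs, switches = self._two_state(seed)
            tr = [TransitionEvent(switches[0] - 300.0, switches[0] + 300.0, 0.0)]
            within, cross = state_vs_transition_jitter(szs, tr)
            assert within.size and cross.size
            wins += cross.mean() > within.mean()
        assert wins >= 9

    def test_no_transitions_empty_cross(self):
        szs, _ = self._two_state()
        within, cross = state_vs_transition_jitter(szs, [])
        assert cross.size == 0
        assert within.size > 0


class TestFano:
    def test_constant_is_zero(self):
        assert fano([10.0, 10.0, 10.0]) == 0.0

    def test_hand_value_sample_variance(self):
        assert fano([5.0, 15.0]) == pytest.approx(5.0)

    def test_poisson_near_one(self, rng):
        counts = rng.poisson(20.0, 10_000)
        assert fano(counts) == pytest.approx(1.0, abs=0.05)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ParameterError):
            fano([1.0, -3.0])


class TestJitterVariabilityCorrelation:
    def _trace_and_seizures(self, rng, n_windows=30):
        szs, vals = [], []
        t = 0.0
        for w in range(n_windows):
            iv = [0.3, 0.4, 0.35, 0.45]
            for k in range(3):
                # duration varies within the window in a controlled way
                extra = 0.1 * w * k
                szs.append(_seizure(t + 200.0 * k, iv + [0.5 + extra]))
            t += 1000.0
        trace = windowed_jitter(szs, window_s=1000.0, step_s=1000.0,
                                t_start=0.0, t_end=t - 1.0)
        return trace, szs

    def test_self_correlation_is_one(self, rng):
        trace, szs = self._trace_and_seizures(rng)
        onsets = np.asarray([s.start_s for s in szs])
        durs = np.asarray([s.duration_s for s in szs])
        sds = []
        for ws in trace.window_start_s:
            idx = (onsets >= ws) & (onsets < ws + 1000.0)
            sds.append(np.std(durs[idx], ddof=1) if idx.sum() >= 2 else np.nan)
        trace2 = JitterTrace(trace.window_start_s, np.asarray(sds),
                             trace.n_seizures_in_window, 1000.0, 1000.0)
        r, p, n = jitter_variability_correlation(trace2, szs, "duration_sd")
        assert r == pytest.approx(1.0)
        assert n == int(np.sum(~np.isnan(np.asarray(sds))))

    def test_anticorrelated_pair(self):
        szs = []
        for w in range(20):
            for k in range(3):
                szs.append(_seizure(1000.0 * w + 200.0 * k,
                                    [0.3, 0.4, 0.5 + 0.05 * w * k]))
        trace = windowed_jitter(szs, 1000.0, 1000.0, t_start=0.0, t_end=19_999.0)
        onsets = np.asarray([s.start_s for s in szs])
        durs = np.asarray([s.duration_s for s in szs])
        sds = []
        for ws in trace.window_start_s:
            idx = (onsets >= ws) & (onsets < ws + 1000.0)
            sds.append(np.std(durs[idx], ddof=1) if idx.sum() >= 2 else np.nan)
        anti = JitterTrace(trace.window_start_s, -np.asarray(sds),
                           trace.n_seizures_in_window, 1000.0, 1000.0)
        r, _, _ = jitter_variability_correlation(anti, szs, "duration_sd")
        assert r == pytest.approx(-1.0)

    def test_independent_noise_low_correlation(self):
        rng = np.random.default_rng(42)
        tpl = abrupt_onset_template()
        szs = []
        for w in range(350):
            for k in range(3):
                onset = 1000.0 * w + 250.0 * k + rng.uniform(0.0, 60.0)
                times = sample_spike_times(tpl, 0.005, rng) + onset
                szs.append(Seizure("ch0", times[0], times[-1] + 0.02,
                                   SpikeTrain(times, np.full(times.size, 1.2e-3)),
                                   3.0))
        trace = windowed_jitter(szs, 1000.0, 1000.0, t_start=0.0,
                                t_end=350_000.0 - 1)
        r, p, n = jitter_variability_correlation(trace, szs, "interval_sd")
        assert n >= 300
        assert abs(r) < 0.15


def test_media_exchange_like_perturbation():
    """Elevated timing noise in the first hour shows up as elevated jitter."""
    cfg = SimConfig(
        duration_s=6 * 3600.0,
        isi_mean_s=300.0,
        noise_schedule=[(0.0, 0.030), (3600.0, 0.005)],
        seed=11,
    )
    szs, _ = simulate_seizure_trains(cfg)
    trace = windowed_jitter(szs, window_s=3600.0, step_s=3600.0, t_start=0.0)
    first = trace.jitter_pct[0]
    later = np.nanmean(trace.jitter_pct[1:])
    assert first > 2 * later
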