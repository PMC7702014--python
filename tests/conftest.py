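"""Shared fixtures and independent oracles.

The naive jitter implementation here is deliberately independent of the
package's diagonal-minimization shortcut: it enumerates every alignment
pair and pairs intervals by explicit offset bookkeeping, so it can serve as
a brute-force oracle for the optimized implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from szjitter.detect import SpikeTrain
from szjitter.synthetic import biphasic_kernel


def naive_jitter(times_a, times_b, pairing="signed"):
    """Brute-force minimum jitter (percent) over all alignment-spike pairs."""
    iva = np.diff(np.asarray(times_a, float))
    ivb = np.diff(np.asarray(times_b, float))
    best = None
    for ia in range(len(times_a)):
        for ib in range(len(times_b)):
            terms = []
            # interval at offset j spans spikes (align+j, align+j+1)
            offsets = range(-max(ia, ib), max(len(iva), len(ivb)))
            for off in offsets:
                if pairing == "forward" and off < 0:
                    continue
                ja, jb = ia + off, ib + off
                if 0 <= ja < len(iva) and 0 <= jb < len(ivb):
                    terms.append(
                        abs(iva[ja] - ivb[jb]) / ((iva[ja] + ivb[jb]) / 2.0)
                    )
            if terms:
                val = 100.0 * float(np.mean(terms))
                if best is None or val < best - 1e-12:
                    best = val
    return best


def make_train(times, amp=1.2e-3):
    times = np.asarray(times, dtype=float)
    return SpikeTrain(times, np.full(times.size, amp))


def render_burst(spike_times_s, rate_hz=6000.0, duration_s=None, amp_v=1.2e-3,
                 noise_sd_v=0.0, seed=0):
    """Render an arbitrary spike-time list as a waveform (test helper).

    Unlike the package generator this accepts any spike schedule, so it can
    build bursts that violate seizure-template invariants (too short, too
    sparse) for testing the detector's rejection rules.
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    if duration_s is None:
        duration_s = spike_times_s.max() + 5.0
    n = int(round(duration_s * rate_hz))
    kernel, kpeak = biphasic_kernel(rate_hz)
    wave = np.zeros(n)
    for t in spike_times_s:
        i0 = int(round(t * rate_hz)) - kpeak
        j0, j1 = max(0, i0), min(n, i0 + kernel.size)
        wave[j0:j1] += amp_v * kernel[j0 - i0 : j1 - i0]
    if noise_sd_v > 0:
        wave = wave + np.random.default_rng(seed).normal(0, noise_sd_v, n)
    return wave


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
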