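"""Filtering, resampling and signal-quality metrics.

All filters are Butterworth designs applied zero-phase (forward-backward via
``sosfiltfilt``) by default: the downstream jitter statistic is a *timing*
statistic, and phase distortion from one-pass IIR filtering would bias spike
peak times. The effective magnitude response of a zero-phase filter is the
squared magnitude of the designed filter, so the stated order refers to the
designed prototype.

Presets
-------
``mea_notch``
    4th-order band-stop 58-62 Hz (mains interference; the stop band brackets
    the 60 Hz line frequency).
``mea_highpass``
    4th-order high-pass at 3 Hz (DC drift and slow mechanical disturbances).
``smw_band``
    4th-order band-pass 1 Hz - min(3 kHz, 0.45 * rate) (wideband LFP front
    end for microwire recordings).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import ParameterError
from .io import Recording

__all__ = ["FilterSpec", "preset", "apply_filter", "downsample", "snr_db", "PRESETS"]

_KINDS = {"bandstop", "highpass", "bandpass", "lowpass"}


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter description.

    ``edges_hz`` holds one corner frequency for highpass/lowpass and two
    ordered corners for bandpass/bandstop; all must lie strictly inside
    ``(0, rate/2)`` of the recording they are applied to.
    """

    kind: str
    order: int = 4
    edges_hz: tuple[float, ...] = ()
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        n_expected = 2 if self.kind in ("bandpass", "bandstop") else 1
        if len(self.edges_hz) != n_expected:
            raise ParameterError(
                f"{self.kind} filter needs {n_expected} edge(s), "
                f"got {len(self.edges_hz)}"
            )
        if any(e <= 0 for e in self.edges_hz):
            raise ParameterError("filter edges must be positive")
        if n_expected == 2 and not self.edges_hz[0] < self.edges_hz[1]:
            raise ParameterError("band edges must be strictly ordered")


PRESETS = ("mea_notch", "mea_highpass", "smw_band")


def preset(name: str, rate_hz: float) -> FilterSpec:
    """Build one of the named filter presets for a given sampling rate."""
    if name == "mea_notch":
        return FilterSpec("bandstop", 4, (58.0, 62.0))
    if name == "mea_highpass":
        return FilterSpec("highpass", 4, (3.0,))
    if name == "smw_band":
        return FilterSpec("bandpass", 4, (1.0, min(3000.0, 0.45 * rate_hz)))
    raise ParameterError(f"unknown preset {name!r}; choose from {PRESETS}")


def _sos(spec: FilterSpec, rate_hz: float) -> np.ndarray:
    nyq = rate_hz / 2.0
    if any(e >= nyq for e in spec.edges_hz):
        raise ParameterError(
            f"filter edge(s) {spec.edges_hz} not below Nyquist {nyq} Hz"
        )
    wn = spec.edges_hz[0] if len(spec.edges_hz) == 1 else list(spec.edges_hz)
    return signal.butter(spec.order, wn, btype=spec.kind, fs=rate_hz, output="sos")


def apply_filter(rec: Recording, spec: FilterSpec | str) -> Recording:
    """Filter every channel of a recording; shape and rate are preserved."""
    if isinstance(spec, str):
        spec = preset(spec, rec.rate_hz)
    sos = _sos(spec, rec.rate_hz)
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    else:
        filtered = signal.sosfilt(sos, rec.samples, axis=-1)
    return replace_samples(rec, filtered)


def replace_samples(rec: Recording, samples: np.ndarray) -> Recording:
    """New Recording with the same metadata and different samples."""
    return Recording(
        np.asarray(samples, dtype=float),
        rec.rate_hz,
        rec.t0_s,
        list(rec.channel_ids),
        dict(rec.meta),
    )


def downsample(rec: Recording, target_hz: float) -> Recording:
    """Anti-alias filter and resample to ``target_hz``.

    Uses polyphase FIR resampling (zero-phase, no systematic peak shift).
    The achieved rate is the rational approximation ``rate * up / down``,
    exact for the usual integer decimations (e.g. 6 kHz -> 1 kHz).
    """
    if not target_hz > 0:
        raise ParameterError("target_hz must be positive")
    if target_hz >= rec.rate_hz:
        raise ParameterError(
            f"target rate {target_hz} Hz must be below the current "
            f"rate {rec.rate_hz} Hz"
        )
    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.samples, up, down, axis=-1)
    new_rate = rec.rate_hz * up / down
    return Recording(out, new_rate, rec.t0_s, list(rec.channel_ids), dict(rec.meta))


def _pooled(rec: Recording, windows, what: str) -> np.ndarray:
    if not windows:
        raise ParameterError(f"empty {what} window list")
    parts = []
    for start_s, end_s in windows:
        i0 = int(round((start_s - rec.t0_s) * rec.rate_hz))
        i1 = int(round((end_s - rec.t0_s) * rec.rate_hz))
        if i0 < 0 or i1 > rec.n_samples or i1 <= i0:
            raise ParameterError(
                f"{what} window ({start_s}, {end_s}) s outside recording"
            )
        parts.append(rec.samples[:, i0:i1].ravel())
    return np.concatenate(parts)


def snr_db(rec: Recording, signal_windows, noise_windows) -> float:
    """Signal-to-noise ratio in dB between two sets of time windows.

    ``10 * log10(P_signal / P_noise)`` where each power is the mean squared
    amplitude after mean removal within the pooled windows (i.e. the pooled
    variance). Typically signal windows cover seizures and noise windows
    cover quiescent background.
    """
    s = _pooled(rec, signal_windows, "signal")
    n = _pooled(rec, noise_windows, "noise")
    p_sig = float(np.mean((s - s.mean()) ** 2))
    p_noise = float(np.mean((n - n.mean()) ** 2))
    if p_noise <= 0:
        raise ParameterError("noise power is zero; cannot form an SNR")
    return 10.0 * np.log10(p_sig / p_noise)
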