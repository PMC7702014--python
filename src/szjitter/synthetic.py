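"""Synthetic epileptiform LFP and fluorescence generators with ground truth.

The signal model abstracts chronic in vitro recordings of spontaneously
epileptic hippocampal cultures: long stretches of low-amplitude Gaussian
background interrupted by paroxysmal events (seizures) lasting tens of
seconds, each a train of millivolt-scale biphasic population spikes riding
on the background. Seizures within one "state" share a waveform *template*;
per-spike Gaussian timing noise makes repeats similar but not identical, and
scheduled template switches emulate spontaneous state transitions.

Everything is a pure function of (config, seed): the same seed reproduces
the same recording byte for byte.

Defaults (chosen once, stated here):

* abrupt-onset template: 60 spikes / 20 s (3 Hz mean), inter-spike
  intervals ramping 0.15 -> 0.53 s, first spike 1.5 mV then 1.2 mV;
* ramping template: 60 spikes / 25 s (2.4 Hz), parabolic interval profile
  (fast in the middle), amplitudes swelling 1.2 -> 1.5 -> 1.2 mV;
* spike kernel: 20 ms biphasic, 8 ms positive main lobe plus a 12 ms
  opposite lobe at 0.9 relative amplitude, so both lobes of a >=1.2 mV
  spike cross a 1 mV threshold and exercise the biphasic-merge rule;
* per-spike timing noise sigma 5 ms; background noise sigma 20 uV;
* inter-seizure intervals gamma-distributed, mean 300 s, CV 0.3 (such
  cultures seize every few minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Seizure, SpikeTrain
from .errors import GenerationError, ParameterError, PlacementError
from .io import Recording, as_event_table

__all__ = [
    "SeizureTemplate",
    "SimConfig",
    "abrupt_onset_template",
    "ramping_template",
    "biphasic_kernel",
    "sample_spike_times",
    "render_seizure",
    "simulate_seizure_trains",
    "simulate_recording",
    "simulate_calcium",
]


@dataclass(frozen=True)
class SeizureTemplate:
    """A seizure waveform prototype: spike offsets (s) and peak amps (V).

    ``kind`` is ``"abrupt_onset"`` (largest spike first, intervals
    monotonically lengthening toward the end) or ``"ramping"`` (intervals
    shrink then lengthen again).
    """

    kind: str
    spike_offsets_s: tuple[float, ...]
    spike_amps_v: tuple[float, ...]

    def __post_init__(self) -> None:
        off = np.asarray(self.spike_offsets_s)
        amp = np.asarray(self.spike_amps_v)
        if off.size != amp.size or off.size < 2:
            raise ParameterError("need matching offsets/amps, >= 2 spikes")
        if off[0] != 0 or np.any(np.diff(off) <= 0):
            raise ParameterError("offsets must start at 0 and increase")
        if np.any(amp < 1e-3):
            raise ParameterError("template spike amplitudes must be >= 1 mV")
        if self.duration_s < 10.0:
            raise ParameterError("template duration must be >= 10 s")
        if self.mean_rate_hz < 2.0:
            raise ParameterError("template mean rate must be >= 2 Hz")
        iv = np.diff(off)
        if self.kind == "abrupt_onset":
            if amp[0] < amp.max() or np.any(np.diff(iv) < -1e-12):
                raise ParameterError(
                    "abrupt_onset: first spike largest, intervals non-decreasing"
                )
        elif self.kind == "ramping":
            imin = int(np.argmin(iv))
            if imin in (0, iv.size - 1):
                raise ParameterError("ramping: intervals must dip in the middle")
        else:
            raise ParameterError(f"unknown template kind {self.kind!r}")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_offsets_s)

    @property
    def duration_s(self) -> float:
        return self.spike_offsets_s[-1]

    @property
    def mean_rate_hz(self) -> float:
        return self.n_spikes / self.duration_s


def abrupt_onset_template(
    duration_s: float = 20.0,
    mean_rate_hz: float = 3.0,
    amp_v: float = 1.2e-3,
    first_amp_scale: float = 1.25,
    interval_spread: float = 0.55,
) -> SeizureTemplate:
    """Abrupt-onset seizure: big first spike, spiking that slows over time."""
    n = int(round(duration_s * mean_rate_hz))
    if n < 3:
        raise ParameterError("too few spikes for a template")
    mean_iv = duration_s / (n - 1)
    lo = mean_iv * (1.0 - interval_spread)
    hi = mean_iv * (1.0 + interval_spread)
    iv = np.linspace(lo, hi, n - 1)
    offsets = np.concatenate([[0.0], np.cumsum(iv)])
    amps = np.full(n, amp_v)
    amps[0] = amp_v * first_amp_scale
    return SeizureTemplate("abrupt_onset", tuple(offsets), tuple(amps))


def ramping_template(
    duration_s: float = 25.0,
    mean_rate_hz: float = 2.4,
    amp_v: float = 1.2e-3,
    peak_amp_scale: float = 1.25,
    interval_dip: float = 0.9,
) -> SeizureTemplate:
    """Ramping seizure: rate builds to a fast middle and fades out again."""
    n = int(round(duration_s * mean_rate_hz))
    if n < 5:
        raise ParameterError("too few spikes for a template")
    m = (n - 2) / 2.0
    u = (np.arange(n - 1) - m) / m  # -1 .. 1 across intervals
    shape = 1.0 - interval_dip / (1.0 + interval_dip / 3.0) * (1.0 - u**2)
    iv = shape / shape.mean() * (duration_s / (n - 1))
    offsets = np.concatenate([[0.0], np.cumsum(iv)])
    amps = amp_v * (1.0 + (peak_amp_scale - 1.0) * (1.0 - u**2))
    amps = np.concatenate([[amp_v], amps])
    return SeizureTemplate("ramping", tuple(offsets), tuple(amps))


def biphasic_kernel(
    rate_hz: float, width_s: float = 0.02, main_frac: float = 0.4,
    neg_amp: float = 0.9,
):
    """Unit-peak biphasic spike kernel and the index of its peak.

    A positive half-sine main lobe (width ``main_frac * width_s``) followed
    by an opposite half-sine lobe at ``neg_amp`` relative amplitude.
    """
    n1 = max(3, int(round(width_s * main_frac * rate_hz)))
    n2 = max(3, int(round(width_s * (1.0 - main_frac) * rate_hz)))
    pos = np.sin(np.pi * (np.arange(n1) + 0.5) / n1)
    neg = -neg_amp * np.sin(np.pi * (np.arange(n2) + 0.5) / n2)
    k = np.concatenate([pos, neg])
    peak = int(np.argmax(np.abs(k)))
    return k / np.abs(k[peak]), peak


def sample_spike_times(
    template: SeizureTemplate,
    timing_noise_sd_s: float,
    rng: np.random.Generator,
    refractory_s: float = 0.1,
    max_tries: int = 1000,
) -> np.ndarray:
    """Template offsets + iid Gaussian perturbations, re-sorted.

    Whole trains violating the minimum spike separation (the detector's
    refractory period) are rejected and redrawn.
    """
    if timing_noise_sd_s < 0:
        raise ParameterError("timing noise sigma must be >= 0")
    base = np.asarray(template.spike_offsets_s)
    if timing_noise_sd_s == 0:
        return base.copy()
    for _ in range(max_tries):
        t = np.sort(base + rng.normal(0.0, timing_noise_sd_s, base.size))
        if np.all(np.diff(t) > refractory_s):
            return t - t[0]  # re-anchor so the train starts at 0
    raise GenerationError(
        f"could not draw a train with separation > {refractory_s} s "
        f"in {max_tries} tries (sigma={timing_noise_sd_s})"
    )


def render_seizure(
    template: SeizureTemplate,
    timing_noise_sd_s: float,
    rate_hz: float,
    rng: np.random.Generator,
    width_s: float = 0.02,
    neg_amp: float = 0.9,
    pad_s: float = 0.05,
):
    """One noisy realization of a template as a waveform segment.

    Returns ``(wave, train, pad_s)``: the segment covers
    ``[-pad_s, duration + pad_s]`` around the template origin and ``train``
    holds the ground-truth spike times (segment-relative plus ``pad_s``)
    with their peak amplitudes.
    """
    times = sample_spike_times(template, timing_noise_sd_s, rng)
    amps = np.asarray(template.spike_amps_v)
    kernel, kpeak = biphasic_kernel(rate_hz, width_s, neg_amp=neg_amp)
    n = int(np.ceil((times[-1] + 2 * pad_s + width_s) * rate_hz))
    wave = np.zeros(n)
    for t, a in zip(times, amps):
        i0 = int(round((t + pad_s) * rate_hz)) - kpeak
        j0, j1 = max(0, i0), min(n, i0 + kernel.size)
        wave[j0:j1] += a * kernel[j0 - i0 : j1 - i0]
    return wave, SpikeTrain(times + pad_s, amps), pad_s


@dataclass
class SimConfig:
    """Recording-simulation configuration; a pure function of itself + seed."""

    rate_hz: float = 6000.0
    duration_s: float = 300.0
    templates: list[SeizureTemplate] = field(
        default_factory=lambda: [abrupt_onset_template()]
    )
    state_schedule: list[tuple[float, int]] = field(default_factory=list)
    seizure_times_s: list[float] | None = None
    isi_mean_s: float = 300.0
    isi_cv: float = 0.3
    timing_noise_sd_s: float = 0.005
    noise_schedule: list[tuple[float, float]] | None = None
    noise_sd_v: float = 20e-6
    kernel_width_s: float = 0.02
    kernel_neg_amp: float = 0.9
    start_offset_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ParameterError("rate_hz and duration_s must be positive")
        if not self.templates:
            raise ParameterError("need at least one template")
        sw = [t for t, _ in self.state_schedule]
        if sw != sorted(sw) or len(set(sw)) != len(sw):
            raise ParameterError("state_schedule times must be increasing")
        if any(not 0 <= t <= self.duration_s for t in sw):
            raise ParameterError("state_schedule times must lie in the recording")
        if any(not 0 <= i < len(self.templates) for _, i in self.state_schedule):
            raise ParameterError("state_schedule template index out of range")
        if self.timing_noise_sd_s < 0 or self.noise_sd_v < 0:
            raise ParameterError("noise sigmas must be >= 0")


def _active(schedule, t: float, default):
    """Last scheduled value at or before time t, else the default."""
    current = default
    for when, value in schedule:
        if when <= t:
            current = value
        else:
            break
    return current


def _placements(cfg: SimConfig, rng: np.random.Generator):
    """Seizure onsets with their active template and timing sigma."""
    placements = []
    if cfg.seizure_times_s is not None:
        onsets = list(cfg.seizure_times_s)
        if onsets != sorted(onsets):
            raise PlacementError("explicit seizure times must be sorted")
        prev_end = -np.inf
        for t in onsets:
            tpl = cfg.templates[_active(cfg.state_schedule, t, 0)]
            if t < prev_end:
                raise PlacementError(f"seizure at {t} s overlaps the previous one")
            if t + tpl.duration_s > cfg.duration_s:
                raise PlacementError(f"seizure at {t} s extends past the recording")
            placements.append((t, tpl))
            prev_end = t + tpl.duration_s + 2 * cfg.kernel_width_s
    else:
        shape = 1.0 / cfg.isi_cv**2
        scale = cfg.isi_mean_s * cfg.isi_cv**2
        t = cfg.start_offset_s
        while True:
            tpl = cfg.templates[_active(cfg.state_schedule, t, 0)]
            if t + tpl.duration_s + 1.0 > cfg.duration_s:
                break
            placements.append((t, tpl))
            isi = float(rng.gamma(shape, scale))
            t += max(isi, tpl.duration_s + 10.0)  # keep events disjoint
    out = []
    for t, tpl in placements:
        sigma = _active(cfg.noise_schedule or [], t, cfg.timing_noise_sd_s)
        out.append((t, tpl, sigma))
    return out


def simulate_seizure_trains(cfg: SimConfig):
    """Ground-truth seizures (no waveform) and programmed transition times.

    Fast path for dynamics experiments where only spike times matter.
    Shares the placement and timing-noise model (and the seed semantics) of
    :func:`simulate_recording`.
    """
    rng = np.random.default_rng(cfg.seed)
    seizures = []
    for onset, tpl, sigma in _placements(cfg, rng):
        times = sample_spike_times(tpl, sigma, rng) + onset
        amps = np.asarray(tpl.spike_amps_v)
        end = times[-1] + cfg.kernel_width_s
        seizures.append(
            Seizure("sim", float(times[0]), float(end),
                    SpikeTrain(times, amps), tpl.mean_rate_hz)
        )
    transitions = [t for t, _ in cfg.state_schedule]
    return seizures, transitions


def simulate_recording(cfg: SimConfig):
    """Render a full recording with ground truth.

    Returns ``(rec, events, transitions)``: the single-channel
    :class:`Recording` (volts), a canonical event table of ground-truth
    seizures and spikes (spike ``value`` is the peak amplitude), and the
    list of programmed state-transition times.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate_hz))
    kernel, kpeak = biphasic_kernel(
        cfg.rate_hz, cfg.kernel_width_s, neg_amp=cfg.kernel_neg_amp
    )
    signal = np.zeros(n)
    rows = []
    for onset, tpl, sigma in _placements(cfg, rng):
        times = sample_spike_times(tpl, sigma, rng) + onset
        amps = np.asarray(tpl.spike_amps_v)
        for t, a in zip(times, amps):
            i0 = int(round(t * cfg.rate_hz)) - kpeak
            j0, j1 = max(0, i0), min(n, i0 + kernel.size)
            if j1 > j0:
                signal[j0:j1] += a * kernel[j0 - i0 : j1 - i0]
        end = times[-1] + cfg.kernel_width_s
        rows.append(dict(channel_id="sim", start_s=times[0], end_s=end,
                         kind="seizure", value=times.size / (end - times[0])))
        for t, a in zip(times, amps):
            rows.append(dict(channel_id="sim", start_s=t, end_s=t,
                             kind="spike", value=a))
    for t, _idx in cfg.state_schedule:
        rows.append(dict(channel_id="sim", start_s=t, end_s=t,
                         kind="transition", value=np.nan))
    noise = rng.normal(0.0, cfg.noise_sd_v, n) if cfg.noise_sd_v > 0 else 0.0
    rec = Recording(signal + noise, cfg.rate_hz, 0.0, ["sim"],
                    {"synthetic": True, "seed": cfg.seed})
    events = as_event_table(rows) if rows else as_event_table([])
    return rec, events, [t for t, _ in cfg.state_schedule]


# ---------------------------------------------------------------------------
# synthetic fluorescence
# ---------------------------------------------------------------------------


def _insertion_shape(t, peak_dff, rise_s, recovery_s, frac):
    """Noiseless insertion transient in dff units; 0 before t=0.

    ``(1 - exp(-t/tau_r)) * exp(-t/tau_d)`` scaled to peak at ``peak_dff``,
    with tau_r set so the peak lands near ``rise_s`` and tau_d so the decay
    reaches ``frac`` near ``recovery_s``. A non-positive ``peak_dff`` means
    no insertion transient at all.
    """
    if peak_dff <= frac:
        return np.zeros_like(np.asarray(t, dtype=float)), 0.0
    tau_d = max(recovery_s - rise_s, 1.0) / np.log(peak_dff / frac)
    tau_r = rise_s / 3.0
    for _ in range(60):  # fixed point for the peak-time condition
        tau_r = rise_s / np.log1p(tau_d / tau_r)
    raw = lambda x: (1.0 - np.exp(-x / tau_r)) * np.exp(-x / tau_d)  # noqa: E731
    t_peak = tau_r * np.log1p(tau_d / tau_r)
    scale = peak_dff / raw(t_peak)
    out = np.where(t > 0, scale * raw(np.maximum(t, 0.0)), 0.0)
    return out, t_peak


def simulate_calcium(
    baseline: float = 100.0,
    drift_frac: float = 0.05,
    peak_dff: float = 0.5,
    rise_s: float = 20.0,
    recovery_s: float = 900.0,
    frac: float = 0.02,
    noise_sd: float = 0.2,
    common_amp: float = 2.0,
    duration_s: float = 3600.0,
    rate_hz: float = 5.0,
    event_s: float = 60.0,
    seed: int = 0,
):
    """Paired affected/reference ROI traces around an electrode insertion.

    The affected ROI carries an insertion transient (rise over ``rise_s``,
    decay back to within ``frac`` of baseline by ``recovery_s`` after the
    event); both share the baseline, a linear drift (``drift_frac`` of
    baseline over the recording) and common-mode spontaneous activity
    (sparse positive calcium bursts, amplitude ~``common_amp``, every
    ~45 s, as culture-wide seizure-associated events produce), and receive
    independent Gaussian noise. Returns
    ``(affected, reference, truth)`` where ``truth`` holds the exact
    programmed recovery time (scanned from the noiseless shape), the event
    time and the peak ΔF/F.
    """
    from .calcium import FluorescenceTrace  # local import avoids a cycle

    if baseline <= 0:
        raise ParameterError("baseline must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    drift = baseline * drift_frac * t / duration_s
    # shared spontaneous activity: positive bursts (alpha shape, ~6 s decay)
    common = np.zeros_like(t)
    n_bursts = rng.poisson(duration_s / 45.0)
    for t_b in rng.uniform(0.0, duration_s, n_bursts):
        amp = common_amp * rng.gamma(2.0, 0.75)
        tau = np.maximum(t - t_b, 0.0)
        common += amp * (tau / 6.0) * np.exp(1.0 - tau / 6.0) * (tau < 60.0)
    shape, _ = _insertion_shape(t - event_s, peak_dff, rise_s, recovery_s, frac)
    noise_a = rng.normal(0, noise_sd, t.size) if noise_sd > 0 else 0.0
    noise_r = rng.normal(0, noise_sd, t.size) if noise_sd > 0 else 0.0
    affected = FluorescenceTrace(t, baseline + drift + common
                                 + baseline * shape + noise_a)
    reference = FluorescenceTrace(t, baseline + drift + common + noise_r)

    # exact programmed recovery: scan the noiseless shape on a fine grid
    tf = np.arange(0.0, duration_s - event_s, 0.01)
    sf, t_peak = _insertion_shape(tf, peak_dff, rise_s, recovery_s, frac)
    after_peak = tf > t_peak
    below = after_peak & (sf <= frac)
    true_recovery = float(tf[np.argmax(below)]) if below.any() else float("nan")
    truth = {
        "recovery_s": true_recovery,
        "event_s": event_s,
        "peak_dff": peak_dff,
        "peak_time_s": float(event_s + t_peak),
    }
    return affected, reference, truth
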