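"""Population-spike and seizure detection.

The detector mirrors the standard dual-threshold scheme for in vitro
epileptiform local field potentials:

* A **population spike** is an excursion of the rectified trace that starts
  below a lower threshold (default 0.5 mV), exceeds an upper threshold
  (default 1 mV) and returns below the lower threshold within 5-150 ms; its
  time is the time of the absolute peak. Two candidate peaks closer than the
  refractory period (100 ms) are counted as one *biphasic* spike at the
  larger peak.
* A **seizure** is a paroxysmal event: a run of 0.5 s bins whose peak
  amplitude exceeds a raster threshold a few tens of microvolts above the
  background, lasting at least 10 s with a within-event discharge rate of at
  least 2 Hz. Sub-threshold gaps up to ``gap_tol_s`` are bridged.

Detection operates on the rectified signal throughout, so it is invariant to
trace polarity (population spikes may be negative-going).

Thresholding note: the raster threshold is ``background + offset`` where the
*background* term is, by default, the median per-bin peak amplitude of the
non-paroxysmal signal rather than its standard deviation. A 0.5 s bin at
6 kHz contains thousands of samples, so the expected per-bin *peak* of pure
Gaussian noise sits ~4 sigma above the sigma-level background estimate; an
offset of 20-65 uV is meaningful only relative to the peak level. The
sigma-scale estimator remains available as :func:`estimate_background`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError
from .io import Recording, as_event_table

__all__ = [
    "SpikeTrain",
    "Seizure",
    "DetectParams",
    "estimate_background",
    "background_bin_peak",
    "resolve_seizure_threshold",
    "raster_counts",
    "detect_spikes",
    "detect_seizures",
    "apply_spike_overrides",
    "seizures_to_table",
    "table_to_seizures",
]


@dataclass
class SpikeTrain:
    """Ordered population-spike times and peak magnitudes within one event."""

    times_s: np.ndarray
    peak_amp_v: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.peak_amp_v = np.asarray(self.peak_amp_v, dtype=float)
        if self.times_s.shape != self.peak_amp_v.shape:
            raise ParameterError("times and amplitudes must have equal length")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ParameterError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class Seizure:
    """A detected paroxysmal event with its constituent spikes."""

    channel_id: str
    start_s: float
    end_s: float
    spikes: SpikeTrain
    mean_event_rate_hz: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def onset_s(self) -> float:
        return self.start_s


@dataclass
class DetectParams:
    """Detection thresholds and durations (volts / seconds / hertz).

    ``seizure_thresh_v`` may be given explicitly; when ``None`` it is
    resolved per recording as background-bin-peak + ``seizure_offset_v``.
    """

    upper_v: float = 1e-3
    lower_v: float = 0.5e-3
    min_excursion_s: float = 0.005
    max_excursion_s: float = 0.150
    refractory_s: float = 0.100
    seizure_thresh_v: float | None = None
    seizure_offset_v: float = 40e-6
    bin_s: float = 0.5
    window_s: float = 10.0
    min_seizure_s: float = 10.0
    min_rate_hz: float = 2.0
    gap_tol_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.lower_v < self.upper_v:
            raise ParameterError("lower_v must be below upper_v")
        if not self.min_excursion_s < self.max_excursion_s:
            raise ParameterError("min_excursion_s must be below max_excursion_s")
        for name in ("upper_v", "lower_v", "min_excursion_s", "refractory_s",
                     "bin_s", "window_s", "min_seizure_s", "min_rate_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.gap_tol_s < 0:
            raise ParameterError("gap_tol_s must be non-negative")
        if not 20e-6 <= self.seizure_offset_v <= 65e-6:
            warnings.warn(
                f"seizure_offset_v={self.seizure_offset_v * 1e6:.1f} uV is "
                "outside the usual 20-65 uV range",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# background estimation and thresholds
# ---------------------------------------------------------------------------


def _exclusion_mask(rec: Recording, exclusion, channel_id: str) -> np.ndarray:
    """Boolean mask of samples to *keep* (True = outside excluded events)."""
    keep = np.ones(rec.n_samples, dtype=bool)
    if exclusion is None or len(exclusion) == 0:
        return keep
    tbl = as_event_table(exclusion)
    for _, row in tbl.iterrows():
        if row["channel_id"] not in ("*", channel_id):
            continue
        i0 = max(0, int(np.floor((row["start_s"] - rec.t0_s) * rec.rate_hz)))
        i1 = min(rec.n_samples,
                 int(np.ceil((row["end_s"] - rec.t0_s) * rec.rate_hz)) + 1)
        keep[i0:i1] = False
    return keep


def estimate_background(
    rec: Recording, exclusion=None, channel: int | str = 0
) -> float:
    """Robust sigma-scale of the non-paroxysmal signal, volts.

    Median absolute deviation about the median, scaled by 1.4826 (consistent
    for Gaussian noise), over samples outside the excluded events.
    """
    x = rec.channel(channel)
    cid = rec.channel_ids[channel] if isinstance(channel, int) else channel
    keep = _exclusion_mask(rec, exclusion, cid)
    x = x[keep]
    if x.size < rec.rate_hz:  # need >= 1 s of usable data
        raise EstimationError("less than 1 s of data outside exclusions")
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def _bin_peaks(x_abs: np.ndarray, rate_hz: float, bin_s: float) -> np.ndarray:
    """Peak |amplitude| per consecutive bin (final partial bin included)."""
    spb = int(round(bin_s * rate_hz))
    if spb < 1:
        raise ParameterError("bin_s too small for the sampling rate")
    idx = np.arange(0, x_abs.size, spb)
    return np.maximum.reduceat(x_abs, idx)


def background_bin_peak(
    rec: Recording,
    params: DetectParams | None = None,
    exclusion=None,
    channel: int | str = 0,
) -> float:
    """Median per-bin peak amplitude of the (non-excluded) signal, volts.

    With paroxysmal activity occupying a minority of bins this is a robust
    estimate of the background's typical bin peak, the natural reference
    level for an "offset above background" raster threshold.
    """
    params = params or DetectParams()
    x = np.abs(rec.channel(channel))
    cid = rec.channel_ids[channel] if isinstance(channel, int) else channel
    keep = _exclusion_mask(rec, exclusion, cid)
    x = np.where(keep, x, 0.0)
    peaks = _bin_peaks(x, rec.rate_hz, params.bin_s)
    # drop bins that are fully excluded (peak forced to 0 by the mask)
    spb = int(round(params.bin_s * rec.rate_hz))
    counts = np.add.reduceat(keep.astype(int), np.arange(0, keep.size, spb))
    peaks = peaks[counts > 0]
    if peaks.size == 0:
        raise EstimationError("everything excluded; cannot estimate background")
    return float(np.median(peaks))


def resolve_seizure_threshold(
    rec: Recording,
    params: DetectParams,
    exclusion=None,
    channel: int | str = 0,
) -> float:
    """The raster threshold in volts for one channel."""
    if params.seizure_thresh_v is not None:
        return params.seizure_thresh_v
    return background_bin_peak(rec, params, exclusion, channel) + params.seizure_offset_v


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def raster_counts(
    rec: Recording,
    params: DetectParams | None = None,
    channel: int | str = 0,
    thresh_v: float | None = None,
):
    """Super-threshold bin counts per sliding window.

    Returns ``(window_start_s, counts)`` where each count is the number of
    0.5 s bins whose peak amplitude exceeds the raster threshold within a
    ``window_s`` (10 s) window advanced one bin at a time.
    """
    params = params or DetectParams()
    if rec.duration_s <= params.window_s:
        raise ParameterError("recording shorter than the raster window")
    if thresh_v is None:
        thresh_v = resolve_seizure_threshold(rec, params, channel=channel)
    x = np.abs(rec.channel(channel))
    super_bins = _bin_peaks(x, rec.rate_hz, params.bin_s) > thresh_v
    win_bins = int(round(params.window_s / params.bin_s))
    counts = np.convolve(super_bins.astype(int), np.ones(win_bins, dtype=int),
                         mode="valid")
    starts = rec.t0_s + np.arange(counts.size) * params.bin_s
    return starts, counts


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------


def _regions(mask: np.ndarray):
    """Half-open [i0, i1) runs of True."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends])


def _merge_peaks(times: np.ndarray, amps: np.ndarray, refractory_s: float):
    """Merge peaks closer than the refractory period, keeping the larger.

    Ties keep the earlier peak. Input must be time-sorted.
    """
    kept_t: list[float] = []
    kept_a: list[float] = []
    for t, a in zip(times, amps):
        if kept_t and t - kept_t[-1] <= refractory_s:
            if a > kept_a[-1]:
                kept_t[-1], kept_a[-1] = t, a
        else:
            kept_t.append(t)
            kept_a.append(a)
    return np.asarray(kept_t), np.asarray(kept_a)


def detect_spikes(
    rec: Recording,
    params: DetectParams | None = None,
    bounds: tuple[float, float] | None = None,
    channel: int | str = 0,
) -> SpikeTrain:
    """Dual-threshold population-spike detection on one channel.

    A candidate is a rectified excursion that rises from below ``lower_v``
    above ``upper_v`` and back, spanning 5-150 ms; its time is the absolute
    peak. Candidates whose peaks fall within the refractory period are merged
    as biphasic spikes (larger peak wins; tie keeps the earlier).
    """
    params = params or DetectParams()
    x = rec.channel(channel)
    rate = rec.rate_hz
    lo_idx, hi_idx = 0, x.size
    if bounds is not None:
        # pad the slice so excursions straddling the bound are still seen
        margin = int(np.ceil(params.max_excursion_s * rate))
        lo_idx = max(0, int(np.floor((bounds[0] - rec.t0_s) * rate)) - margin)
        hi_idx = min(x.size, int(np.ceil((bounds[1] - rec.t0_s) * rate)) + margin)
    seg = np.abs(x[lo_idx:hi_idx])

    mask = seg >= params.lower_v
    times, amps = [], []
    for i0, i1 in _regions(mask):
        if i0 == 0 or i1 == seg.size:
            continue  # never started below / returned below the lower threshold
        span = (i1 - i0) / rate
        if not params.min_excursion_s <= span <= params.max_excursion_s:
            continue
        peak = i0 + int(np.argmax(seg[i0:i1]))
        if seg[peak] < params.upper_v:
            continue
        times.append(rec.t0_s + (lo_idx + peak) / rate)
        amps.append(seg[peak])

    t, a = _merge_peaks(np.asarray(times), np.asarray(amps), params.refractory_s)
    if bounds is not None and t.size:
        inside = (t >= bounds[0]) & (t < bounds[1])
        t, a = t[inside], a[inside]
    return SpikeTrain(t, a)


# ---------------------------------------------------------------------------
# seizure detection
# ---------------------------------------------------------------------------


def _bridged_runs(super_bins: np.ndarray, gap_bins: int):
    """Runs of True bins, bridging gaps of <= gap_bins False bins."""
    idx = np.flatnonzero(super_bins)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_bins:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def _excursion_rate(
    seg_abs: np.ndarray, rate: float, thresh_v: float, refractory_s: float
) -> int:
    """Count super-threshold excursions, biphasic-merged, within a segment."""
    regions = _regions(seg_abs > thresh_v)
    if regions.shape[0] == 0:
        return 0
    times = np.empty(regions.shape[0])
    amps = np.empty(regions.shape[0])
    for k, (i0, i1) in enumerate(regions):
        p = i0 + int(np.argmax(seg_abs[i0:i1]))
        times[k] = p / rate
        amps[k] = seg_abs[p]
    t, _ = _merge_peaks(times, amps, refractory_s)
    return t.size


def detect_seizures(
    rec: Recording,
    params: DetectParams | None = None,
    channel: int | str = 0,
    exclusion=None,
    overrides=None,
) -> list[Seizure]:
    """Segment paroxysmal events on one channel.

    Contiguous runs of super-threshold 0.5 s bins (gaps up to ``gap_tol_s``
    bridged) become candidates; candidates shorter than ``min_seizure_s`` or
    with a biphasic-merged super-threshold discharge rate below
    ``min_rate_hz`` are discarded. Spikes are attached via
    :func:`detect_spikes` restricted to the event bounds, with optional
    manual overrides applied afterwards.
    """
    params = params or DetectParams()
    cid = rec.channel_ids[channel] if isinstance(channel, int) else channel
    thr = resolve_seizure_threshold(rec, params, exclusion, channel)
    x = np.abs(rec.channel(channel))
    peaks = _bin_peaks(x, rec.rate_hz, params.bin_s)
    gap_bins = int(round(params.gap_tol_s / params.bin_s))

    seizures: list[Seizure] = []
    for b0, b1 in _bridged_runs(peaks > thr, gap_bins):
        start_s = rec.t0_s + b0 * params.bin_s
        end_s = min(rec.t0_s + (b1 + 1) * params.bin_s,
                    rec.t0_s + rec.duration_s)
        duration = end_s - start_s
        if duration < params.min_seizure_s:
            continue
        i0 = int(round((start_s - rec.t0_s) * rec.rate_hz))
        i1 = int(round((end_s - rec.t0_s) * rec.rate_hz))
        n_exc = _excursion_rate(x[i0:i1], rec.rate_hz, thr, params.refractory_s)
        rate_hz = n_exc / duration
        if rate_hz < params.min_rate_hz:
            continue
        spikes = detect_spikes(rec, params, (start_s, end_s), channel)
        if overrides is not None:
            spikes = apply_spike_overrides(
                spikes, overrides, rec, cid, (start_s, end_s), params
            )
        seizures.append(Seizure(cid, start_s, end_s, spikes, rate_hz))
    return seizures


def apply_spike_overrides(
    train: SpikeTrain,
    overrides,
    rec: Recording,
    channel_id: str,
    bounds: tuple[float, float],
    params: DetectParams | None = None,
) -> SpikeTrain:
    """Apply a manual spike correction table to a detected train.

    Replaces an interactive curation step: rows of an event table with
    ``kind == "spike"`` whose time falls in ``bounds``. A row with
    ``value >= 0`` (or missing) *adds* a spike at that time, its amplitude
    taken from ``value`` if positive else measured from the trace; a row
    with ``value < 0`` *removes* the nearest detected spike within the
    refractory period.
    """
    params = params or DetectParams()
    tbl = as_event_table(overrides)
    times = list(train.times_s)
    amps = list(train.peak_amp_v)
    for _, row in tbl.iterrows():
        if row["kind"] != "spike" or row["channel_id"] not in ("*", channel_id):
            continue
        t = float(row["start_s"])
        if not bounds[0] <= t < bounds[1]:
            continue
        if not pd.isna(row["value"]) and row["value"] < 0:
            if times:
                j = int(np.argmin(np.abs(np.asarray(times) - t)))
                if abs(times[j] - t) <= params.refractory_s:
                    del times[j], amps[j]
        else:
            if pd.isna(row["value"]) or row["value"] == 0:
                k = int(round((t - rec.t0_s) * rec.rate_hz))
                k = min(max(k, 0), rec.n_samples - 1)
                amp = float(abs(rec.channel(channel_id)[k]))
            else:
                amp = float(row["value"])
            times.append(t)
            amps.append(amp)
    order = np.argsort(times)
    t_arr = np.asarray(times)[order]
    a_arr = np.asarray(amps)[order]
    keep = np.ones(t_arr.size, dtype=bool)  # drop exact duplicates
    keep[1:] = np.diff(t_arr) > 0
    return SpikeTrain(t_arr[keep], a_arr[keep])


# ---------------------------------------------------------------------------
# event-table bridging
# ---------------------------------------------------------------------------


def seizures_to_table(seizures: list[Seizure]) -> pd.DataFrame:
    """Serialize seizures (and their spikes) to a canonical event table."""
    rows = []
    for sz in seizures:
        rows.append(
            dict(channel_id=sz.channel_id, start_s=sz.start_s, end_s=sz.end_s,
                 kind="seizure", value=sz.mean_event_rate_hz)
        )
        for t, a in zip(sz.spikes.times_s, sz.spikes.peak_amp_v):
            rows.append(
                dict(channel_id=sz.channel_id, start_s=t, end_s=t,
                     kind="spike", value=a)
            )
    return as_event_table(rows)


def table_to_seizures(tbl) -> list[Seizure]:
    """Rebuild Seizure objects from an event table written by this module."""
    df = as_event_table(tbl)
    seizures = []
    spikes = df[df["kind"] == "spike"]
    for _, row in df[df["kind"] == "seizure"].iterrows():
        sel = spikes[
            (spikes["channel_id"] == row["channel_id"])
            & (spikes["start_s"] >= row["start_s"])
            & (spikes["start_s"] < row["end_s"])
        ].sort_values("start_s")
        train = SpikeTrain(sel["start_s"].to_numpy(), sel["value"].to_numpy())
        seizures.append(
            Seizure(row["channel_id"], float(row["start_s"]), float(row["end_s"]),
                    train, float(row["value"]))
        )
    seizures.sort(key=lambda s: (s.channel_id, s.start_s))
    return seizures
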