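"""Fluorescence (ΔF/F) analysis of electrode-insertion damage.

Pipeline for per-ROI mean-intensity traces from calcium-indicator imaging
(typically ~5 frames/s): estimate a slowly varying baseline F0 by asymmetric
least squares (ALS) smoothing, form ΔF/F = (F - F0)/F0, subtract a reference
ROI to remove culture-wide spontaneous activity, average insertion-aligned
traces, and measure the recovery time after the insertion transient.

ALS baseline
------------
Minimize  sum_i w_i (f_i - z_i)^2 + lam * sum_i (Δ² z_i)^2  with asymmetric
weights w_i = p where f_i > z_i and 1 - p otherwise, iterated ``n_iter``
times (Eilers-Boelens-style smoothing). Small ``p`` makes positive
transients sit *above* the baseline rather than dragging it up; ``lam``
sets the stiffness (second-difference penalty, so linear drift is not
penalized at all and is recovered exactly).

Recovery time
-------------
"Recovered to within ``frac`` of baseline" means |ΔF/F| <= frac (ΔF/F is
already relative to baseline) *sustained* for ``sustain_s`` so single noise
crossings do not count. The reported value is the time from the event to the
first sample of the sustained sub-threshold run after the post-event peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import (
    AlignmentError,
    BaselineError,
    DataError,
    ParameterError,
    UndefinedEventError,
)

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "als_baseline",
    "dff",
    "roi_subtract",
    "align_average",
    "recovery_time",
]


@dataclass
class FluorescenceTrace:
    """A per-ROI mean-intensity trace (arbitrary units, uniform sampling)."""

    t_s: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t_s.shape != self.f.shape or self.t_s.ndim != 1:
            raise ParameterError("t_s and f must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.f)):
            raise DataError("non-finite fluorescence values")
        if self.t_s.size >= 2:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0):
                raise ParameterError("time must be strictly increasing")
            if np.max(np.abs(dt - np.median(dt))) > 0.01 * np.median(dt):
                raise ParameterError("sampling non-uniform beyond 1% tolerance")

    @property
    def rate_hz(self) -> float:
        if self.t_s.size < 2:
            raise ParameterError("need >= 2 samples for a rate")
        return 1.0 / float(np.median(np.diff(self.t_s)))


@dataclass
class DffTrace:
    """ΔF/F trace with the baseline it was computed against."""

    t_s: np.ndarray
    dff: np.ndarray
    f0: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if not (self.t_s.shape == self.dff.shape == self.f0.shape):
            raise ParameterError("t_s, dff, f0 must share one length")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))


def als_baseline(
    trace: FluorescenceTrace | np.ndarray,
    lam: float = 1e5,
    p: float = 0.01,
    n_iter: int = 10,
    exclude: tuple[float, float] | None = None,
) -> np.ndarray:
    """Asymmetric least squares baseline of a fluorescence trace.

    ``exclude`` optionally names a time span (seconds; requires a
    :class:`FluorescenceTrace`) whose samples get (near-)zero weight, so
    the smoothness penalty bridges them. Use this when a known, long
    event-locked transient (e.g. an electrode insertion) would otherwise
    be partially absorbed into the baseline: no finite stiffness keeps a
    transient lasting thousands of samples entirely above the fit.
    """
    is_trace = isinstance(trace, FluorescenceTrace)
    f = trace.f if is_trace else np.asarray(trace, float)
    if f.size < 10:
        raise ParameterError("need >= 10 samples for a baseline")
    if not np.all(np.isfinite(f)):
        raise DataError("non-finite input")
    if not 0 < p < 1:
        raise ParameterError("p must lie in (0, 1)")
    if lam <= 0:
        raise ParameterError("lam must be positive")
    n = f.size
    keep = np.ones(n)
    if exclude is not None:
        if not is_trace:
            raise ParameterError("exclude requires a FluorescenceTrace input")
        inside = (trace.t_s >= exclude[0]) & (trace.t_s < exclude[1])
        if inside.all():
            raise ParameterError("cannot exclude the whole trace")
        keep[inside] = 1e-8
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = f.copy()
    for _ in range(n_iter):
        W = sparse.diags(w * keep, format="csc")
        z = spsolve((W + penalty).tocsc(), w * keep * f)
        w = np.where(f > z, p, 1.0 - p)
    return np.asarray(z)


def dff(trace: FluorescenceTrace, baseline: np.ndarray) -> DffTrace:
    """ΔF/F = (F - F0)/F0 against a positive baseline."""
    f0 = np.asarray(baseline, dtype=float)
    if f0.shape != trace.f.shape:
        raise ParameterError("baseline length must match the trace")
    if np.any(f0 <= 0):
        raise BaselineError("baseline must be positive everywhere")
    return DffTrace(trace.t_s.copy(), (trace.f - f0) / f0, f0)


def roi_subtract(affected: DffTrace, reference: DffTrace) -> DffTrace:
    """Subtract a reference-ROI ΔF/F to remove culture-wide activity.

    The reference is linearly resampled onto the affected trace's timebase
    when the rates differ by more than 1%; samples outside the reference's
    support raise an alignment error.
    """
    ref = reference.dff
    if affected.t_s.shape == reference.t_s.shape and np.allclose(
        affected.t_s, reference.t_s
    ):
        pass
    else:
        if (
            affected.t_s[0] < reference.t_s[0] - 1e-9
            or affected.t_s[-1] > reference.t_s[-1] + 1e-9
        ):
            raise AlignmentError("reference does not cover the affected timebase")
        ref = np.interp(affected.t_s, reference.t_s, reference.dff)
    return DffTrace(affected.t_s.copy(), affected.dff - ref, affected.f0.copy())


def align_average(traces, event_times_s):
    """Event-aligned mean and SD of several ΔF/F traces.

    Each trace is shifted so its event time becomes 0, all are truncated to
    the common support and interpolated onto the first trace's sample grid;
    returns ``(t_rel_s, mean, sd)`` with sample (n-1) SD.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ParameterError("need >= 2 traces to align and average")
    if len(event_times_s) != len(traces):
        raise ParameterError("one event time per trace required")
    rates = [tr.rate_hz for tr in traces]
    if max(rates) / min(rates) > 1.01:
        raise AlignmentError("trace sampling rates differ by more than 1%")
    rels = [tr.t_s - ev for tr, ev in zip(traces, event_times_s)]
    for tr, ev in zip(traces, event_times_s):
        if not tr.t_s[0] <= ev <= tr.t_s[-1]:
            raise ParameterError("event time outside its trace")
    lo = max(r[0] for r in rels)
    hi = min(r[-1] for r in rels)
    if hi <= lo:
        raise AlignmentError("aligned traces have no overlapping support")
    dt = 1.0 / rates[0]
    grid = np.arange(lo, hi + dt / 2, dt)
    stack = np.vstack(
        [np.interp(grid, r, tr.dff) for r, tr in zip(rels, traces)]
    )
    return grid, stack.mean(axis=0), stack.std(axis=0, ddof=1)


def insertion_dff(
    affected: FluorescenceTrace,
    reference: FluorescenceTrace,
    event_s: float,
    lam: float = 1e10,
    p: float = 0.01,
    exclude_s: float = 1800.0,
) -> DffTrace:
    """Reference-subtracted ΔF/F around a known insertion event.

    Baselines both ROIs by ALS; the affected ROI's fit excludes
    ``[event_s, event_s + exclude_s)`` so the insertion transient (which
    outlasts any practical ALS stiffness) cannot be absorbed into F0. The
    default stiffness is much higher than for ordinary baselining: the
    penalty must bridge the excluded gap with a stable slope, which needs a
    smoothing length of minutes rather than seconds.
    """
    za = als_baseline(affected, lam=lam, p=p,
                      exclude=(event_s, event_s + exclude_s))
    zr = als_baseline(reference, lam=lam, p=p)
    return roi_subtract(dff(affected, za), dff(reference, zr))


def recovery_time(
    trace: DffTrace,
    event_s: float,
    frac: float = 0.02,
    sustain_s: float = 60.0,
) -> float:
    """Time from the event until |ΔF/F| stays within ``frac`` of baseline.

    Finds the post-event peak of |ΔF/F| (which must exceed ``frac``, else
    the event-locked transient is undefined), then the first time after the
    peak from which |ΔF/F| <= frac holds for at least ``sustain_s`` (a run
    reaching the end of the trace counts). Returns NaN when the trace never
    recovers.
    """
    if not trace.t_s[0] <= event_s <= trace.t_s[-1]:
        raise ParameterError("event time outside the trace")
    post = trace.t_s >= event_s
    if post.sum() < 2:
        raise ParameterError("no post-event data")
    t = trace.t_s[post]
    a = np.abs(trace.dff[post])
    ipk = int(np.argmax(a))
    if a[ipk] <= frac:
        raise UndefinedEventError("no post-event excursion beyond frac")
    below = a <= frac
    below[: ipk + 1] = False
    rate = trace.rate_hz
    need = max(1, int(round(sustain_s * rate)))
    run = 0
    candidate: int | None = None
    for i in range(t.size - 1, ipk, -1):
        # scan backwards: run = length of the below-run starting at i
        run = run + 1 if below[i] else 0
        if below[i] and (run >= need or i + run == t.size):
            candidate = i
    if candidate is None:
        return float("nan")
    return float(t[candidate] - event_s)
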