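"""Time-resolved jitter, state-transition calling and variability summaries.

Seizure waveforms in chronic in vitro recordings drift: cultures settle into
a stable waveform (low jitter between nearby seizures), occasionally passing
through transient periods during which the waveform reorganizes (high
jitter). This module tracks the mean pairwise jitter in a sliding window
(default 1 h, stepped 10 min), calls *state transitions* where that trace
exceeds its own mean by ``k`` standard deviations (default 2), and provides
the routine dispersion summaries used alongside: Fano factors of seizure
durations/intervals and the Pearson correlation between windowed jitter and
windowed duration/interval variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .jitter import jitter

__all__ = [
    "JitterTrace",
    "TransitionEvent",
    "windowed_jitter",
    "event_windowed_jitter",
    "bin_trace",
    "detect_transitions",
    "state_vs_transition_jitter",
    "fano",
    "jitter_variability_correlation",
]


@dataclass
class JitterTrace:
    """Windowed jitter time series.

    ``jitter_pct`` is NaN where a window held fewer than 2 seizures.
    ``window_s`` is the window length the trace was built with (0 for
    event-count windows, where the window is a fixed number of events).
    """

    window_start_s: np.ndarray
    jitter_pct: np.ndarray
    n_seizures_in_window: np.ndarray
    window_s: float = 0.0
    step_s: float = 0.0

    def __post_init__(self) -> None:
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        self.jitter_pct = np.asarray(self.jitter_pct, dtype=float)
        self.n_seizures_in_window = np.asarray(self.n_seizures_in_window, dtype=int)
        if not (
            self.window_start_s.shape
            == self.jitter_pct.shape
            == self.n_seizures_in_window.shape
        ):
            raise ParameterError("trace arrays must share one length")
        if self.window_start_s.size > 1 and np.any(np.diff(self.window_start_s) <= 0):
            raise ParameterError("windows must be strictly ordered")

    def __len__(self) -> int:
        return self.window_start_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start_s": self.window_start_s,
                "jitter_pct": self.jitter_pct,
                "n_seizures_in_window": self.n_seizures_in_window,
            }
        )


@dataclass(frozen=True)
class TransitionEvent:
    """A maximal run of super-threshold jitter windows.

    ``onset_s`` is the start of the first super-threshold window and
    ``offset_s`` the end of the last. Because every window *containing* a
    waveform change shows elevated jitter, the unbiased point estimate of
    the transition time is the midpoint ``time_s``.
    """

    onset_s: float
    offset_s: float
    peak_jitter_pct: float

    @property
    def time_s(self) -> float:
        return 0.5 * (self.onset_s + self.offset_s)


class _PairCache:
    """Memoized pairwise jitter over a fixed seizure list."""

    def __init__(self, seizures):
        self.seizures = seizures
        self._cache: dict[tuple[int, int], float] = {}

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        if (i, j) not in self._cache:
            si, sj = self.seizures[i], self.seizures[j]
            if len(si.spikes) < 2 or len(sj.spikes) < 2:
                self._cache[(i, j)] = np.nan
            else:
                self._cache[(i, j)] = jitter(si.spikes, sj.spikes).jitter_pct
        return self._cache[(i, j)]

    def mean_over(self, idx) -> float:
        vals = [self.get(i, j) for a, i in enumerate(idx) for j in idx[a + 1:]]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else np.nan


def _onsets(seizures) -> np.ndarray:
    on = np.asarray([s.start_s for s in seizures], dtype=float)
    if on.size > 1 and np.any(np.diff(on) < 0):
        raise ParameterError("seizures must be time-ordered")
    return on


def windowed_jitter(
    seizures,
    window_s: float = 3600.0,
    step_s: float = 600.0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> JitterTrace:
    """Mean pairwise jitter in a sliding time window.

    A seizure belongs to the window ``[w, w + window_s)`` if its onset does;
    each trace point is the mean jitter over all unique pairs in the window,
    NaN where fewer than 2 seizures fall inside.
    """
    if window_s <= 0 or step_s <= 0:
        raise ParameterError("window_s and step_s must be positive")
    onsets = _onsets(seizures)
    if onsets.size == 0:
        raise ParameterError("no seizures")
    t_start = onsets[0] if t_start is None else t_start
    t_end = onsets[-1] if t_end is None else t_end
    starts = np.arange(t_start, t_end + step_s / 2, step_s)
    cache = _PairCache(list(seizures))
    vals = np.full(starts.size, np.nan)
    counts = np.zeros(starts.size, dtype=int)
    for w, ws in enumerate(starts):
        idx = np.flatnonzero((onsets >= ws) & (onsets < ws + window_s))
        counts[w] = idx.size
        if idx.size >= 2:
            vals[w] = cache.mean_over(list(idx))
    return JitterTrace(starts, vals, counts, window_s, step_s)


def event_windowed_jitter(seizures, events_per_window: int = 2) -> JitterTrace:
    """Jitter over consecutive runs of ``events_per_window`` seizures.

    The window advances one seizure per step; each point is stamped with the
    onset of the first seizure in its run. This is the natural windowing for
    short recordings where a fixed time window would often be empty.
    """
    if events_per_window < 2:
        raise ParameterError("events_per_window must be >= 2")
    seizures = list(seizures)
    if len(seizures) < events_per_window:
        raise ParameterError(
            f"need >= {events_per_window} seizures, got {len(seizures)}"
        )
    onsets = _onsets(seizures)
    cache = _PairCache(seizures)
    n_pts = len(seizures) - events_per_window + 1
    starts = onsets[:n_pts]
    vals = np.asarray(
        [cache.mean_over(list(range(i, i + events_per_window))) for i in range(n_pts)]
    )
    counts = np.full(n_pts, events_per_window)
    return JitterTrace(starts, vals, counts, 0.0, 0.0)


def bin_trace(trace: JitterTrace, bin_s: float = 300.0) -> pd.DataFrame:
    """Box-plot-ready per-bin summaries of a jitter trace.

    Returns one row per ``bin_s`` bin holding the median, quartiles, range
    and count of the non-missing trace values whose window start falls in
    the bin.
    """
    if len(trace) == 0:
        raise ParameterError("empty trace")
    if bin_s <= 0:
        raise ParameterError("bin_s must be positive")
    ok = ~np.isnan(trace.jitter_pct)
    t = trace.window_start_s[ok]
    v = trace.jitter_pct[ok]
    t0 = trace.window_start_s[0]
    rows = []
    for b in np.unique(np.floor((t - t0) / bin_s).astype(int)):
        sel = v[(t >= t0 + b * bin_s) & (t < t0 + (b + 1) * bin_s)]
        rows.append(
            dict(
                bin_start_s=t0 + b * bin_s,
                median=float(np.median(sel)),
                q25=float(np.percentile(sel, 25)),
                q75=float(np.percentile(sel, 75)),
                low=float(np.min(sel)),
                high=float(np.max(sel)),
                n=int(sel.size),
            )
        )
    return pd.DataFrame(rows)


def detect_transitions(trace: JitterTrace, k_sd: float = 2.0) -> list[TransitionEvent]:
    """Call state transitions from a windowed jitter trace.

    The threshold is ``mean + k_sd * SD`` of the trace's own non-missing
    values (sample SD); maximal runs of consecutive super-threshold windows
    become one event each. Missing windows break runs. A constant trace
    (SD = 0) yields no transitions: nothing exceeds its own mean.
    """
    vals = trace.jitter_pct
    ok = ~np.isnan(vals)
    if ok.sum() < 3:
        raise ParameterError("need >= 3 non-missing trace points")
    mean = float(np.mean(vals[ok]))
    sd = float(np.std(vals[ok], ddof=1))
    thresh = mean + k_sd * sd
    above = ok & (vals > thresh)
    events: list[TransitionEvent] = []
    i = 0
    n = len(trace)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        onset = float(trace.window_start_s[i])
        offset = float(trace.window_start_s[j] + (trace.window_s or trace.step_s))
        events.append(
            TransitionEvent(onset, offset, float(np.nanmax(vals[i : j + 1])))
        )
        i = j + 1
    return events


def state_vs_transition_jitter(seizures, transitions):
    """Within-state vs cross-state jitter samples around called transitions.

    States are the gaps between consecutive transitions (plus before the
    first and after the last); seizures with onsets inside a transition's
    ``[onset_s, offset_s]`` span belong to no state. Returns
    ``(within, cross)`` arrays: pairwise jitters inside single states, and
    pairwise jitters between seizures of adjacent states (straddling one
    transition). Either array may be empty when states hold < 2 seizures.
    """
    seizures = list(seizures)
    onsets = _onsets(seizures)
    edges = sorted(transitions, key=lambda tr: tr.onset_s)
    # state s spans (end of transition s-1, start of transition s)
    state_members: list[list[int]] = []
    starts = [-np.inf] + [tr.offset_s for tr in edges]
    stops = [tr.onset_s for tr in edges] + [np.inf]
    for lo, hi in zip(starts, stops):
        state_members.append(
            [i for i, t in enumerate(onsets) if lo <= t < hi]
        )
    cache = _PairCache(seizures)
    within, cross = [], []
    for members in state_members:
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                v = cache.get(members[a], members[b])
                if not np.isnan(v):
                    within.append(v)
    for s in range(len(state_members) - 1):
        for i in state_members[s]:
            for j in state_members[s + 1]:
                v = cache.get(i, j)
                if not np.isnan(v):
                    cross.append(v)
    return np.asarray(within), np.asarray(cross)


def fano(values) -> float:
    """Fano factor: sample variance (n-1 denominator) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("need >= 2 values for a Fano factor")
    mean = float(np.mean(v))
    if mean <= 0:
        raise ParameterError("Fano factor requires a positive mean")
    return float(np.var(v, ddof=1) / mean)


def jitter_variability_correlation(
    trace: JitterTrace, seizures, stat: str = "duration_sd"
):
    """Pearson correlation between windowed jitter and windowed variability.

    For each trace window, the SD (sample) of either the durations of the
    seizures whose onsets fall in the window (``stat="duration_sd"``) or of
    the inter-seizure onset intervals within it (``stat="interval_sd"``) is
    paired with the window's jitter; windows missing either quantity are
    dropped. Returns ``(r, p, n)`` with a two-sided p-value.
    """
    if stat not in ("duration_sd", "interval_sd"):
        raise ParameterError(f"unknown stat {stat!r}")
    seizures = list(seizures)
    onsets = _onsets(seizures)
    durations = np.asarray([s.duration_s for s in seizures])
    xs, ys = [], []
    win = trace.window_s or np.inf
    for ws, jit in zip(trace.window_start_s, trace.jitter_pct):
        if np.isnan(jit):
            continue
        idx = np.flatnonzero((onsets >= ws) & (onsets < ws + win))
        if stat == "duration_sd":
            if idx.size < 2:
                continue
            y = float(np.std(durations[idx], ddof=1))
        else:
            if idx.size < 3:
                continue
            y = float(np.std(np.diff(onsets[idx]), ddof=1))
        xs.append(jit)
        ys.append(y)
    if len(xs) < 3:
        raise ParameterError("fewer than 3 paired windows")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), len(xs)
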