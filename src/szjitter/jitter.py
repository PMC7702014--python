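"""The jitter statistic: inter-spike-interval similarity between seizures.

Two seizures are compared through their inter-spike-interval (ISI)
sequences. After choosing one *alignment spike* in each train, intervals are
indexed by their signed offset from the alignment spike and paired across
trains at matching offsets; the jitter is

    jitter = 100 * mean_i |I1_i - I2_i| / ((I1_i + I2_i) / 2)   [percent]

over the paired intervals. The reported value is the minimum over all
alignment-spike choices, so the statistic is invariant to global time shifts
of either train and to which spike a seizure "starts" with.

Each paired term is bounded by 2 for positive intervals, so
0 <= jitter <= 200 %. The statistic is dimensionless: rescaling all
intervals of both trains by a common factor leaves it unchanged.

Implementation note: the set of intervals paired at alignment ``(ia, ib)``
depends only on the difference ``ib - ia``, so minimizing over all O(n^2)
alignment pairs reduces to minimizing the mean over each diagonal of the
normalized-interval-difference matrix -- O(n_a * n_b) total. The exhaustive
search over alignment pairs is therefore exact, not heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Seizure, SpikeTrain
from .errors import AlignmentError, InsufficientSpikesError, ParameterError

__all__ = [
    "JitterResult",
    "intervals",
    "jitter_at_alignment",
    "jitter",
    "pairwise_jitter",
]


@dataclass(frozen=True)
class JitterResult:
    """Minimum-alignment jitter between two seizures.

    ``align_idx_1`` / ``align_idx_2`` are 0-based spike indices of the
    alignment spikes achieving the minimum (ties broken lexicographically);
    ``n_interval`` is the number of interval pairs entering the mean.
    """

    jitter_pct: float
    align_idx_1: int
    align_idx_2: int
    n_interval: int


def _train(x) -> SpikeTrain:
    if isinstance(x, Seizure):
        return x.spikes
    if isinstance(x, SpikeTrain):
        return x
    return SpikeTrain(np.asarray(x, dtype=float),
                      np.full(len(x), np.nan))


def intervals(train) -> np.ndarray:
    """Successive inter-spike intervals in seconds (length ``n_spikes - 1``)."""
    t = _train(train).times_s
    if t.size < 2:
        raise InsufficientSpikesError(
            f"need >= 2 spikes to form intervals, got {t.size}"
        )
    iv = np.diff(t)
    if np.any(iv <= 0):
        raise ParameterError("spike times must be strictly increasing")
    return iv


def _norm_diff_matrix(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """|Ia_p - Ib_q| / ((Ia_p + Ib_q)/2) for every interval pair."""
    a = ia[:, None]
    b = ib[None, :]
    return np.abs(a - b) / ((a + b) / 2.0)


def jitter_at_alignment(
    a, b, ia: int, ib: int, pairing: str = "signed"
) -> tuple[float, int]:
    """Jitter (percent) and pair count at a fixed alignment ``(ia, ib)``.

    With ``pairing="signed"`` intervals are matched at every signed offset
    from the alignment spike present in both trains; ``pairing="forward"``
    uses non-negative offsets only.
    """
    iv_a, iv_b = intervals(a), intervals(b)
    na, nb = iv_a.size + 1, iv_b.size + 1
    if not (0 <= ia < na and 0 <= ib < nb):
        raise ParameterError(f"alignment indices ({ia}, {ib}) out of range")
    if pairing not in ("signed", "forward"):
        raise ParameterError(f"unknown pairing {pairing!r}")
    k = ib - ia
    lo = max(0, -k) if pairing == "signed" else ia
    hi = min(iv_a.size - 1, iv_b.size - 1 - k)
    if hi < lo:
        raise AlignmentError(
            f"alignment ({ia}, {ib}) pairs zero intervals"
        )
    ja = np.arange(lo, hi + 1)
    terms = np.abs(iv_a[ja] - iv_b[ja + k]) / ((iv_a[ja] + iv_b[ja + k]) / 2.0)
    return 100.0 * float(np.mean(terms)), ja.size


def jitter(a, b, pairing: str = "signed", max_shift: int | None = None) -> JitterResult:
    """Minimum jitter between two trains over all alignment-spike pairs.

    ``max_shift`` optionally restricts the search to alignments with
    ``|ia - ib| <= max_shift`` (a windowed search; the default searches
    everything). Ties are broken by the lexicographically smallest
    ``(ia, ib)``.
    """
    iv_a, iv_b = intervals(a), intervals(b)
    na, nb = iv_a.size + 1, iv_b.size + 1

    if pairing == "forward":
        return _jitter_forward(iv_a, iv_b, na, nb, max_shift)
    if pairing != "signed":
        raise ParameterError(f"unknown pairing {pairing!r}")

    d = _norm_diff_matrix(iv_a, iv_b)
    best: JitterResult | None = None
    # visit k in tie-break order: (0,0),(0,1).. then (1,0),(2,0)..
    ks = list(range(0, nb)) + list(range(-1, -na, -1))
    for k in ks:
        if max_shift is not None and abs(k) > max_shift:
            continue
        diag = np.diagonal(d, offset=k)
        if diag.size == 0:
            continue
        val = 100.0 * float(np.mean(diag))
        if best is None or val < best.jitter_pct - 1e-12:
            ia = max(0, -k)
            best = JitterResult(val, ia, ia + k, diag.size)
    if best is None:
        raise AlignmentError("no alignment pairs any intervals")
    return best


def _jitter_forward(iv_a, iv_b, na, nb, max_shift) -> JitterResult:
    d = _norm_diff_matrix(iv_a, iv_b)
    best = None
    for ia in range(na):
        for ib in range(nb):
            if max_shift is not None and abs(ia - ib) > max_shift:
                continue
            k = ib - ia
            lo, hi = ia, min(iv_a.size - 1, iv_b.size - 1 - k)
            if hi < lo:
                continue
            ja = np.arange(lo, hi + 1)
            val = 100.0 * float(np.mean(d[ja, ja + k]))
            if best is None or val < best.jitter_pct - 1e-12:
                best = JitterResult(val, ia, ib, ja.size)
    if best is None:
        raise AlignmentError("no alignment pairs any intervals")
    return best


def pairwise_jitter(seizures, pairing: str = "signed") -> np.ndarray:
    """Symmetric matrix of pairwise jitter percentages.

    Entries involving seizures with fewer than 2 spikes are NaN (their whole
    row/column, including the diagonal, is marked missing rather than being
    silently dropped). The diagonal is 0 for valid seizures.
    """
    if len(seizures) < 2:
        raise ParameterError("need at least 2 seizures")
    trains = [_train(s) for s in seizures]
    valid = [len(t) >= 2 for t in trains]
    n = len(trains)
    out = np.full((n, n), np.nan)
    for i in range(n):
        if valid[i]:
            out[i, i] = 0.0
        for j in range(i + 1, n):
            if valid[i] and valid[j]:
                val = jitter(trains[i], trains[j], pairing=pairing).jitter_pct
                out[i, j] = out[j, i] = val
    return out
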