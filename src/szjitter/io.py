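"""Recording and event-table I/O and the shared data model.

The in-memory substrate of every analysis is a :class:`Recording`: a
channels-by-timepoints array of extracellular voltage in **volts** at a
uniform sampling rate. Detected events (population spikes, seizures, state
transitions) travel as a plain :class:`pandas.DataFrame` with the fixed
column set :data:`EVENT_COLUMNS`, validated and sorted by
:func:`as_event_table`.

Two storage formats are supported: CSV (lossless, the primary format) and a
minimal EDF implementation (16-bit quantized, as the format dictates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, SamplingError

__all__ = [
    "Recording",
    "EVENT_COLUMNS",
    "EVENT_KINDS",
    "as_event_table",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]

#: Canonical event-table columns. ``kind`` is one of :data:`EVENT_KINDS`;
#: for ``kind == "spike"`` the row is an instant (``start_s == end_s``) and
#: ``value`` holds the peak amplitude in volts where known.
EVENT_COLUMNS = ("channel_id", "start_s", "end_s", "kind", "value")
EVENT_KINDS = ("spike", "seizure", "transition")

_UNIT_SCALE = {"V": 1.0, "mV": 1e-3, "uV": 1e-6, "µV": 1e-6}

_TIME_COLUMNS = ("time_s", "time", "t_s", "t")


@dataclass
class Recording:
    """A uniformly sampled multichannel voltage recording.

    Parameters
    ----------
    samples:
        Array of shape ``(n_channels, n_samples)`` in volts. 1-D input is
        promoted to a single channel.
    rate_hz:
        Sampling rate in samples per second (> 0).
    t0_s:
        Time of the first sample, seconds. Sample ``k`` of any channel is at
        ``t0_s + k / rate_hz``.
    channel_ids:
        One label per channel; defaults to ``ch0, ch1, ...``.
    meta:
        Free-form annotations (modality, media-exchange time, ...).
    """

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    channel_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 1-D or 2-D array")
        if not (self.rate_hz > 0):
            raise SamplingError(f"rate_hz must be positive, got {self.rate_hz}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        """Per-sample time stamps, seconds."""
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, key: int | str) -> np.ndarray:
        """One channel's trace, by index or id."""
        if isinstance(key, str):
            key = self.channel_ids.index(key)
        return self.samples[key]


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


def as_event_table(rows) -> pd.DataFrame:
    """Validate, coerce and sort an event table.

    Accepts a DataFrame or any record collection with the columns of
    :data:`EVENT_COLUMNS`; returns a sorted copy (by ``channel_id`` then
    ``start_s``) with a fresh integer index.
    """
    df = pd.DataFrame(rows)
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=list(EVENT_COLUMNS))
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"event table missing columns {missing}")
    df = df.loc[:, list(EVENT_COLUMNS)].copy()
    df["channel_id"] = df["channel_id"].astype(str)
    for col in ("start_s", "end_s", "value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["kind"] = df["kind"].astype(str)
    for i, row in df.iterrows():
        if row["kind"] not in EVENT_KINDS:
            raise ParseError(f"unknown event kind {row['kind']!r}", row=int(i))
        if math.isnan(row["start_s"]) or math.isnan(row["end_s"]):
            raise ParseError("non-numeric start_s/end_s", row=int(i))
        if row["start_s"] > row["end_s"]:
            raise ParseError("start_s > end_s", row=int(i))
        if row["kind"] == "spike" and row["start_s"] != row["end_s"]:
            raise ParseError("spike rows must have start_s == end_s", row=int(i))
    df = df.sort_values(["channel_id", "start_s"], kind="stable")
    return df.reset_index(drop=True)


def write_events(tbl, path) -> None:
    """Write an event table as CSV (validated and sorted first)."""
    as_event_table(tbl).to_csv(path, index=False, float_format="%.9g")


def read_events(path) -> pd.DataFrame:
    """Read an event-table CSV written by :func:`write_events`."""
    try:
        df = pd.read_csv(path, dtype={"channel_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse event CSV {path}: {exc}") from exc
    return as_event_table(df)


# ---------------------------------------------------------------------------
# CSV recordings
# ---------------------------------------------------------------------------


def _detect_format(path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("edf", "csv"):
            raise FormatError(f"unknown format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer format from {path!r}")


def _read_csv_recording(path, rate_hz, unit, t0_s) -> Recording:
    if unit not in _UNIT_SCALE:
        raise FormatError(f"unknown amplitude unit {unit!r}")
    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c.lower() in _TIME_COLUMNS), None)
    if time_col is not None:
        t = df[time_col].to_numpy(dtype=float)
        if len(t) < 2:
            raise SamplingError("need at least 2 samples to infer a rate")
        dt = np.diff(t)
        dt_med = float(np.median(dt))
        if dt_med <= 0:
            raise SamplingError("time column is not strictly increasing")
        if np.max(np.abs(dt - dt_med)) > 1e-6 * dt_med:
            raise SamplingError("timestamps non-uniform beyond 1 ppm tolerance")
        inferred = 1.0 / dt_med
        if abs(inferred - round(inferred)) < 1e-6 * inferred:
            inferred = float(round(inferred))  # undo decimal round-trip fuzz
        if rate_hz is not None and abs(inferred - rate_hz) > 1e-6 * rate_hz:
            raise SamplingError(
                f"declared rate {rate_hz} Hz conflicts with time column "
                f"({inferred:.6g} Hz)"
            )
        rate_hz = rate_hz or inferred
        t0_s = float(t[0])
        df = df.drop(columns=[time_col])
    elif rate_hz is None:
        raise SamplingError("CSV has no time column; pass rate_hz explicitly")
    if df.shape[1] == 0:
        raise FormatError("CSV contains no channel columns")
    scale = _UNIT_SCALE[unit]
    samples = df.to_numpy(dtype=float).T * scale
    return Recording(samples, float(rate_hz), t0_s, list(map(str, df.columns)))


def _write_csv_recording(rec: Recording, path) -> None:
    data = {"time_s": rec.times()}
    for cid, trace in zip(rec.channel_ids, rec.samples):
        data[cid] = trace
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# EDF recordings (minimal, self-contained)
# ---------------------------------------------------------------------------
# EDF stores an ASCII header followed by little-endian int16 data records.
# Amplitudes are 16-bit quantized over a per-channel physical range; the
# sampling rate round-trips exactly (integer samples per 1 s record). The
# true sample count is stashed in the reserved header field so padding in the
# final record can be stripped on read.


def _ascii(value, width: int) -> bytes:
    s = f"{value}"[:width]
    return s.ljust(width).encode("ascii")


def _write_edf_recording(rec: Recording, path) -> None:
    rate = rec.rate_hz
    spr = int(round(rate))
    if abs(spr - rate) > 1e-9 * max(rate, 1.0):
        raise FormatError("EDF writer requires an integer sampling rate in Hz")
    ns = rec.n_channels
    n_records = int(math.ceil(rec.n_samples / spr))
    header_bytes = 256 * (1 + ns)

    pmins, pmaxs, scaled = [], [], []
    for trace in rec.samples:
        lo, hi = float(np.min(trace)), float(np.max(trace))
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        # widen slightly, then re-parse the 8-char ASCII serialization so the
        # digitization uses exactly the stored (truncated) range
        span = hi - lo
        lo = float(f"{lo - 1e-3 * span:.6g}"[:8])
        hi = float(f"{hi + 1e-3 * span:.6g}"[:8])
        pmins.append(lo)
        pmaxs.append(hi)
        gain = 65535.0 / (hi - lo)
        dig = np.round((trace - lo) * gain - 32768.0)
        dig = np.clip(dig, -32768, 32767).astype(np.int16)
        pad = n_records * spr - len(dig)
        if pad:
            dig = np.concatenate([dig, np.zeros(pad, dtype=np.int16)])
        scaled.append(dig)

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X", 80))  # patient
        fh.write(_ascii("X", 80))  # recording
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii(f"NS={rec.n_samples} T0={rec.t0_s:.9g}", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))  # record duration, s
        fh.write(_ascii(ns, 4))
        for cid in rec.channel_ids:
            fh.write(_ascii(cid, 16))
        for _ in range(ns):
            fh.write(_ascii("", 80))  # transducer
        for _ in range(ns):
            fh.write(_ascii("V", 8))
        for lo in pmins:
            fh.write(_ascii(f"{lo:.6g}", 8))
        for hi in pmaxs:
            fh.write(_ascii(f"{hi:.6g}", 8))
        for _ in range(ns):
            fh.write(_ascii(-32768, 8))
        for _ in range(ns):
            fh.write(_ascii(32767, 8))
        for _ in range(ns):
            fh.write(_ascii("", 80))  # prefilter
        for _ in range(ns):
            fh.write(_ascii(spr, 8))
        for _ in range(ns):
            fh.write(_ascii("", 32))
        for r in range(n_records):
            for dig in scaled:
                fh.write(dig[r * spr : (r + 1) * spr].tobytes())


def _read_edf_recording(path) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        reserved = head[192:236].decode("ascii", "replace").split()
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)
        labels = [
            sig[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(ns)
        ]
        off = 16 * ns + 80 * ns + 8 * ns
        pmins = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        pmaxs = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dmins = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dmaxs = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns + 80 * ns
        sprs = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        if len(set(sprs)) != 1:
            raise FormatError("mixed per-channel rates are not supported")
        spr = sprs[0]
        data = fh.read(2 * spr * ns * n_records)
    raw = np.frombuffer(data, dtype="<i2").reshape(n_records, ns, spr)
    samples = np.empty((ns, n_records * spr))
    for i in range(ns):
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        dig = raw[:, i, :].astype(np.float64).reshape(-1)
        samples[i] = (dig - dmins[i]) * gain + pmins[i]
    n_true, t0_s = n_records * spr, 0.0
    for token in reserved:
        if token.startswith("NS="):
            n_true = int(token[3:])
        elif token.startswith("T0="):
            t0_s = float(token[3:])
    rate = spr / record_dur
    return Recording(samples[:, :n_true], rate, t0_s, labels)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def read_recording(
    path,
    format: str = "auto",
    *,
    rate_hz: float | None = None,
    unit: str = "V",
    t0_s: float = 0.0,
) -> Recording:
    """Read a recording from CSV or EDF.

    CSV files must carry a header; a column named ``time_s``/``time``/``t``
    provides the time axis (checked uniform to 1 ppm), otherwise ``rate_hz``
    must be passed. ``unit`` declares the stored amplitude unit (``"V"``,
    ``"mV"`` or ``"uV"``); samples are converted to volts.
    """
    fmt = _detect_format(path, format)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        return _read_csv_recording(path, rate_hz, unit, t0_s)
    return _read_edf_recording(path)


def write_recording(rec: Recording, path, format: str = "auto") -> None:
    """Write a recording as CSV (lossless) or EDF (16-bit quantized)."""
    if rec.n_channels == 0 or rec.n_samples == 0:
        raise FormatError("cannot write an empty recording")
    fmt = _detect_format(path, format)
    if fmt == "csv":
        _write_csv_recording(rec, path)
    else:
        _write_edf_recording(rec, path)
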