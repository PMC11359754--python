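"""Reading, writing and epoching of multichannel EEG recordings.

A :class:`Recording` is a channels x samples matrix in microvolts with a
uniform sampling rate.  Recordings round-trip through two on-disk formats:

* EDF (European Data Format), written as a single-data-record file with
  16-bit quantization — the standard interchange format for biosignals;
* a plain CSV dialect with a ``time`` column in seconds followed by one
  column per channel in microvolts.

Event tables are tab-separated files with columns ``onset_s``,
``duration_s`` and ``phase``; epochs are fixed-length sliding windows cut
strictly inside one event each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    EmptySelectionError,
    FormatError,
    PreconditionError,
    SamplingError,
)

logger = logging.getLogger(__name__)

#: The 14 electrode labels of the Emotiv EPOC+ montage (10–20 positions),
#: in the canonical acquisition order.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "AF3", "F3", "F7", "FC5", "T7", "P7", "O1",
    "AF4", "F4", "FC6", "F8", "T8", "P8", "O2",
)

#: Flight-phase labels recognised in event tables.
PHASES: tuple[str, ...] = ("cruise", "turn_left", "turn_right")

#: Default sampling rate in Hz (Emotiv EPOC+ native rate); configurable.
DEFAULT_FS: float = 128.0

#: Relative tolerance on CSV time-step uniformity.
CSV_TIME_JITTER_TOL: float = 0.01


@dataclass
class Recording:
    """A uniformly sampled multichannel EEG segment in microvolts.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, strictly positive.
    channels : sequence of str
        Ordered channel labels; must match ``data`` row count.
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts; all finite.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    fs: float
    channels: Sequence[str]
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        if self.fs <= 0:
            raise PreconditionError(f"sampling rate must be > 0, got {self.fs}")
        if self.data.ndim != 2:
            raise PreconditionError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channels):
            raise PreconditionError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise PreconditionError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(self.fs, list(self.channels), data, self.start_time)


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    phase: str


@dataclass
class EventTable:
    """Ordered, non-overlapping flight-phase annotations."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_onset = -np.inf
        for ev in self.events:
            if ev.onset_s < 0:
                raise PreconditionError(f"negative onset {ev.onset_s}")
            if ev.onset_s < prev_onset:
                raise PreconditionError("event onsets must be non-decreasing")
            if ev.duration_s <= 0:
                raise PreconditionError(f"non-positive duration {ev.duration_s}")
            if ev.onset_s < prev_end - 1e-9:
                raise PreconditionError(
                    f"event at {ev.onset_s}s overlaps the previous one"
                )
            if ev.phase not in PHASES:
                raise PreconditionError(
                    f"unknown phase {ev.phase!r}; expected one of {PHASES}"
                )
            prev_end = ev.onset_s + ev.duration_s
            prev_onset = ev.onset_s

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def phases(self) -> list[str]:
        return [ev.phase for ev in self.events]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        required = {"onset_s", "duration_s", "phase"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"event table must have columns {sorted(required)}, got {list(df.columns)}"
            )
        events = [
            Event(float(r.onset_s), float(r.duration_s), str(r.phase))
            for r in df.itertuples()
        ]
        return cls(events)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "onset_s": [ev.onset_s for ev in self.events],
                "duration_s": [ev.duration_s for ev in self.events],
                "phase": [ev.phase for ev in self.events],
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class EpochSet:
    """Fixed-length windows cut from a recording, one phase label each."""

    epochs: np.ndarray          # (n_epochs, n_channels, n_samples)
    labels: np.ndarray          # (n_epochs,) phase strings
    fs: float
    window_s: float
    channels: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epochs.ndim != 3:
            raise PreconditionError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.epochs.shape[0] != len(self.labels):
            raise PreconditionError("one label per epoch required")
        if self.epochs.shape[1] != len(self.channels):
            raise PreconditionError("epoch channel count must match labels")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def select(self, phase: str) -> np.ndarray:
        """Boolean mask of epochs carrying ``phase``."""
        return self.labels == phase

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.epochs[mask], self.labels[mask], self.fs, self.window_s,
            list(self.channels),
        )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv_recording(path: Path) -> Recording:
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise FormatError(
            "CSV recordings need a leading 'time' column plus one column per channel"
        )
    if len(df) < 2:
        raise FormatError("CSV recording must contain at least two samples")
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) / med > CSV_TIME_JITTER_TOL:
        raise SamplingError(
            f"non-uniform time step: jitter exceeds {CSV_TIME_JITTER_TOL:.0%} of the median"
        )
    channels = [str(c) for c in df.columns[1:]]
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    return Recording(fs=1.0 / med, channels=channels, data=data, start_time=float(t[0]))


def _write_csv_recording(rec: Recording, path: Path) -> None:
    t = rec.start_time + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(rec.data.T, columns=list(rec.channels))
    df.insert(0, "time", t)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Minimal EDF codec
#
# Standard EDF layout: a 256-byte fixed header, 256 bytes per signal of
# per-signal headers, then int16 little-endian data records.  We write the
# whole recording as a single data record whose duration is the full
# recording length, which every standard reader accepts and which avoids
# constraining fs to an integer number of samples per second.
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def _fmt_float(x: float, width: int = 8) -> str:
    for fmt in (f"{x:.{width - 2}g}", f"{x:.3f}", f"{x:.1f}", f"{x:.0f}"):
        if len(fmt) <= width:
            return fmt
    raise FormatError(f"cannot format {x} in {width} EDF header bytes")


def _write_edf(rec: Recording, path: Path) -> None:
    n_sig = rec.n_channels
    n_samp = rec.n_samples
    header_bytes = 256 + 256 * n_sig
    record_duration = n_samp / rec.fs

    hdr = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),                      # patient id (anonymous)
            _pad("Startdate X X X X", 80),            # recording id
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(header_bytes), 8),
            _pad("", 44),
            _pad("1", 8),                             # one data record
            _pad(_fmt_float(record_duration), 8),
            _pad(str(n_sig), 4),
        ]
    )

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def col(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    labels = [str(c) for c in rec.channels]
    hdr += col(labels, 16)
    hdr += col([""] * n_sig, 80)                      # transducer
    hdr += col(["uV"] * n_sig, 8)
    hdr += col([_fmt_float(v) for v in phys_min], 8)
    hdr += col([_fmt_float(v) for v in phys_max], 8)
    hdr += col([str(dig_min)] * n_sig, 8)
    hdr += col([str(dig_max)] * n_sig, 8)
    hdr += col([""] * n_sig, 80)                      # prefiltering
    hdr += col([str(n_samp)] * n_sig, 8)
    hdr += col([""] * n_sig, 32)

    # header-string phys min/max must be what the reader will parse, so
    # quantize against the *formatted* values to keep the round trip tight
    pmin = np.array([float(_fmt_float(v)) for v in phys_min])
    pmax = np.array([float(_fmt_float(v)) for v in phys_max])
    scale = (pmax - pmin) / (dig_max - dig_min)
    digital = np.rint((rec.data - pmin[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(digital.tobytes())                   # one record: signals consecutive


def _read_edf(path: Path) -> Recording:
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256 or not fixed[:8].strip().startswith(b"0"):
            raise FormatError(f"{path} is not an EDF file")
        try:
            n_records = int(fixed[236:244].decode().strip())
            record_duration = float(fixed[244:252].decode().strip())
            n_sig = int(fixed[252:256].decode().strip())
        except ValueError as exc:
            raise FormatError(f"malformed EDF header in {path}") from exc

        def sig_fields(width: int, conv=str):
            raw = fh.read(width * n_sig)
            return [
                conv(raw[i * width:(i + 1) * width].decode("ascii").strip())
                for i in range(n_sig)
            ]

        labels = sig_fields(16)
        sig_fields(80)                                # transducer
        sig_fields(8)                                 # physical dimension
        pmin = np.array(sig_fields(8, float))
        pmax = np.array(sig_fields(8, float))
        dmin = np.array(sig_fields(8, int))
        dmax = np.array(sig_fields(8, int))
        sig_fields(80)                                # prefiltering
        spr = np.array(sig_fields(8, int))            # samples per record
        sig_fields(32)

        chunks: list[list[np.ndarray]] = [[] for _ in range(n_sig)]
        for _ in range(max(n_records, 0)):
            for i in range(n_sig):
                raw = fh.read(2 * spr[i])
                if len(raw) < 2 * spr[i]:
                    raise FormatError(f"truncated EDF data record in {path}")
                chunks[i].append(np.frombuffer(raw, dtype="<i2").astype(float))

    if len(set(spr)) != 1:
        raise FormatError("mixed per-signal sampling rates are not supported")
    scale = (pmax - pmin) / (dmax - dmin)
    data = np.stack([np.concatenate(c) for c in chunks])
    data = (data - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return Recording(fs=float(spr[0] / record_duration), channels=labels, data=data)


# ---------------------------------------------------------------------------
# Public I/O surface
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("edf", "csv"):
            raise FormatError(f"unsupported format {fmt!r}; use 'edf' or 'csv'")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("edf", "csv"):
        return suffix
    raise FormatError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EEG recording from EDF or the CSV dialect.

    The sampling rate comes from the EDF header, or from the reciprocal of
    the median time step for CSV (steps must be uniform to within 1%).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_edf(path) if fmt == "edf" else _read_csv_recording(path)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording so that :func:`read_recording` round-trips it.

    EDF output is 16-bit quantized; CSV is lossless to float printing.
    """
    if rec.n_samples == 0:
        raise EmptyInputError("refusing to write a zero-length recording")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        _write_csv_recording(rec, path)


def extract_epochs(
    rec: Recording,
    events: EventTable,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
) -> EpochSet:
    """Cut phase-labelled sliding windows strictly inside each event.

    Windows are half-open ``[onset, onset + window)`` with hop
    ``window_s * (1 - overlap_frac)``; per event the number of epochs is
    ``floor((duration - window)/hop) + 1`` (0 if the event is shorter than
    the window, which is logged and skipped rather than raised).
    """
    if not 0 <= overlap_frac < 1:
        raise PreconditionError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    win = int(round(window_s * rec.fs))
    if win < 2:
        raise PreconditionError("window must cover at least 2 samples")
    hop = max(int(round(win * (1.0 - overlap_frac))), 1)

    slices: list[np.ndarray] = []
    labels: list[str] = []
    for ev in events:
        start = int(round((ev.onset_s - rec.start_time) * rec.fs))
        dur = int(round(ev.duration_s * rec.fs))
        if start < 0 or start + dur > rec.n_samples:
            raise PreconditionError(
                f"event at {ev.onset_s}s extends outside the recording"
            )
        if dur < win:
            logger.warning(
                "event %s at %.2fs (%.2fs) shorter than the %.2fs window; skipped",
                ev.phase, ev.onset_s, ev.duration_s, window_s,
            )
            continue
        n_ep = (dur - win) // hop + 1
        for k in range(n_ep):
            s0 = start + k * hop
            slices.append(rec.data[:, s0:s0 + win])
            labels.append(ev.phase)

    epochs = (
        np.stack(slices)
        if slices
        else np.empty((0, rec.n_channels, win))
    )
    return EpochSet(
        epochs=epochs,
        labels=np.array(labels, dtype=object),
        fs=rec.fs,
        window_s=window_s,
        channels=list(rec.channels),
    )
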