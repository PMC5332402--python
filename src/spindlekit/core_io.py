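"""Data model and file I/O: recordings, epochs, annotations, corrections, stats.

Conventions
-----------
Times are seconds from the start of the recording.  Intervals are half-open
``[onset, offset)``; sample ``k`` covers ``[k/fs, (k+1)/fs)``.  Amplitudes
are microvolts.

Annotation files are tab-separated text with a version header::

    # spindlekit-annotations v1
    scorer	event_type	onset_s	offset_s

with ``event_type`` one of ``spindle`` / ``kcomplex`` and times printed to
3 decimals.  Correction files use the same layout with an ``action`` column
(``add`` / ``remove``) instead of ``scorer``.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import dominant_frequency

__all__ = [
    "EVENT_TYPES",
    "Recording",
    "Epoch",
    "EventAnnotation",
    "CorrectionRecord",
    "EventStatsReport",
    "read_edf_channel",
    "write_edf",
    "segment_epochs",
    "read_annotations",
    "write_annotations",
    "read_corrections",
    "write_corrections",
    "apply_corrections",
    "compute_event_stats",
    "stats_report",
]

EVENT_TYPES = ("spindle", "kcomplex")

ANNOTATION_HEADER = "# spindlekit-annotations v1"
CORRECTION_HEADER = "# spindlekit-corrections v1"

#: Matching tolerance (s) for `remove` corrections, on both bounds.
CORRECTION_TOL_S = 0.1


@dataclass
class Recording:
    """Uniformly sampled single-channel EEG in µV."""

    samples: np.ndarray
    fs: float
    channel: str = "EEG"
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class Epoch:
    """One scoring page: a half-open sample span ``[first, last)``."""

    index: int
    first: int
    last: int
    duration: float = 20.0

    @property
    def sample_span(self) -> tuple[int, int]:
        return (self.first, self.last)


@dataclass(frozen=True)
class EventAnnotation:
    """A typed, scored time interval (seconds from recording start)."""

    event_type: str
    onset: float
    offset: float
    scorer: str = "unknown"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not (0 <= self.onset < self.offset):
            raise ValueError(
                f"invalid interval [{self.onset}, {self.offset}) for {self.event_type}"
            )


@dataclass(frozen=True)
class CorrectionRecord:
    """A manual correction: add a missed event or remove a false detection."""

    action: str
    event: EventAnnotation

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError(f"unknown correction action {self.action!r}")


@dataclass
class EventStatsReport:
    """Descriptive statistics of one event type over a recording."""

    event_type: str
    total_count: int
    density: float               # events per minute
    mean_duration: float         # s (spindles only; NaN otherwise)
    mean_frequency: float        # Hz (dominant frequency per event, averaged)
    mean_amplitude: float        # µV peak-to-peak within event bounds

    def to_dict(self) -> dict:
        def _clean(v):
            return None if isinstance(v, float) and math.isnan(v) else v
        return {
            "event_type": self.event_type,
            "total_count": self.total_count,
            "density_per_min": _clean(self.density),
            "mean_duration_s": _clean(self.mean_duration),
            "mean_frequency_hz": _clean(self.mean_frequency),
            "mean_amplitude_uv": _clean(self.mean_amplitude),
        }


# ---------------------------------------------------------------------------
# epoch segmentation

def segment_epochs(rec: Recording, epoch_s: float = 20.0) -> list[Epoch]:
    """Split a recording into maximal disjoint full epochs.

    The trailing partial epoch is discarded; a recording shorter than one
    epoch yields an empty list.
    """
    if epoch_s <= 0:
        raise ValueError("epoch duration must be > 0")
    n_per = int(round(epoch_s * rec.fs))
    n_epochs = len(rec.samples) // n_per
    return [Epoch(index=i, first=i * n_per, last=(i + 1) * n_per, duration=epoch_s)
            for i in range(n_epochs)]


# ---------------------------------------------------------------------------
# annotation / correction text files

def write_annotations(events: list[EventAnnotation], path: str | Path) -> None:
    """Write events as a version-headered TSV (times to 3 decimals)."""
    lines = [ANNOTATION_HEADER, "scorer\tevent_type\tonset_s\toffset_s"]
    for ev in sorted(events, key=lambda e: (e.onset, e.offset)):
        lines.append(f"{ev.scorer}\t{ev.event_type}\t{ev.onset:.3f}\t{ev.offset:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read an annotation TSV; malformed lines raise with their line number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    events = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.strip() != ANNOTATION_HEADER:
            raise ValueError(f"{path}: missing header {ANNOTATION_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("scorer\t", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            scorer, etype, onset_s, offset_s = parts
            try:
                onset, offset = float(onset_s), float(offset_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric time") from exc
            try:
                events.append(EventAnnotation(etype, onset, offset, scorer))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return events


def write_corrections(corrections: list[CorrectionRecord], path: str | Path) -> None:
    lines = [CORRECTION_HEADER, "action\tevent_type\tonset_s\toffset_s"]
    for c in corrections:
        ev = c.event
        lines.append(f"{c.action}\t{ev.event_type}\t{ev.onset:.3f}\t{ev.offset:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_corrections(path: str | Path) -> list[CorrectionRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.strip() != CORRECTION_HEADER:
            raise ValueError(f"{path}: missing header {CORRECTION_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("action\t", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            action, etype, onset_s, offset_s = parts
            try:
                ev = EventAnnotation(etype, float(onset_s), float(offset_s),
                                     scorer="correction")
                out.append(CorrectionRecord(action, ev))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def _matches(a: EventAnnotation, b: EventAnnotation, tol: float) -> bool:
    return (a.event_type == b.event_type
            and abs(a.onset - b.onset) <= tol
            and abs(a.offset - b.offset) <= tol)


def apply_corrections(auto_events: list[EventAnnotation],
                      corrections: list[CorrectionRecord],
                      tol: float = CORRECTION_TOL_S) -> list[EventAnnotation]:
    """Apply manual add/remove corrections to a detector's event list.

    ``remove`` must match an existing event within ``tol`` on both bounds
    (same event type); otherwise an orphan-correction error is raised.
    ``add`` events already present within tolerance are skipped, so
    re-applying a list of additions is a no-op.  Output is re-sorted by
    onset; the result is independent of correction order for
    non-conflicting corrections.
    """
    events = list(auto_events)
    orphans = []
    for c in corrections:
        if c.action == "remove":
            match = next((ev for ev in events if _matches(ev, c.event, tol)), None)
            if match is None:
                orphans.append(c)
            else:
                events.remove(match)
    if orphans:
        desc = "; ".join(
            f"remove {c.event.event_type} [{c.event.onset:.3f}, {c.event.offset:.3f})"
            for c in orphans)
        raise ValueError(f"orphan corrections with no matching event: {desc}")
    for c in corrections:
        if c.action == "add" and not any(_matches(ev, c.event, tol) for ev in events):
            events.append(c.event)
    return sorted(events, key=lambda e: (e.onset, e.offset, e.event_type))


# ---------------------------------------------------------------------------
# per-recording event statistics

def compute_event_stats(events: list[EventAnnotation], rec: Recording,
                        event_type: str) -> EventStatsReport:
    """Descriptive statistics for one event type over ``rec``.

    Density is events per minute of recording.  Mean frequency averages the
    dominant frequency of each event's raw-signal segment; mean amplitude
    averages the within-event peak-to-peak amplitude.  Mean duration is
    reported for spindles only (K-complex extents are peak-window
    conventions, not scored durations).  With zero events the means are NaN.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    evs = [e for e in events if e.event_type == event_type]
    for e in evs:
        if e.offset > rec.duration + 1e-9:
            raise ValueError(f"event [{e.onset}, {e.offset}) outside recording")
    minutes = rec.duration / 60.0
    if not evs:
        return EventStatsReport(event_type, 0, 0.0,
                                float("nan"), float("nan"), float("nan"))
    freqs, amps, durs = [], [], []
    for e in evs:
        a = int(np.floor(e.onset * rec.fs))
        b = max(int(np.ceil(e.offset * rec.fs)), a + 1)
        seg = rec.samples[a:min(b, len(rec.samples))]
        freqs.append(dominant_frequency(seg, rec.fs))
        amps.append(float(seg.max() - seg.min()))
        durs.append(e.offset - e.onset)
    mean_dur = float(np.mean(durs)) if event_type == "spindle" else float("nan")
    return EventStatsReport(
        event_type=event_type,
        total_count=len(evs),
        density=len(evs) / minutes,
        mean_duration=mean_dur,
        mean_frequency=float(np.nanmean(freqs)),
        mean_amplitude=float(np.mean(amps)),
    )


def stats_report(events: list[EventAnnotation], rec: Recording) -> dict:
    """JSON-ready stats keyed by event type."""
    return {et: compute_event_stats(events, rec, et).to_dict() for et in EVENT_TYPES}


# ---------------------------------------------------------------------------
# EDF I/O
#
# Reading goes through MNE.  Writing implements the 16-bit EDF layout
# directly (fixed-width ASCII header + little-endian int16 data records):
# one signal, 1-s data records, the trailing partial record zero-padded.

def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a single-channel recording as 16-bit EDF (µV physical units).

    Requires an integer sampling rate.  The quantization step is
    ``(phys_max - phys_min) / (dig_max - dig_min)`` with a symmetric
    physical range covering the data.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    x = rec.samples
    n_rec = int(np.ceil(len(x) / spr))

    dig_min, dig_max = -32767, 32767
    pmax = max(float(np.max(np.abs(x))), 1.0)
    # physical extrema are stored as 8-char ASCII; quantize against the
    # value that will actually be read back
    for _ in range(4):
        pstr = _ascii_num(pmax)
        if float(pstr) >= np.max(np.abs(x)):
            break
        pmax *= 1.001
    pmax = float(_ascii_num(pmax))
    pmin = -pmax
    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.clip(np.round((x - pmin) * scale) + dig_min,
                      dig_min, dig_max).astype("<i2")
    padded = np.zeros(n_rec * spr, dtype="<i2")
    padded[:len(digital)] = digital

    def f(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),                       # version
        f("X X X X", 80),                # patient id
        f("Startdate X X X X", 80),      # recording id
        f("01.01.01", 8), f("00.00.00", 8),
        f(str(256 + 256), 8),            # header bytes (1 signal)
        f("", 44),
        f(str(n_rec), 8),
        f("1", 8),                       # record duration (s)
        f("1", 4),                       # number of signals
        f(rec.channel, 16),
        f("", 80),                       # transducer
        f("uV", 8),
        f(_ascii_num(pmin), 8), f(_ascii_num(pmax), 8),
        f(str(dig_min), 8), f(str(dig_max), 8),
        f("", 80),                       # prefiltering
        f(str(spr), 8),
        f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(padded.tobytes())


def _ascii_num(v: float) -> str:
    """Format a float into at most 8 ASCII characters (EDF header field)."""
    for fmt in ("{:.6g}", "{:.5g}", "{:.4g}", "{:.3g}", "{:.2g}"):
        s = fmt.format(v)
        if len(s) <= 8:
            return s
    return "{:.1g}".format(v)


def read_edf_channel(path: str | Path, channel: str) -> Recording:
    """Read one EEG channel from an EDF file into µV.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` with
    the available labels when the channel is absent.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}"
        )
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    data = raw.get_data()[0] * 1e6  # V -> µV
    return Recording(samples=data, fs=float(raw.info["sfreq"]), channel=channel)
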