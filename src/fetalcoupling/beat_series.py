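"""Event-train data model: beat series, 1-min segments, spike-grid encoding.

A :class:`BeatSeries` is an ordered train of R-peak times (seconds from
record start) for one channel -- maternal or fetal -- of one subject.
Records are cut into non-overlapping 1-minute :class:`SegmentPair` windows,
which are the unit of labeling, coherence analysis and classification.
For the CNN each segment is encoded as a binary spike grid of shape
``(2, window_length * fs)`` with a 1 at every beat sample.

Conventions: all windows are half-open ``[start, start + length)``; sample
indices are 0-based; beat-time -> sample-index rounding is round-half-up.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "REFRACTORY_S",
    "BeatSeries",
    "SubjectMeta",
    "SegmentPair",
    "EncodedSegment",
    "read_rpeaks_csv",
    "write_rpeaks_csv",
    "read_physionet_annotations",
    "segment_minutes",
    "encode_segment",
    "write_segment_manifest",
]

#: Physiological refractory floor on RR intervals (seconds). Shorter
#: intervals cannot be genuine consecutive heartbeats and are rejected.
REFRACTORY_S = 0.2

CHANNELS = ("maternal", "fetal")


class FormatError(ValueError):
    """Malformed input file (missing columns, bad header...)."""


class ValidationError(ValueError):
    """Input violates a physiological or structural invariant."""


@dataclass(frozen=True)
class BeatSeries:
    """Ordered train of R-peak times for one channel of one subject.

    Parameters
    ----------
    subject_id : str
    channel : {"maternal", "fetal"}
    times : ndarray
        Strictly increasing beat times in seconds from record start.
    record_duration : float
        Record length in seconds; all times must lie in
        ``[0, record_duration]``.
    """

    subject_id: str
    channel: str
    times: np.ndarray
    record_duration: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValidationError("times must be a 1-D sequence")
        if t.size:
            if t[0] < 0 or t[-1] > self.record_duration:
                raise ValidationError(
                    f"{self.subject_id}/{self.channel}: beat times outside "
                    f"[0, {self.record_duration}]"
                )
            rr = np.diff(t)
            if t.size > 1 and not np.all(rr > 0):
                bad = float(t[1:][rr <= 0][0])
                raise ValidationError(
                    f"{self.subject_id}/{self.channel}: times not strictly increasing at {bad} s"
                )
            if t.size > 1 and np.any(rr < REFRACTORY_S):
                bad = float(t[1:][rr < REFRACTORY_S][0])
                raise ValidationError(
                    f"{self.subject_id}/{self.channel}: RR interval < {REFRACTORY_S} s "
                    f"at t = {bad} s"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    def restrict(self, start: float, stop: float) -> "BeatSeries":
        """Beats with ``start <= t < stop`` (absolute times kept)."""
        lo, hi = np.searchsorted(self.times, [start, stop], side="left")
        return replace(self, times=self.times[lo:hi])


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata; any field may be absent (None)."""

    gestational_age: float | None = None  # weeks
    maternal_age: float | None = None  # years
    bmi: float | None = None  # kg/m^2

    def __post_init__(self) -> None:
        ga = self.gestational_age
        if ga is not None and not (15.0 <= ga <= 45.0):
            raise ValidationError(f"gestational_age {ga} weeks outside sanity bound [15, 45]")


#: Minimum beat counts for a segment to be analyzable: phase-occurrence
#: counting needs at least one 3-maternal-beat window and one fetal beat pair.
MIN_MATERNAL_BEATS = 4
MIN_FETAL_BEATS = 2


@dataclass(frozen=True)
class SegmentPair:
    """One fixed-length window of aligned maternal + fetal beat trains."""

    maternal: BeatSeries
    fetal: BeatSeries
    window_start: float
    window_length: float = 60.0
    segment_index: int = 0
    meta: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self) -> None:
        end = self.window_start + self.window_length
        for s in (self.maternal, self.fetal):
            if len(s) and (s.times[0] < self.window_start or s.times[-1] >= end):
                raise ValidationError(
                    f"{s.subject_id}/{s.channel}: beats outside window "
                    f"[{self.window_start}, {end})"
                )

    @property
    def subject_id(self) -> str:
        return self.maternal.subject_id

    @property
    def usable(self) -> bool:
        return len(self.maternal) >= MIN_MATERNAL_BEATS and len(self.fetal) >= MIN_FETAL_BEATS


@dataclass(frozen=True)
class EncodedSegment:
    """Binary spike grid for one segment: row 0 maternal, row 1 fetal."""

    grid: np.ndarray  # shape (2, L), uint8
    fs: float  # Hz
    segment: SegmentPair | None = None

    @property
    def L(self) -> int:
        return int(self.grid.shape[1])


# ---------------------------------------------------------------------------
# readers / writers


def read_rpeaks_csv(path: str | os.PathLike | io.IOBase) -> list[BeatSeries]:
    """Read an R-peaks CSV (columns ``subject_id,channel,time_s``).

    Returns one :class:`BeatSeries` per (subject, channel), with times
    sorted and duplicates (equal to 1 ms) collapsed under a warning.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "channel", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"R-peaks CSV missing column(s): {sorted(missing)}")
    bad = set(df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise FormatError(f"unknown channel value(s): {sorted(bad)}")
    out: list[BeatSeries] = []
    n_dup = 0
    for (sid, chan), grp in df.groupby(["subject_id", "channel"], sort=True):
        t = np.sort(grp["time_s"].to_numpy(dtype=float))
        # collapse duplicates at 1 ms resolution
        keep = np.ones(t.size, dtype=bool)
        keep[1:] = np.diff(t) >= 1e-3
        n_dup += int(t.size - keep.sum())
        t = t[keep]
        duration = float(t[-1]) if t.size else 0.0
        out.append(BeatSeries(str(sid), str(chan), t, record_duration=duration))
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate beat time(s) (within 1 ms)", stacklevel=2)
    return out


def write_rpeaks_csv(series: list[BeatSeries], path: str | os.PathLike) -> None:
    """Write beat series to the R-peaks CSV format (3-decimal-ms times)."""
    rows = [
        {"subject_id": s.subject_id, "channel": s.channel, "time_s": f"{t:.3f}"}
        for s in series
        for t in s.times
    ]
    pd.DataFrame(rows, columns=["subject_id", "channel", "time_s"]).to_csv(path, index=False)


# --- minimal MIT-format annotation reader (PhysioNet dialect) --------------
#
# Beat annotations are stored as 2-byte little-endian pairs: the high 6 bits
# of the second byte are the annotation code, the remaining 10 bits the
# sample interval since the previous annotation.  Codes 1..49 are beats;
# 59 (SKIP) carries a 4-byte interval, 60-62 (NUM/SUB/CHN) carry attributes,
# 63 (AUX) is followed by `interval` auxiliary bytes padded to even length,
# and a zero pair terminates the stream.

_MIT_SKIP, _MIT_NUM, _MIT_SUB, _MIT_CHN, _MIT_AUX = 59, 60, 61, 62, 63


def _read_mit_annotation_samples(path: str) -> np.ndarray:
    data = open(path, "rb").read()
    samples: list[int] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        lo, hi = data[i], data[i + 1]
        i += 2
        code = hi >> 2
        interval = ((hi & 3) << 8) | lo
        if code == 0 and interval == 0:
            break
        if code == _MIT_SKIP:
            if i + 4 > len(data):
                raise IOError(f"{path}: truncated SKIP annotation")
            # 32-bit interval: high-order 16-bit word first, each little-endian
            t += int.from_bytes(
                bytes([data[i + 1], data[i], data[i + 3], data[i + 2]]), "big", signed=True
            )
            i += 4
        elif code in (_MIT_NUM, _MIT_SUB, _MIT_CHN):
            continue
        elif code == _MIT_AUX:
            i += interval + (interval & 1)
        else:
            t += interval
            if 1 <= code <= 49:  # beat annotation family
                samples.append(t)
    return np.asarray(samples, dtype=np.int64)


def _read_header_fs(hea_path: str) -> tuple[str, float, float | None]:
    """Parse record name, sampling frequency and duration from a .hea file."""
    with open(hea_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise IOError(f"{hea_path}: corrupt header line {line!r}")
            name = fields[0].split("/")[0]
            fs = 250.0
            n_samples = None
            if len(fields) >= 3:
                try:
                    fs = float(fields[2].split("/")[0])
                except ValueError as exc:
                    raise IOError(f"{hea_path}: unparsable sampling frequency") from exc
            if len(fields) >= 4:
                try:
                    n_samples = int(fields[3])
                except ValueError:
                    n_samples = None
            dur = n_samples / fs if n_samples else None
            return name, fs, dur
    raise IOError(f"{hea_path}: empty header")


def read_physionet_annotations(
    record_path: str | os.PathLike,
    fetal_suffix: str = "fqrs",
    maternal_suffix: str | None = "mqrs",
) -> dict[str, BeatSeries | None]:
    """Read PhysioNet-style beat annotations for one record.

    ``record_path`` is the record path without extension; the header
    ``<record>.hea`` supplies the sampling frequency by which annotation
    sample indices are divided to obtain seconds.  Returns a dict with keys
    ``"fetal"`` and ``"maternal"``; maternal is None (with a warning) when
    no maternal annotation file exists -- maternal R-peak detection itself
    is out of scope.
    """
    record_path = os.fspath(record_path)
    hea = record_path + ".hea"
    if not os.path.exists(hea):
        raise IOError(f"missing header file {hea}")
    _, fs, duration = _read_header_fs(hea)
    ann_path = record_path + "." + fetal_suffix
    if not os.path.exists(ann_path):
        raise IOError(f"missing annotation file {ann_path}")
    subject = os.path.basename(record_path)
    fetal_t = _read_mit_annotation_samples(ann_path) / fs
    dur = duration if duration is not None else (float(fetal_t[-1]) if fetal_t.size else 0.0)
    out: dict[str, BeatSeries | None] = {
        "fetal": BeatSeries(subject, "fetal", fetal_t, record_duration=max(dur, fetal_t[-1] if fetal_t.size else 0.0)),
        "maternal": None,
    }
    if maternal_suffix:
        m_path = record_path + "." + maternal_suffix
        if os.path.exists(m_path):
            m_t = _read_mit_annotation_samples(m_path) / fs
            d = max(dur, float(m_t[-1]) if m_t.size else 0.0)
            out["maternal"] = BeatSeries(subject, "maternal", m_t, record_duration=d)
        else:
            warnings.warn(
                f"{subject}: no maternal annotation file ({m_path}); returning fetal only",
                stacklevel=2,
            )
    return out


# ---------------------------------------------------------------------------
# segmentation and encoding


def segment_minutes(
    maternal: BeatSeries,
    fetal: BeatSeries,
    meta: SubjectMeta | None = None,
    window_length: float = 60.0,
) -> list[SegmentPair]:
    """Cut a record into non-overlapping fixed-length segment pairs.

    Windows start at 0 and advance by ``window_length``; a trailing partial
    window is discarded, and segments failing the analyzability thresholds
    (>= 4 maternal, >= 2 fetal beats) are excluded.
    """
    if maternal.subject_id != fetal.subject_id:
        raise ValidationError("maternal and fetal series must come from the same subject")
    meta = meta or SubjectMeta()
    duration = min(maternal.record_duration, fetal.record_duration)
    n_windows = int(duration // window_length)
    if n_windows == 0:
        warnings.warn(
            f"{maternal.subject_id}: record shorter than one {window_length}-s window",
            stacklevel=2,
        )
        return []
    out: list[SegmentPair] = []
    n_unusable = 0
    for i in range(n_windows):
        start = i * window_length
        seg = SegmentPair(
            maternal=maternal.restrict(start, start + window_length),
            fetal=fetal.restrict(start, start + window_length),
            window_start=start,
            window_length=window_length,
            segment_index=i,
            meta=meta,
        )
        if seg.usable:
            out.append(seg)
        else:
            n_unusable += 1
    if n_unusable:
        warnings.warn(
            f"{maternal.subject_id}: excluded {n_unusable} unusable segment(s)", stacklevel=2
        )
    return out


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half-to-even; the grid rule is round-half-up
    return np.floor(x + 0.5).astype(np.int64)


def encode_segment(seg: SegmentPair, fs: float = 1000.0) -> EncodedSegment:
    """Encode a segment as a binary spike grid of shape ``(2, L)``.

    ``L = window_length * fs`` (60,000 at the native 1 kHz).  Entry
    ``[row, i]`` is 1 exactly when a beat time maps to sample ``i`` via
    ``round_half_up((t - window_start) * fs)`` clamped to ``[0, L-1]``;
    colliding beats merge into a single 1.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if not seg.usable:
        raise ValidationError(f"{seg.subject_id} segment {seg.segment_index} is not analyzable")
    L = int(round(seg.window_length * fs))
    grid = np.zeros((2, L), dtype=np.uint8)
    for row, series in enumerate((seg.maternal, seg.fetal)):
        idx = _round_half_up((series.times - seg.window_start) * fs)
        np.clip(idx, 0, L - 1, out=idx)
        grid[row, idx] = 1
    return EncodedSegment(grid=grid, fs=fs, segment=seg)


def write_segment_manifest(segments: list[SegmentPair], path: str | os.PathLike) -> pd.DataFrame:
    """Write the segment manifest CSV and return it as a DataFrame."""
    rows = [
        {
            "subject_id": s.subject_id,
            "segment_index": s.segment_index,
            "window_start": s.window_start,
            "n_maternal": len(s.maternal),
            "n_fetal": len(s.fetal),
            "usable": s.usable,
        }
        for s in segments
    ]
    df = pd.DataFrame(
        rows, columns=["subject_id", "segment_index", "window_start", "n_maternal", "n_fetal", "usable"]
    )
    df.to_csv(path, index=False)
    return df
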