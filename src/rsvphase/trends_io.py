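"""Reading and writing hourly RSV segments in the Google Trends export dialect.

A segment is one week (168 hourly points) of relative search volume on its
own private 0–100 integer scale, indexed by consecutive UTC hours.  The
serialised form is a two-column CSV, header ``datetime,rsv``, timestamps
``YYYY-MM-DDTHH:00`` with no zone suffix (documented as UTC, matching an
export with time-zone offset 0).  Round-trips are bit-exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "HOURS_PER_SEGMENT",
    "SEGMENT_STRIDE_HOURS",
    "OVERLAP_HOURS",
    "RsvSegment",
    "SegmentFormatError",
    "read_segment",
    "write_segment",
    "segment_filename",
    "write_normalized",
    "read_normalized",
]

HOURS_PER_SEGMENT = 168  # 7 days
SEGMENT_STRIDE_HOURS = 120  # consecutive segments start 5 days apart
OVERLAP_HOURS = HOURS_PER_SEGMENT - SEGMENT_STRIDE_HOURS  # 48: two shared days

_TS_FORMAT = "%Y-%m-%dT%H:00"


class SegmentFormatError(ValueError):
    """A serialized segment violates the export dialect (structure or values)."""


def _as_utc_hour(ts) -> pd.Timestamp:
    t = pd.Timestamp(ts)
    t = t.tz_localize("UTC") if t.tzinfo is None else t.tz_convert("UTC")
    if t != t.floor("h"):
        raise ValueError(f"timestamp {t} is not on a whole hour")
    return t


@dataclass(frozen=True)
class RsvSegment:
    """One 7-day block of hourly integer RSV values on its own 0–100 scale.

    Invariants enforced on construction: exactly 168 values, all integers
    in [0, 100], and — because each window is scaled to its own maximum —
    at least one value equal to 100 unless the segment is all zero.
    """

    term: str
    start: pd.Timestamp
    values: np.ndarray = field(repr=False)
    geo: str = "IT"

    def __post_init__(self):
        object.__setattr__(self, "start", _as_utc_hour(self.start))
        vals = np.asarray(self.values)
        if vals.shape != (HOURS_PER_SEGMENT,):
            raise ValueError(
                f"segment must hold exactly {HOURS_PER_SEGMENT} hourly values, "
                f"got shape {vals.shape}"
            )
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.round(vals)):
                raise ValueError("RSV values must be integers")
            vals = vals.astype(np.int64)
        else:
            vals = vals.astype(np.int64)
        if vals.min() < 0 or vals.max() > 100:
            raise ValueError("RSV values must lie in [0, 100]")
        if vals.max() != 100 and vals.any():
            raise ValueError(
                "a non-zero segment must contain the value 100 (window maximum)"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=HOURS_PER_SEGMENT, freq="h", tz="UTC")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name=self.term)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RsvSegment):
            return NotImplemented
        return (
            self.term == other.term
            and self.geo == other.geo
            and self.start == other.start
            and np.array_equal(self.values, other.values)
        )


def _open(source: Union[str, Path, IO[str]], mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, newline=""), True
    return source, False


def read_segment(source: Union[str, Path, IO[str]], term: str = "", geo: str = "IT") -> RsvSegment:
    """Parse one segment from a ``datetime,rsv`` CSV stream or path.

    Validates the dialect strictly: a header line, exactly 168 rows,
    ISO-8601 hourly UTC timestamps with no gaps or duplicates, integer
    values in [0, 100].  The first offending timestamp or value is named
    in the error.
    """
    stream, close = _open(source, "r")
    try:
        header = stream.readline().strip()
        if header != "datetime,rsv":
            raise SegmentFormatError(
                f"expected header 'datetime,rsv', got {header!r}"
            )
        stamps: list[pd.Timestamp] = []
        values: list[int] = []
        for lineno, line in enumerate(stream, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                ts_str, val_str = line.split(",")
            except ValueError as exc:
                raise SegmentFormatError(f"line {lineno}: not 'timestamp,value'") from exc
            try:
                ts = pd.Timestamp(ts_str).tz_localize("UTC")
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise SegmentFormatError(f"line {lineno}: bad timestamp {ts_str!r}") from exc
            try:
                val = int(val_str)
                if str(val) != val_str.strip():
                    raise ValueError
            except ValueError as exc:
                raise SegmentFormatError(
                    f"line {lineno}: value {val_str!r} is not an integer"
                ) from exc
            if not 0 <= val <= 100:
                raise SegmentFormatError(
                    f"line {lineno}: value {val} outside [0, 100]"
                )
            if stamps:
                want = stamps[-1] + pd.Timedelta(hours=1)
                if ts != want:
                    kind = "duplicate or out-of-order" if ts <= stamps[-1] else "missing"
                    raise SegmentFormatError(
                        f"line {lineno}: {kind} hour — expected "
                        f"{want.strftime(_TS_FORMAT)}, found {ts.strftime(_TS_FORMAT)}"
                    )
            stamps.append(ts)
            values.append(val)
    finally:
        if close:
            stream.close()

    if len(values) != HOURS_PER_SEGMENT:
        raise SegmentFormatError(
            f"expected {HOURS_PER_SEGMENT} rows, got {len(values)}"
        )
    return RsvSegment(term=term, geo=geo, start=stamps[0], values=np.array(values))


def write_segment(segment: RsvSegment, sink: Union[str, Path, IO[str]]) -> None:
    """Serialize a segment; ``read_segment(write_segment(s)) == s`` bit-exactly."""
    stream, close = _open(sink, "w")
    try:
        stream.write("datetime,rsv\n")
        for ts, val in zip(segment.index, segment.values):
            stream.write(f"{ts.strftime(_TS_FORMAT)},{val}\n")
    finally:
        if close:
            stream.close()


def segment_to_text(segment: RsvSegment) -> str:
    buf = _io.StringIO()
    write_segment(segment, buf)
    return buf.getvalue()


def segment_filename(term: str, geo: str, start) -> str:
    """Canonical file name ``{term}_{geo}_{start-date}.csv`` (spaces dashed)."""
    slug = term.replace(" ", "-")
    return f"{slug}_{geo}_{_as_utc_hour(start):%Y-%m-%d}.csv"


def write_normalized(series, path: Union[str, Path], coefficients_path: Union[str, Path, None] = None) -> None:
    """Write a stitched series as ``datetime,rsv_normalized`` (full precision).

    If *coefficients_path* is given, a sidecar ``segment_start,coefficient``
    CSV records the per-segment normalization coefficients.
    """
    idx = pd.date_range(series.start, periods=len(series.values), freq="h", tz="UTC")
    with open(path, "w", newline="") as fh:
        fh.write("datetime,rsv_normalized\n")
        for ts, val in zip(idx, series.values):
            fh.write(f"{ts.strftime(_TS_FORMAT)},{val!r}\n")
    if coefficients_path is not None:
        starts = pd.date_range(
            series.start, periods=len(series.coefficients), freq=f"{SEGMENT_STRIDE_HOURS}h", tz="UTC"
        )
        with open(coefficients_path, "w", newline="") as fh:
            fh.write("segment_start,coefficient\n")
            for ts, c in zip(starts, series.coefficients):
                fh.write(f"{ts.strftime(_TS_FORMAT)},{c!r}\n")


def read_normalized(path: Union[str, Path]) -> pd.Series:
    """Read a ``datetime,rsv_normalized`` CSV back into a UTC-indexed Series."""
    df = pd.read_csv(path, parse_dates=["datetime"])
    idx = pd.DatetimeIndex(df["datetime"]).tz_localize("UTC")
    return pd.Series(df["rsv_normalized"].to_numpy(dtype=float), index=idx)
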