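"""Chain normalization of overlapping per-window-scaled RSV segments.

Each downloaded week of RSV is scaled to its own maximum, so consecutive
weeks are not on a common scale.  Because consecutive segments share two
calendar days (48 hourly points), the ratio of the shared days' totals
gives a normalization coefficient that re-expresses the incoming week on
the scale of the week before it; chaining these coefficients back to the
first week puts the whole period on one reference scale.

The coefficient is the ratio of the 48-hour *sums* (equivalently, means).
Pointwise ratios are avoided deliberately: night-time hours of low-volume
terms are frequently 0 or 1 RSV units, and a mean of pointwise ratios
explodes there.  On overlap days the earlier, already-normalized values
are retained; the incoming segment's overlap is used only to estimate the
coefficient, which keeps the output single-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .trends_io import HOURS_PER_SEGMENT, OVERLAP_HOURS, SEGMENT_STRIDE_HOURS, RsvSegment

__all__ = [
    "DegenerateOverlapError",
    "NormalizedSeries",
    "overlap_coefficient",
    "chain_normalize",
    "stitch_segments",
    "SegmentStitcher",
]


class DegenerateOverlapError(ValueError):
    """The incoming overlap sums to zero: no coefficient can be estimated."""


@dataclass(frozen=True)
class NormalizedSeries:
    """A continuous hourly series on the reference (first) segment's scale.

    ``coefficients[k]`` is the factor applied to segment ``k``; the
    reference segment has coefficient exactly 1.
    """

    term: str
    start: pd.Timestamp
    values: np.ndarray = field(repr=False)
    coefficients: tuple[float, ...] = (1.0,)
    geo: str = "IT"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        n_seg = len(self.coefficients)
        expected = HOURS_PER_SEGMENT + SEGMENT_STRIDE_HOURS * (n_seg - 1)
        if vals.shape != (expected,):
            raise ValueError(
                f"{n_seg} segments imply {expected} hourly values, got {vals.shape}"
            )
        if self.coefficients[0] != 1.0:
            raise ValueError("reference segment must have coefficient 1")
        if np.any(vals < 0):
            raise ValueError("normalized RSV values must be non-negative")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.values), freq="h", tz="UTC")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name=self.term)


def overlap_coefficient(reference_overlap, incoming_overlap) -> float:
    """Normalization coefficient from the two shared days of adjacent segments.

    Returns ``sum(reference_overlap) / sum(incoming_overlap)`` — the factor
    that expresses the incoming segment on the reference scale.  Both
    inputs must be the same 48 hours, aligned hour by hour.
    """
    ref = np.asarray(reference_overlap, dtype=float)
    inc = np.asarray(incoming_overlap, dtype=float)
    if ref.shape != (OVERLAP_HOURS,) or inc.shape != (OVERLAP_HOURS,):
        raise ValueError(f"overlaps must each hold {OVERLAP_HOURS} hourly values")
    if np.any(ref < 0) or np.any(inc < 0):
        raise ValueError("RSV overlaps cannot contain negative values")
    inc_sum = inc.sum()
    if inc_sum == 0:
        raise DegenerateOverlapError(
            "incoming overlap sums to 0; normalization coefficient undefined"
        )
    return float(ref.sum() / inc_sum)


def chain_normalize(arrays: Sequence[np.ndarray]) -> tuple[np.ndarray, list[float]]:
    """Core stitching on raw value arrays (floats allowed).

    Each array is one 168-hour segment; consecutive arrays describe
    instants 120 hours apart and share their last/first 48 hours.
    Returns the stitched values and the per-segment coefficients.
    """
    if not arrays:
        raise ValueError("need at least one segment")
    first = np.asarray(arrays[0], dtype=float)
    if first.shape != (HOURS_PER_SEGMENT,):
        raise ValueError(f"segments must hold {HOURS_PER_SEGMENT} values")
    out = first.copy()
    coeffs = [1.0]
    for k, arr in enumerate(arrays[1:], start=1):
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (HOURS_PER_SEGMENT,):
            raise ValueError(f"segments must hold {HOURS_PER_SEGMENT} values")
        try:
            c = overlap_coefficient(out[-OVERLAP_HOURS:], arr[:OVERLAP_HOURS])
        except DegenerateOverlapError as exc:
            raise DegenerateOverlapError(
                f"segments {k - 1} and {k}: {exc}"
            ) from None
        coeffs.append(c)
        out = np.concatenate([out, arr[OVERLAP_HOURS:] * c])
    return out, coeffs


class SegmentStitcher(TransformerMixin, BaseEstimator):
    """Transformer stitching overlapping RSV segments onto one scale.

    ``fit`` estimates the chain of normalization coefficients from the
    48-hour overlaps; ``transform`` applies them and assembles the
    continuous series.  Fitted attributes follow sklearn conventions.

    Attributes
    ----------
    coefficients_ : list of float
        Per-segment coefficients; ``coefficients_[0] == 1``.
    """

    def fit(self, X: Sequence[RsvSegment], y=None):
        segments = self._validate(X)
        _, self.coefficients_ = chain_normalize([s.values for s in segments])
        self.n_segments_ = len(segments)
        return self

    def transform(self, X: Sequence[RsvSegment]) -> NormalizedSeries:
        if not hasattr(self, "coefficients_"):
            raise RuntimeError("SegmentStitcher must be fitted before transform")
        segments = self._validate(X)
        if len(segments) != self.n_segments_:
            raise ValueError("transform expects the segments it was fitted on")
        values, _ = chain_normalize([s.values for s in segments])
        return NormalizedSeries(
            term=segments[0].term,
            geo=segments[0].geo,
            start=segments[0].start,
            values=values,
            coefficients=tuple(self.coefficients_),
        )

    @staticmethod
    def _validate(X: Sequence[RsvSegment]) -> list[RsvSegment]:
        segments = list(X)
        if not segments:
            raise ValueError("need at least one segment")
        term, geo = segments[0].term, segments[0].geo
        for k, (a, b) in enumerate(zip(segments, segments[1:]), start=1):
            if b.term != term or b.geo != geo:
                raise ValueError(
                    f"segment {k}: term/geo {b.term!r}/{b.geo!r} differs from "
                    f"reference {term!r}/{geo!r}"
                )
            gap = (b.start - a.start) / pd.Timedelta(hours=1)
            if gap != SEGMENT_STRIDE_HOURS:
                raise ValueError(
                    f"segments {k - 1} and {k}: starts {a.start} and {b.start} are "
                    f"{gap:g} h apart; expected {SEGMENT_STRIDE_HOURS} h "
                    f"({OVERLAP_HOURS} h overlap)"
                )
        return segments


def stitch_segments(segments: Sequence[RsvSegment]) -> NormalizedSeries:
    """Chain-normalize ordered overlapping segments onto the first one's scale."""
    return SegmentStitcher().fit(segments).transform(segments)
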