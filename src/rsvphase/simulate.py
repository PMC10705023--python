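"""Synthetic hourly RSV around a daylight-saving transition.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without touching the live search
service:

* a 24-h cosine search-intensity rhythm whose acrophase is anchored to
  the *local civil clock* (CET = UTC+1 / CEST = UTC+2, switching at the
  transition instant);
* a ``social_fraction`` in [0, 1]: the fraction of the 60-minute
  civil-clock shift that the rhythm adopts after the transition.  1 means
  the behaviour follows the clock on the wall (the UTC acrophase moves by
  the full hour); 0 means it is fully solar/endogenous (the UTC acrophase
  does not move).  Spring transitions advance the UTC acrophase, autumn
  ones delay it;
* a multiplicative weekend level factor (Saturday/Sunday in local civil
  time) and optional one-day event spikes;
* additive Gaussian noise on intensity, clamped at zero;
* the observation model: the series is cut into 7-day windows advancing
  by 5 days (two shared calendar days), each window multiplied by its own
  lognormal jitter factor — mimicking independent resampling per request —
  then scaled so its maximum is 100 and rounded to integers.

The exact per-day ground-truth UTC acrophase is returned with every
dataset so recovery tests can compare against truth.
"""

from __future__ import annotations

import calendar
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .trends_io import HOURS_PER_SEGMENT, SEGMENT_STRIDE_HOURS, RsvSegment

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "transition_instant",
    "generate_intensity",
    "segment_and_scale",
    "generate_rsv_dataset",
    "padded_days_after",
]

logger = logging.getLogger(__name__)

SEASONS = ("spring", "autumn")
_CET = 1  # UTC offset in hours, standard time
_CEST = 2  # UTC offset in hours, daylight saving time


def transition_instant(year: int, season: str) -> pd.Timestamp:
    """UTC instant of the DST transition in Italy for *year* and *season*.

    Clocks change at 01:00 UTC on the last Sunday of March (spring, to
    DST) or of October (autumn, back to standard time).
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    if not 2000 <= int(year) <= 2100:
        raise ValueError(f"year {year} outside the supported range 2000-2100")
    month = 3 if season == "spring" else 10
    last_day = calendar.monthrange(year, month)[1]
    d = pd.Timestamp(year=year, month=month, day=last_day)
    d -= pd.Timedelta(days=(d.dayofweek - 6) % 7)  # back to the last Sunday
    return (d + pd.Timedelta(hours=1)).tz_localize("UTC")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic search population.

    ``acrophase_local`` is the local civil clock time of the intensity
    peak *before* the transition; after it, the underlying UTC acrophase
    moves by exactly ``social_fraction`` * 60 min (spring: advance,
    autumn: delay).
    """

    season: str
    transition_year: int
    baseline: float = 100.0
    amplitude: float = 50.0
    acrophase_local: float = 3.0
    social_fraction: float = 1.0
    weekend_gain: float = 1.2
    noise_sd: float = 5.0
    segment_scale_jitter: float = 0.15
    event_spikes: tuple[tuple[str, float], ...] = ()
    days_before: int = 15
    days_after: int = 15
    seed: int = 0
    term: str = "synthetic"
    geo: str = "IT"

    def __post_init__(self):
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}; expected one of {SEASONS}")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.social_fraction <= 1.0:
            raise ValueError("social_fraction must lie in [0, 1]")
        if self.weekend_gain <= 0:
            raise ValueError("weekend_gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.segment_scale_jitter < 0:
            raise ValueError("segment_scale_jitter must be non-negative")
        if self.days_before <= 0 or self.days_after <= 0:
            raise ValueError("days_before and days_after must be positive")
        object.__setattr__(self, "event_spikes", tuple(
            (str(pd.Timestamp(d).date()), float(g)) for d, g in self.event_spikes
        ))

    @property
    def transition(self) -> pd.Timestamp:
        return transition_instant(self.transition_year, self.season)

    @property
    def shift_minutes(self) -> float:
        """Ground-truth UTC acrophase step at the transition, in minutes.

        Negative in spring (advance), positive in autumn (delay).
        """
        sign = -1.0 if self.season == "spring" else 1.0
        return sign * self.social_fraction * 60.0


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-day UTC acrophase of the simulated rhythm."""

    acrophase_utc: pd.Series = field(repr=False)  # index: UTC dates; values: hours [0,24)
    shift_minutes: float = 0.0
    transition: pd.Timestamp | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [d.date() for d in self.acrophase_utc.index],
                "acrophase_utc_hours": self.acrophase_utc.to_numpy(),
            }
        )


def _offsets(index: pd.DatetimeIndex, transition: pd.Timestamp, season: str) -> np.ndarray:
    """Civil UTC offset (hours) per timestamp: CET/CEST switching at the transition."""
    post = index >= transition
    if season == "spring":
        return np.where(post, _CEST, _CET)
    return np.where(post, _CET, _CEST)


def generate_intensity(config: SimulationConfig) -> tuple[pd.Series, GroundTruth]:
    """Simulate the underlying hourly search intensity, UTC-indexed.

    The span covers whole UTC days: from midnight ``days_before`` days
    before the transition date to midnight ``days_after`` days after it
    (the transition day itself counts as the first post day).  Returns
    the intensity series and the exact per-day UTC acrophase record.
    """
    transition = config.transition
    day0 = transition.normalize()
    start = day0 - pd.Timedelta(days=config.days_before)
    end = day0 + pd.Timedelta(days=config.days_after)
    index = pd.date_range(start, end, freq="h", tz="UTC", inclusive="left")

    offsets = _offsets(index, transition, config.season)
    offset_pre = _CET if config.season == "spring" else _CEST
    acro_pre_utc = config.acrophase_local - offset_pre
    acro_post_utc = acro_pre_utc + config.shift_minutes / 60.0

    post = np.asarray(index >= transition)
    acro_utc = np.where(post, acro_post_utc, acro_pre_utc)
    utc_hour = index.hour.to_numpy(dtype=float)
    rhythm = config.baseline + config.amplitude * np.cos(
        2.0 * np.pi * (utc_hour - acro_utc) / 24.0
    )

    local = index + pd.to_timedelta(offsets, unit="h")
    weekend = local.dayofweek >= 5  # Saturday, Sunday in local civil time
    gain = np.where(weekend, config.weekend_gain, 1.0)
    if config.event_spikes:
        local_dates = local.strftime("%Y-%m-%d").to_numpy()
        for date_str, g in config.event_spikes:
            gain = gain * np.where(local_dates == date_str, g, 1.0)

    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=len(index)) if config.noise_sd > 0 else 0.0
    intensity = np.maximum(0.0, rhythm * gain + noise)

    days = pd.date_range(start, end, freq="D", tz="UTC", inclusive="left")
    day_post = days >= day0  # transition day (01:00 UTC switch) counted as post
    truth = pd.Series(
        np.where(day_post, acro_post_utc % 24.0, acro_pre_utc % 24.0), index=days
    )
    return (
        pd.Series(intensity, index=index, name=config.term),
        GroundTruth(acrophase_utc=truth, shift_minutes=config.shift_minutes, transition=transition),
    )


def segment_and_scale(
    intensity: pd.Series,
    seed: int,
    segment_scale_jitter: float = 0.0,
    term: str = "synthetic",
    geo: str = "IT",
) -> list[RsvSegment]:
    """Cut an intensity series into per-window-scaled integer RSV segments.

    Consecutive 7-day windows advance by 5 days (48 shared hours).  Each
    window is multiplied by an independent lognormal factor (sigma =
    ``segment_scale_jitter``), scaled so its maximum is exactly 100,
    rounded to the nearest integer and clipped to [0, 100].  Trailing
    hours that do not fill a complete window are dropped with a warning.
    """
    n = len(intensity)
    if n < HOURS_PER_SEGMENT:
        raise ValueError(
            f"series must cover at least 7 days ({HOURS_PER_SEGMENT} hours); got {n}"
        )
    if (intensity.to_numpy() < 0).any():
        raise ValueError("intensity must be non-negative")
    n_segments = (n - HOURS_PER_SEGMENT) // SEGMENT_STRIDE_HOURS + 1
    tail = n - (HOURS_PER_SEGMENT + SEGMENT_STRIDE_HOURS * (n_segments - 1))
    if tail:
        warnings.warn(
            f"{tail} trailing hours do not fill a 7-day window and were dropped",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    values = intensity.to_numpy(dtype=float)
    segments = []
    for k in range(n_segments):
        lo = k * SEGMENT_STRIDE_HOURS
        window = values[lo : lo + HOURS_PER_SEGMENT]
        jitter = rng.lognormal(0.0, segment_scale_jitter) if segment_scale_jitter > 0 else 1.0
        window = window * jitter
        peak = window.max()
        scaled = np.zeros(HOURS_PER_SEGMENT) if peak == 0 else 100.0 * window / peak
        rsv = np.clip(np.rint(scaled), 0, 100).astype(np.int64)
        segments.append(
            RsvSegment(term=term, geo=geo, start=intensity.index[lo], values=rsv)
        )
    return segments


def padded_days_after(days_before: int, days_after: int) -> int:
    """Smallest ``days_after' >= days_after`` making the whole span segmentable.

    7-day windows at a 5-day stride tile spans of ``7 + 5k`` days; the
    simulated span is padded *after* the analysis window so the stitched
    series covers every post-transition day.
    """
    total = days_before + days_after
    pad = (-(total - 7)) % 5
    return days_after + pad


def generate_rsv_dataset(
    config: SimulationConfig,
) -> tuple[list[RsvSegment], GroundTruth, pd.Series]:
    """End-to-end synthetic dataset: segments, ground truth and raw intensity.

    The simulated span is extended past ``days_after`` to the next 7+5k-day
    alignment so that complete 7-day windows cover the full analysis
    window; the extra padding days follow the post-transition regime.
    Independent RNG streams (spawned from ``config.seed``) drive the
    intensity noise and the per-window scale jitter.
    """
    padded = replace(config, days_after=padded_days_after(config.days_before, config.days_after))
    noise_seed, jitter_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(2)
    )
    intensity, truth = generate_intensity(replace(padded, seed=noise_seed))
    segments = segment_and_scale(
        intensity,
        seed=jitter_seed,
        segment_scale_jitter=config.segment_scale_jitter,
        term=config.term,
        geo=config.geo,
    )
    return segments, truth, intensity
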