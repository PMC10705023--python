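"""Per-day cosinor rhythm fitting: acrophase, significance, Rhythmicity Index.

Each calendar UTC day (24 hourly points) is fitted with a single-harmonic
cosinor, the standard chronobiology model for fixed-period rhythm
quantification:

    y_t = M + A * cos(2*pi*(t - phi)/24) + e_t

solved by least squares through the linear parameterization
``y_t = M + b1*cos(w t) + b2*sin(w t)`` with ``A = sqrt(b1^2 + b2^2)`` and
``phi = atan2(b2, b1)/w (mod 24)``.  The zero-amplitude test is the usual
cosinor F test on (2, n-3) degrees of freedom.  Three rhythm-quality
outputs accompany the phase: the fit p-value, the Pearson correlation
between fitted and observed values, and the Rhythmicity Index
``RI = r * (2A)`` — the correlation multiplied by the fitted
peak-to-trough range of oscillation.

Because the acrophase is circular within the day, peaks near midnight are
estimated without bias even though they sit at the day boundary; no
sliding window is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .stitch import NormalizedSeries

__all__ = ["DailyFit", "CosinorRegressor", "fit_day", "fit_window", "filter_significant", "fits_to_frame"]

logger = logging.getLogger(__name__)

_AMPLITUDE_EPS = 1e-9  # below this (relative to level) the day is treated as flat


@dataclass(frozen=True)
class DailyFit:
    """Cosinor summary of one calendar day.

    ``acrophase`` is the UTC clock hour of the fitted peak in ``[0, 24)``;
    it is NaN for degenerate (flat) days, which carry ``p_value = 1`` so
    that the significance filter removes them.
    """

    date: pd.Timestamp
    mesor: float
    amplitude: float
    acrophase: float
    p_value: float
    pearson_r: float
    oscillation_range: float
    rhythmicity_index: float
    n_points: int


class CosinorRegressor(RegressorMixin, BaseEstimator):
    """Least-squares single-harmonic cosinor with a fixed period.

    Parameters
    ----------
    period : float, default 24.0
        Rhythm period in hours.  The period is fixed, not estimated.

    Attributes
    ----------
    mesor_ : float
        Fitted midline (rhythm-adjusted mean level).
    amplitude_ : float
        Fitted cosine amplitude (half peak-to-trough), >= 0.
    acrophase_ : float
        Clock time of the fitted peak in ``[0, period)`` on the same time
        axis as the input; NaN when the fitted amplitude is numerically 0.
    p_value_ : float
        F-test p-value for zero amplitude, on (2, n-3) degrees of freedom.
    pearson_r_ : float
        Pearson correlation between fitted and observed values (0 for
        degenerate flat fits, where it is undefined).
    oscillation_range_ : float
        Fitted peak-to-trough range, exactly ``2 * amplitude_``.
    rhythmicity_index_ : float
        ``pearson_r_ * oscillation_range_`` — rhythm-quality index.
    """

    def __init__(self, period: float = 24.0):
        self.period = period

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-D hour offsets (or a single column)")
        yv = np.asarray(y, dtype=float)
        if yv.shape != t.shape:
            raise ValueError("X and y must have the same length")
        n = t.size
        if n < 4:
            raise ValueError("cosinor needs at least 4 points (3 parameters)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(yv))):
            raise ValueError("inputs must be finite")

        w = 2.0 * np.pi / self.period
        design = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
        beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
        mesor, b1, b2 = (float(b) for b in beta)
        amplitude = float(np.hypot(b1, b2))
        fitted = design @ beta

        ss_res = float(np.sum((yv - fitted) ** 2))
        ss_mod = float(np.sum((fitted - yv.mean()) ** 2))

        self.n_points_ = int(n)
        self.mesor_ = mesor
        if amplitude <= _AMPLITUDE_EPS * max(1.0, abs(mesor)):
            # flat day: no rhythm, phase undefined
            self.amplitude_ = 0.0
            self.acrophase_ = float("nan")
            self.p_value_ = 1.0
            self.pearson_r_ = 0.0
        else:
            self.amplitude_ = amplitude
            acro = float((np.arctan2(b2, b1) / w) % self.period)
            self.acrophase_ = 0.0 if acro >= self.period else acro
            if ss_res == 0.0:
                self.p_value_ = 0.0
            else:
                f_stat = (ss_mod / 2.0) / (ss_res / (n - 3))
                self.p_value_ = float(stats.f.sf(f_stat, 2, n - 3))
            sy, sf = yv.std(), fitted.std()
            if sy == 0.0 or sf == 0.0:
                self.pearson_r_ = 0.0
            else:
                self.pearson_r_ = float(np.corrcoef(fitted, yv)[0, 1])
        self.oscillation_range_ = 2.0 * self.amplitude_
        self.rhythmicity_index_ = self.pearson_r_ * self.oscillation_range_
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        w = 2.0 * np.pi / self.period
        if np.isnan(self.acrophase_):
            return np.full(t.shape, self.mesor_)
        return self.mesor_ + self.amplitude_ * np.cos(w * (t - self.acrophase_))


def fit_day(day_values: Sequence[float], day_start=None) -> DailyFit:
    """Cosinor fit of exactly 24 hourly values for one calendar day.

    ``day_start`` anchors the phase axis: the returned acrophase is the
    UTC clock hour of the fitted peak.  When omitted, the first value is
    taken to be midnight.
    """
    yv = np.asarray(day_values, dtype=float)
    if yv.shape != (24,):
        raise ValueError(f"a day holds exactly 24 hourly values, got shape {yv.shape}")
    start = pd.Timestamp("2000-01-01", tz="UTC") if day_start is None else pd.Timestamp(day_start)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    reg = CosinorRegressor(period=24.0).fit(np.arange(24.0), yv)
    start_hour = start.hour + start.minute / 60.0
    acro = reg.acrophase_
    if not np.isnan(acro):
        acro = float((acro + start_hour) % 24.0)
    return DailyFit(
        date=start.normalize(),
        mesor=reg.mesor_,
        amplitude=reg.amplitude_,
        acrophase=acro,
        p_value=reg.p_value_,
        pearson_r=reg.pearson_r_,
        oscillation_range=reg.oscillation_range_,
        rhythmicity_index=reg.rhythmicity_index_,
        n_points=reg.n_points_,
    )


def fit_window(series: NormalizedSeries | pd.Series, window=None) -> list[DailyFit]:
    """Fit every complete calendar UTC day of *series* within *window*.

    *window* is an optional ``(start, end)`` pair of timestamps (end
    exclusive); days only partially covered by the series or the window
    are skipped with a logged notice.  Returns one :class:`DailyFit` per
    complete day, in chronological order.
    """
    s = series.to_series() if isinstance(series, NormalizedSeries) else series
    if window is not None:
        lo, hi = (pd.Timestamp(b) for b in window)
        lo = lo.tz_localize("UTC") if lo.tzinfo is None else lo.tz_convert("UTC")
        hi = hi.tz_localize("UTC") if hi.tzinfo is None else hi.tz_convert("UTC")
        if hi <= lo:
            raise ValueError("empty window")
        s = s[(s.index >= lo) & (s.index < hi)]
    if s.empty:
        raise ValueError("window does not intersect the series")
    fits: list[DailyFit] = []
    for day, group in s.groupby(s.index.normalize()):
        if len(group) != 24:
            logger.info("skipping incomplete day %s (%d of 24 hours)", day.date(), len(group))
            continue
        fits.append(fit_day(group.to_numpy(), day_start=day))
    return fits


def filter_significant(fits: Sequence[DailyFit], alpha: float = 0.05) -> list[DailyFit]:
    """Keep the days whose rhythm is significant (``p <= alpha``, phase defined).

    Days whose cosinor fit fails the significance cut are removed from
    the analysis; days exactly at the threshold are retained.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return [f for f in fits if f.p_value <= alpha and not np.isnan(f.acrophase)]


def fits_to_frame(fits: Sequence[DailyFit]) -> pd.DataFrame:
    """Tabulate daily fits with one row per day (CSV-ready)."""
    return pd.DataFrame(
        {
            "date": [f.date.date() for f in fits],
            "mesor": [f.mesor for f in fits],
            "amplitude": [f.amplitude for f in fits],
            "acrophase_h": [f.acrophase for f in fits],
            "p_value": [f.p_value for f in fits],
            "pearson_r": [f.pearson_r for f in fits],
            "oscillation_range": [f.oscillation_range for f in fits],
            "rhythmicity_index": [f.rhythmicity_index for f in fits],
        }
    )
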