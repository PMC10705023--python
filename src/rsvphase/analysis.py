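"""Pre/post-transition phase comparison and across-year trend tests.

Daily acrophases from the 15 days before and after the clock change are
averaged circularly per side; outliers are removed with the Tukey boxplot
rule (1.5 * IQR fences) applied to phases unwrapped about their circular
mean, so that clusters straddling midnight are not split; the signed
pre/post difference is reported in minutes (negative = advance, positive
= delay); and the two sides are compared with a classic equal-variance
two-sample t-test on the unwrapped phases.  An across-year analysis
reports both a one-way year-effect ANOVA and a least-squares linear trend
of phase on year in minutes per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .circular import circular_mean_phase, phase_difference, unwrap_phases
from .cosinor import DailyFit, filter_significant, fit_window
from .simulate import SimulationConfig, generate_rsv_dataset
from .stitch import NormalizedSeries, stitch_segments
from .trends_io import RsvSegment

__all__ = [
    "PhaseWindow",
    "TransitionComparison",
    "YearTrend",
    "boxplot_outlier_filter",
    "compare_windows",
    "year_trend",
    "DstPhaseShiftAnalyzer",
    "run_pipeline",
    "comparisons_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseWindow:
    """Retained daily acrophases on one side of a transition."""

    word: str
    season: str
    year: int | str  # calendar year or "combined"
    side: str  # "pre" or "post"
    phases: tuple[float, ...]
    n_removed_nonsig: int = 0
    n_removed_outlier: int = 0

    def __post_init__(self):
        if self.side not in ("pre", "post"):
            raise ValueError("side must be 'pre' or 'post'")
        if any(not 0.0 <= p < 24.0 for p in self.phases):
            raise ValueError("phases must lie in [0, 24)")
        if self.n_removed_nonsig < 0 or self.n_removed_outlier < 0:
            raise ValueError("removal counts must be non-negative")


@dataclass(frozen=True)
class TransitionComparison:
    """Mean phases before/after one transition and their signed difference."""

    word: str
    season: str
    year: int | str
    mean_phase_pre: float
    mean_phase_post: float
    delta_minutes: float
    p_value: float  # NaN when a side has < 2 phases
    n_pre: int = 0
    n_post: int = 0


@dataclass(frozen=True)
class YearTrend:
    """Across-year phase trend: year-effect ANOVA plus a linear drift fit."""

    anova_f: float
    anova_p: float
    slope_min_per_year: float
    slope_p: float
    degenerate: bool = False  # zero within/between variance


def boxplot_outlier_filter(phases: Sequence[float]) -> tuple[list[float], list[float]]:
    """Tukey boxplot outlier removal on circular phases.

    Phases are unwrapped about their circular mean, quartiles computed by
    linear interpolation, and points strictly outside
    ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` removed (points exactly on a fence
    are kept).  Returns ``(kept, removed)`` in original order, re-wrapped
    to [0, 24).  With fewer than 4 points quartiles are not meaningful;
    the filter is skipped with a logged notice and everything is kept.
    """
    ph = [float(p) % 24.0 for p in phases]
    if len(ph) < 4:
        logger.info("boxplot filter skipped: only %d phases (need >= 4)", len(ph))
        return ph, []
    unwrapped = unwrap_phases(ph, circular_mean_phase(ph))
    q1, q3 = np.percentile(unwrapped, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept, removed = [], []
    for p, u in zip(ph, unwrapped):
        (kept if lo <= u <= hi else removed).append(p)
    return kept, removed


def compare_windows(pre: PhaseWindow, post: PhaseWindow) -> TransitionComparison:
    """Compare the two sides of a transition.

    Circular means per side; signed difference via the circular
    minute-wrap; two-tailed unpaired equal-variance Student t-test on the
    phases unwrapped about the pooled circular mean.  With fewer than two
    phases on a side the t-test is undefined and ``p_value`` is NaN.
    """
    if (pre.word, pre.season, pre.year) != (post.word, post.season, post.year):
        raise ValueError("windows describe different word/season/year")
    if not pre.phases or not post.phases:
        raise ValueError("both windows must be non-empty")
    mean_pre = circular_mean_phase(pre.phases)
    mean_post = circular_mean_phase(post.phases)
    delta = phase_difference(mean_pre, mean_post)
    if len(pre.phases) < 2 or len(post.phases) < 2:
        p = float("nan")
    else:
        pooled = circular_mean_phase(list(pre.phases) + list(post.phases))
        a = unwrap_phases(pre.phases, pooled)
        b = unwrap_phases(post.phases, pooled)
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return TransitionComparison(
        word=pre.word,
        season=pre.season,
        year=pre.year,
        mean_phase_pre=mean_pre,
        mean_phase_post=mean_post,
        delta_minutes=delta,
        p_value=p,
        n_pre=len(pre.phases),
        n_post=len(post.phases),
    )


def year_trend(yearly: Mapping[int, Sequence[float]], side: str = "pre") -> YearTrend:
    """Across-year phase trend on one side of the transition.

    Two complementary views of "does the phase drift over the years":
    a one-way ANOVA with year as the factor, and a least-squares linear
    regression of unwrapped daily phase on calendar year, whose slope is
    reported in minutes per year with its t-test p-value.
    """
    if side not in ("pre", "post"):
        raise ValueError("side must be 'pre' or 'post'")
    years = sorted(yearly)
    if len(years) < 3:
        raise ValueError("year trend needs at least 3 years")
    groups_raw = [list(yearly[y]) for y in years]
    if any(len(g) < 2 for g in groups_raw):
        raise ValueError("each year needs at least 2 phases")
    pooled = circular_mean_phase([p for g in groups_raw for p in g])
    groups = [unwrap_phases(g, pooled) for g in groups_raw]
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return YearTrend(float("nan"), float("nan"), 0.0, float("nan"), degenerate=True)
    if all(np.var(g) == 0.0 for g in groups):
        # no within-year variance: ANOVA F undefined (infinite)
        anova_f, anova_p = float("inf"), 0.0
    else:
        res = stats.f_oneway(*groups)
        anova_f, anova_p = float(res.statistic), float(res.pvalue)
    x = np.concatenate([np.full(len(g), y, dtype=float) for g, y in zip(groups, years)])
    reg = stats.linregress(x, flat)
    return YearTrend(
        anova_f=anova_f,
        anova_p=anova_p,
        slope_min_per_year=float(reg.slope) * 60.0,
        slope_p=float(reg.pvalue),
    )


class DstPhaseShiftAnalyzer(BaseEstimator):
    """Estimate the pre/post-transition phase shift of one stitched series.

    Runs the per-day cosinor fits over the two analysis windows, applies
    the day-level significance filter and the circular boxplot outlier
    filter, and compares the sides.

    Parameters
    ----------
    window_days : int, default 15
        Days analysed on each side of the transition (the transition day
        is the first post day).
    alpha : float, default 0.05
        Day-level significance threshold; days with a cosinor fit
        p-value above it are discarded.
    outlier_filter : bool, default True
        Apply the 1.5*IQR circular boxplot filter to each side's phases.

    Attributes
    ----------
    pre_window_, post_window_ : PhaseWindow
        Retained phases per side with removal counts.
    comparison_ : TransitionComparison
        Mean phases, signed delta in minutes and t-test p-value.
    fits_pre_, fits_post_ : list of DailyFit
        All complete-day cosinor fits per side, before filtering.
    """

    def __init__(self, window_days: int = 15, alpha: float = 0.05, outlier_filter: bool = True):
        self.window_days = window_days
        self.alpha = alpha
        self.outlier_filter = outlier_filter

    def fit(self, X: NormalizedSeries | pd.Series, transition, *, word: str = "", season: str = "", year: int | str = 0):
        transition = pd.Timestamp(transition)
        if transition.tzinfo is None:
            transition = transition.tz_localize("UTC")
        day0 = transition.normalize()
        pre_lo = day0 - pd.Timedelta(days=self.window_days)
        post_hi = day0 + pd.Timedelta(days=self.window_days)
        self.fits_pre_ = fit_window(X, (pre_lo, day0))
        self.fits_post_ = fit_window(X, (day0, post_hi))
        self.pre_window_ = self._make_window(self.fits_pre_, word, season, year, "pre")
        self.post_window_ = self._make_window(self.fits_post_, word, season, year, "post")
        self.comparison_ = compare_windows(self.pre_window_, self.post_window_)
        return self

    def _make_window(self, fits: list[DailyFit], word, season, year, side) -> PhaseWindow:
        significant = filter_significant(fits, alpha=self.alpha)
        n_nonsig = len(fits) - len(significant)
        if n_nonsig:
            logger.info("%s/%s/%s %s: %d non-significant days removed", word, season, year, side, n_nonsig)
        phases = [f.acrophase for f in significant]
        if self.outlier_filter:
            kept, removed = boxplot_outlier_filter(phases)
        else:
            kept, removed = phases, []
        if removed:
            logger.info("%s/%s/%s %s: %d outlier days removed", word, season, year, side, len(removed))
        return PhaseWindow(
            word=word,
            season=season,
            year=year,
            side=side,
            phases=tuple(kept),
            n_removed_nonsig=n_nonsig,
            n_removed_outlier=len(removed),
        )


def _hhmm(hours: float) -> str:
    minutes = int(round((hours % 24.0) * 60.0)) % 1440
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def comparisons_to_frame(
    comparisons: Sequence[TransitionComparison], categories: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate comparisons in the study's summary-table shape."""
    categories = categories or {}
    return pd.DataFrame(
        {
            "word": [c.word for c in comparisons],
            "category": [categories.get(c.word, "") for c in comparisons],
            "season": [c.season for c in comparisons],
            "scope": [str(c.year) for c in comparisons],
            "phase_pre_hhmm": [_hhmm(c.mean_phase_pre) for c in comparisons],
            "phase_post_hhmm": [_hhmm(c.mean_phase_post) for c in comparisons],
            "delta_min": [c.delta_minutes for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "n_pre": [c.n_pre for c in comparisons],
            "n_post": [c.n_post for c in comparisons],
        }
    )


@dataclass(frozen=True)
class WordYearData:
    """Input bundle for one word at one transition: segments plus identity."""

    word: str
    season: str
    year: int
    segments: tuple[RsvSegment, ...]
    transition: pd.Timestamp


def run_pipeline(
    items: Sequence[WordYearData] | Sequence[SimulationConfig],
    window_days: int = 15,
    alpha: float = 0.05,
    outlier_filter: bool = True,
    categories: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full analysis: stitch, fit, filter and compare, per year and combined.

    *items* are either :class:`WordYearData` bundles of real segments or
    :class:`SimulationConfig` objects (simulated on the fly).  For every
    word x season, one comparison row is produced per year plus a
    "combined" row pooling all retained daily phases across years.
    Returns ``(table, log)``: the summary table and a per-window log of
    days dropped at each stage.
    """
    prepared: list[WordYearData] = []
    for item in items:
        if isinstance(item, SimulationConfig):
            segments, truth, _ = generate_rsv_dataset(item)
            prepared.append(
                WordYearData(
                    word=item.term,
                    season=item.season,
                    year=item.transition_year,
                    segments=tuple(segments),
                    transition=truth.transition,
                )
            )
        else:
            prepared.append(item)
    if not prepared:
        raise ValueError("no inputs")

    comparisons: list[TransitionComparison] = []
    log_rows: list[dict] = []
    pooled: dict[tuple[str, str], dict[str, list[float]]] = {}
    order: list[tuple[str, str]] = []
    for item in prepared:
        key = (item.word, item.season)
        if key not in pooled:
            pooled[key] = {"pre": [], "post": []}
            order.append(key)
        series = stitch_segments(list(item.segments))
        analyzer = DstPhaseShiftAnalyzer(
            window_days=window_days, alpha=alpha, outlier_filter=outlier_filter
        ).fit(series, item.transition, word=item.word, season=item.season, year=item.year)
        comparisons.append(analyzer.comparison_)
        for win in (analyzer.pre_window_, analyzer.post_window_):
            pooled[key][win.side].extend(win.phases)
            log_rows.append(
                {
                    "word": item.word,
                    "season": item.season,
                    "year": item.year,
                    "side": win.side,
                    "n_days": len(win.phases) + win.n_removed_nonsig + win.n_removed_outlier,
                    "n_removed_nonsig": win.n_removed_nonsig,
                    "n_removed_outlier": win.n_removed_outlier,
                    "n_retained": len(win.phases),
                }
            )

    for word, season in order:
        sides = {}
        for side in ("pre", "post"):
            sides[side] = PhaseWindow(
                word=word, season=season, year="combined", side=side,
                phases=tuple(pooled[(word, season)][side]),
            )
        comparisons.append(compare_windows(sides["pre"], sides["post"]))

    return comparisons_to_frame(comparisons, categories), pd.DataFrame(log_rows)
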