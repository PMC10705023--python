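"""Window comparison, outlier filtering, year trends and the full pipeline."""

import numpy as np
import pandas as pd
import pytest

from rsvphase import (
    PhaseWindow,
    SimulationConfig,
    boxplot_outlier_filter,
    compare_windows,
    run_pipeline,
    unwrap_phases,
    year_trend,
)
from rsvphase.analysis import comparisons_to_frame
from rsvphase.circular import circular_mean_phase

from _oracles import student_t_pvalue, tukey_fences


def window(phases, side="pre", **kw):
    base = dict(word="insomnia", season="spring", year=2018)
    base.update(kw)
    return PhaseWindow(side=side, phases=tuple(p % 24.0 for p in phases), **base)


class TestBoxplotOutlierFilter:
    def test_removes_single_far_point(self, rng):
        phases = list((2.0 + rng.uniform(-0.2, 0.2, 14)) % 24.0) + [9.0]
        kept, removed = boxplot_outlier_filter(phases)
        assert removed == [9.0]
        assert len(kept) == 14
        # brute-force fence oracle on the unwrapped values
        unwrapped = unwrap_phases(phases, circular_mean_phase(phases))
        lo, hi = tukey_fences(unwrapped)
        oracle_removed = [p for p, u in zip(phases, unwrapped) if not lo <= u <= hi]
        assert removed == oracle_removed

    def test_identical_phases_keep_everything(self):
        kept, removed = boxplot_outlier_filter([3.0] * 6)
        assert kept == [3.0] * 6 and removed == []

    def test_midnight_straddling_cluster_is_not_split(self, rng):
        cluster = list((rng.uniform(23.8, 24.2, 12)) % 24.0)
        phases = cluster + [12.5]
        kept, removed = boxplot_outlier_filter(phases)
        assert removed == [12.5]
        assert sorted(kept) == sorted(cluster)

    def test_fewer_than_four_points_skips_filter(self):
        kept, removed = boxplot_outlier_filter([1.0, 2.0, 20.0])
        assert kept == [1.0, 2.0, 20.0] and removed == []

    def test_preserves_original_order(self, rng):
        phases = list((5.0 + rng.normal(0, 0.1, 10)) % 24.0)
        kept, _ = boxplot_outlier_filter(phases)
        assert kept == phases


class TestCompareWindows:
    def test_identical_samples_give_zero_delta_unit_p(self, rng):
        phases = (2.0 + rng.normal(0, 0.2, 15)) % 24.0
        cmp = compare_windows(window(phases, "pre"), window(phases, "post"))
        assert cmp.delta_minutes == pytest.approx(0.0, abs=1e-9)
        assert cmp.p_value == pytest.approx(1.0)

    def test_hour_shift_detected_with_oracle_t_test(self, rng):
        pre = (2.0 + rng.normal(0, 0.1, 15)) % 24.0
        post = (1.0 + rng.normal(0, 0.1, 15)) % 24.0
        cmp = compare_windows(window(pre, "pre"), window(post, "post"))
        assert cmp.delta_minutes == pytest.approx(-60.0, abs=6.0)
        assert cmp.p_value < 1e-6
        pooled = circular_mean_phase(np.concatenate([pre, post]))
        oracle_p = student_t_pvalue(unwrap_phases(pre, pooled), unwrap_phases(post, pooled))
        assert cmp.p_value == pytest.approx(oracle_p, rel=1e-9)

    def test_midnight_straddling_windows(self):
        pre = [23.8, 23.9, 0.1, 0.2]
        post = [0.3, 0.4, 0.6, 0.7]
        cmp = compare_windows(window(pre, "pre"), window(post, "post"))
        assert cmp.delta_minutes == pytest.approx(30.0, abs=1e-6)

    def test_single_phase_side_yields_nan_p(self):
        cmp = compare_windows(window([2.0], "pre"), window([1.0, 1.1], "post"))
        assert np.isnan(cmp.p_value)
        assert cmp.delta_minutes < 0

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError, match="word/season/year"):
            compare_windows(window([2.0], "pre"), window([1.0], "post", year=2019))


class TestYearTrend:
    def test_recovers_built_in_drift(self, rng):
        yearly = {
            year: list((2.0 - 0.1 * (year - 2015) + rng.normal(0, 0.1, 15)) % 24.0)
            for year in range(2015, 2021)
        }
        trend = year_trend(yearly)
        assert trend.slope_min_per_year == pytest.approx(-6.0, abs=2.0)
        assert trend.slope_p < 0.01
        assert trend.anova_p < 0.01
        assert not trend.degenerate

    def test_constant_phase_is_degenerate(self):
        trend = year_trend({y: [4.0, 4.0] for y in (2015, 2016, 2017)})
        assert trend.degenerate
        assert trend.slope_min_per_year == 0.0

    def test_insufficient_years_rejected(self):
        with pytest.raises(ValueError, match="3 years"):
            year_trend({2015: [1.0, 2.0], 2016: [1.0, 2.0]})
        with pytest.raises(ValueError, match="2 phases"):
            year_trend({2015: [1.0, 2.0], 2016: [1.0, 2.0], 2017: [1.0]})


class TestRunPipeline:
    @staticmethod
    def configs(words, years, season="spring", **kw):
        return [
            SimulationConfig(
                season=season, transition_year=year, term=word,
                seed=1000 * i + j, **kw,
            )
            for i, word in enumerate(words)
            for j, year in enumerate(years)
        ]

    def test_output_shape_three_words(self):
        table, log = run_pipeline(self.configs(["a", "b", "c"], [2017, 2018]))
        assert len(table) == 3 * (2 + 1)  # per-year rows plus combined
        assert set(table.word) == {"a", "b", "c"}
        assert (table.groupby("word").scope.apply(set) == {"2017", "2018", "combined"}).all()
        assert table.delta_min.notna().all()
        # the run log records both sides of every word x year
        assert len(log) == 3 * 2 * 2
        assert (log.n_retained + log.n_removed_nonsig + log.n_removed_outlier == log.n_days).all()

    def test_sign_convention_spring_advance_autumn_delay(self):
        spring, _ = run_pipeline(self.configs(["w"], [2018], season="spring"))
        autumn, _ = run_pipeline(self.configs(["w"], [2018], season="autumn"))
        assert (spring.delta_min < 0).all()
        assert (autumn.delta_min > 0).all()

    def test_combined_row_pools_daily_phases(self):
        table, log = run_pipeline(self.configs(["w"], [2017, 2018], noise_sd=0.0))
        combined = table[table.scope == "combined"].iloc[0]
        yearly = table[table.scope != "combined"]
        assert combined.n_pre == yearly.n_pre.sum()
        assert combined.n_post == yearly.n_post.sum()

    def test_outlier_filter_removes_little_on_clean_data(self):
        _, log = run_pipeline(self.configs(["w"], [2016, 2017, 2018]))
        assert (log.n_removed_outlier <= 0.25 * log.n_days).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline([])


def test_hhmm_formatting():
    frame = comparisons_to_frame([])
    assert list(frame.columns[:4]) == ["word", "category", "season", "scope"]
    from rsvphase.analysis import _hhmm

    assert _hhmm(0.0) == "00:00"
    assert _hhmm(23.9999) == "00:00"  # rounds up across midnight
    assert _hhmm(2.3) == "02:18"
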