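"""Chain normalization of per-window-scaled segments back onto one scale."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsvphase import SimulationConfig, overlap_coefficient, stitch_segments
from rsvphase.simulate import generate_intensity, segment_and_scale
from rsvphase.stitch import DegenerateOverlapError, SegmentStitcher, chain_normalize
from rsvphase.trends_io import HOURS_PER_SEGMENT, OVERLAP_HOURS, SEGMENT_STRIDE_HOURS

from _oracles import least_squares_ratio
from conftest import make_segment


def split_into_raw_segments(values, factors):
    """Cut a continuous series into overlapping 168-h windows, each rescaled."""
    n_seg = (len(values) - HOURS_PER_SEGMENT) // SEGMENT_STRIDE_HOURS + 1
    return [
        values[k * SEGMENT_STRIDE_HOURS : k * SEGMENT_STRIDE_HOURS + HOURS_PER_SEGMENT] * f
        for k, f in zip(range(n_seg), factors)
    ]


def test_identical_overlaps_give_unit_coefficient(rng):
    ov = rng.uniform(1.0, 50.0, OVERLAP_HOURS)
    assert overlap_coefficient(ov, ov) == pytest.approx(1.0)


def test_halved_overlap_gives_coefficient_two(rng):
    ov = rng.uniform(1.0, 50.0, OVERLAP_HOURS)
    assert overlap_coefficient(ov, ov * 0.5) == pytest.approx(2.0)


def test_sum_ratio_matches_least_squares_oracle_on_rescaled_overlaps(rng):
    """An independently max-scaled copy of the same 48 hours: the sum-ratio
    coefficient and the explicit least-squares ratio agree within 2%."""
    base = 100.0 + 50.0 * np.cos(2 * np.pi * (np.arange(OVERLAP_HOURS) - 2.0) / 24.0)
    for jitter in (0.6, 1.0, 1.7):
        incoming = base * jitter
        incoming = 100.0 * incoming / incoming.max()
        c = overlap_coefficient(base, incoming)
        c_star = least_squares_ratio(base, incoming)
        assert c == pytest.approx(c_star, rel=0.02)
        # and both recover proportionality: c * incoming ~ base
        assert np.allclose(c * incoming, base, rtol=1e-9)


def test_degenerate_and_invalid_overlaps():
    ones = np.ones(OVERLAP_HOURS)
    with pytest.raises(DegenerateOverlapError):
        overlap_coefficient(ones, np.zeros(OVERLAP_HOURS))
    with pytest.raises(ValueError, match="negative"):
        overlap_coefficient(ones, -ones)
    with pytest.raises(ValueError, match="48"):
        overlap_coefficient(ones[:10], ones[:10])


def test_single_segment_is_identity():
    seg = make_segment(np.linspace(0, 100, HOURS_PER_SEGMENT).round().astype(int))
    out = stitch_segments([seg])
    assert np.array_equal(out.values, seg.values.astype(float))
    assert out.coefficients == (1.0,)


def test_two_rescaled_cuts_stitch_back_exactly(rng):
    truth = rng.uniform(5.0, 80.0, 12 * 24)
    raw = split_into_raw_segments(truth, [0.37, 11.3])
    stitched, coeffs = chain_normalize(raw)
    # proportional to the original: the reference factor is absorbed globally
    assert coeffs[0] == 1.0
    rel_err = np.abs(stitched / (truth * 0.37) - 1.0)
    assert rel_err.max() < 1e-12


def test_jitter_free_synthetic_with_rounding_recovers_intensity():
    """32-day noiseless world (6 windows), integer rounding only: the stitched
    series matches the intensity up to one global least-squares factor."""
    cfg = SimulationConfig(
        season="spring", transition_year=2018, noise_sd=0.0,
        segment_scale_jitter=0.0, days_after=17, seed=11,
    )
    intensity, _ = generate_intensity(cfg)
    segments = segment_and_scale(intensity, seed=12, segment_scale_jitter=0.0)
    assert len(segments) == 6
    out = stitch_segments(segments)
    truth = intensity.loc[out.index].to_numpy()
    scale = least_squares_ratio(out.values, truth)
    assert np.max(np.abs(out.values / (scale * truth) - 1.0)) <= 0.02


@settings(max_examples=25)
@given(
    factors=st.lists(st.floats(0.05, 20.0), min_size=2, max_size=5),
    seed=st.integers(0, 10_000),
)
def test_exact_stitching_without_rounding(factors, seed):
    rng = np.random.default_rng(seed)
    n = HOURS_PER_SEGMENT + SEGMENT_STRIDE_HOURS * (len(factors) - 1)
    truth = rng.uniform(1.0, 100.0, n)
    stitched, coeffs = chain_normalize(split_into_raw_segments(truth, factors))
    assert np.allclose(stitched, truth * factors[0], rtol=1e-9)
    # estimated coefficients undo the relative factors
    for k, c in enumerate(coeffs[1:], start=1):
        assert c == pytest.approx(factors[0] / factors[k], rel=1e-9)


@settings(max_examples=25)
@given(scale=st.floats(0.1, 10.0), which=st.integers(1, 2), seed=st.integers(0, 10_000))
def test_scale_invariance_of_non_reference_segments(scale, which, seed):
    rng = np.random.default_rng(seed)
    truth = rng.uniform(1.0, 100.0, HOURS_PER_SEGMENT + 2 * SEGMENT_STRIDE_HOURS)
    raw = split_into_raw_segments(truth, [1.0, 2.0, 0.5])
    base_values, base_coeffs = chain_normalize(raw)
    raw[which] = raw[which] * scale
    new_values, new_coeffs = chain_normalize(raw)
    assert np.allclose(new_values, base_values, rtol=1e-9)
    assert new_coeffs[which] == pytest.approx(base_coeffs[which] / scale, rel=1e-9)


@settings(max_examples=25)
@given(seed=st.integers(0, 10_000), n_seg=st.integers(2, 5))
def test_chain_consistency(seed, n_seg):
    """Stitching 1..n then appending n+1 equals stitching 1..n+1 in one pass."""
    rng = np.random.default_rng(seed)
    n = HOURS_PER_SEGMENT + SEGMENT_STRIDE_HOURS * (n_seg - 1)
    raw = split_into_raw_segments(rng.uniform(1.0, 100.0, n), rng.uniform(0.2, 5.0, n_seg))
    full_values, full_coeffs = chain_normalize(raw)
    head_values, head_coeffs = chain_normalize(raw[:-1])
    assert np.allclose(full_values[: len(head_values)], head_values, rtol=1e-12)
    assert np.allclose(full_coeffs[:-1], head_coeffs, rtol=1e-12)


def test_structural_errors():
    a = make_segment([100] * HOURS_PER_SEGMENT, start="2018-03-10 00:00")
    misaligned = make_segment([100] * HOURS_PER_SEGMENT, start="2018-03-16 00:00")
    with pytest.raises(ValueError, match="overlap"):
        stitch_segments([a, misaligned])
    other_term = make_segment(
        [100] * HOURS_PER_SEGMENT, start="2018-03-15 00:00", term="taxi"
    )
    with pytest.raises(ValueError, match="term"):
        stitch_segments([a, other_term])
    zeros = make_segment([0] * HOURS_PER_SEGMENT, start="2018-03-20 00:00")
    b = make_segment([100] * HOURS_PER_SEGMENT, start="2018-03-15 00:00")
    with pytest.raises(DegenerateOverlapError, match="segments 1 and 2"):
        stitch_segments([a, b, zeros])


def test_stitcher_is_a_fitted_transformer():
    seg = make_segment(np.linspace(0, 100, HOURS_PER_SEGMENT).round().astype(int))
    st_ = SegmentStitcher()
    with pytest.raises(RuntimeError):
        st_.transform([seg])
    out = st_.fit([seg]).transform([seg])
    assert st_.coefficients_ == [1.0]
    assert out.term == seg.term
    assert st_.get_params() == {}
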