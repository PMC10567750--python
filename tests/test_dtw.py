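"""DTW distance against exhaustive path enumeration; reference building."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlhub import (
    CHANNELS,
    InfeasibleBandError,
    SensorChannel,
    build_reference,
    classify,
    dtw_distance,
    slice_series,
    znorm,
)

from conftest import make_series

T = SensorChannel.TEMPERATURE


def brute_force_dtw(a, b):
    """Minimal |a_i - b_j| path cost by exhaustive monotone-path enumeration."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDtwDistance:
    def test_identical_sequences_distance_zero(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert dtw_distance(a, a) == 0.0

    def test_two_by_two_hand_enumeration(self):
        assert dtw_distance([0.0, 0.0], [1.0, 1.0]) == 2.0

    def test_two_by_three_hand_dp_table(self):
        assert dtw_distance([1.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    def test_band_narrower_than_length_difference_is_infeasible(self):
        with pytest.raises(InfeasibleBandError):
            dtw_distance([1.0, 2.0, 3.0, 4.0, 5.0], [1.0], band=1)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_brute_force_on_short_sequences(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        a = rng.uniform(-5, 5, n)
        b = rng.uniform(-5, 5, m)
        assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(a, b), rel=1e-12, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_self_distance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-3, 3, int(rng.integers(2, 30)))
        b = rng.uniform(-3, 3, int(rng.integers(2, 30)))
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a), rel=1e-12)
        assert dtw_distance(a, a) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_band_restriction_never_beats_unbanded_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        m = int(rng.integers(3, 25))
        a = rng.uniform(-3, 3, n)
        b = rng.uniform(-3, 3, m)
        band = int(rng.integers(abs(n - m), max(n, m) + 1))
        assert dtw_distance(a, b, band=band) >= dtw_distance(a, b) - 1e-12

    def test_wide_band_recovers_unbanded_distance(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 1, 12), rng.uniform(0, 1, 17)
        assert dtw_distance(a, b, band=20) == pytest.approx(dtw_distance(a, b), rel=1e-12)


def single_channel_segment(t, v):
    series = make_series(np.asarray(t, dtype=float), lambda k, tt: np.asarray(v, dtype=float))
    return slice_series(series, float(t[0]), float(t[-1]) + 1.0)


class TestBuildReference:
    def test_mean_of_one_is_the_resampled_instance(self):
        seg = single_channel_segment([0, 1, 2, 3, 4], [0.0, 1.0, 4.0, 9.0, 16.0])
        ref = build_reference([seg], grid_len=5, adl="x")
        np.testing.assert_allclose(ref.channels[T], [0, 1, 4, 9, 16])
        assert ref.source_count == 1

    def test_pointwise_mean_of_two_constant_instances(self):
        a = single_channel_segment([0, 1, 2], [0.0, 0.0, 0.0])
        b = single_channel_segment([0, 1, 2], [2.0, 2.0, 2.0])
        ref = build_reference([a, b], grid_len=4)
        np.testing.assert_allclose(ref.channels[T], np.ones(4))

    def test_hand_computed_linear_interpolation(self):
        """Lengths 5 and 9 (values t^2) resampled to grid 4 and averaged.

        Instance A grid points 0, 4/3, 8/3, 4 -> 0, 2, 22/3, 16;
        instance B grid points 0, 8/3, 16/3, 8 -> 0, 22/3, 86/3, 64;
        pointwise mean: 0, 14/3, 18, 40.
        """
        a = single_channel_segment(np.arange(5), np.arange(5.0) ** 2)
        b = single_channel_segment(np.arange(9), np.arange(9.0) ** 2)
        ref = build_reference([a, b], grid_len=4)
        np.testing.assert_allclose(ref.channels[T], [0.0, 14.0 / 3.0, 18.0, 40.0], rtol=1e-12)

    def test_empty_instance_list_rejected(self):
        with pytest.raises(ValueError):
            build_reference([], grid_len=4)


class TestClassify:
    def test_segment_equal_to_a_reference_wins_with_zero_distance(self):
        rng = np.random.default_rng(2)
        seg = single_channel_segment(np.arange(20), rng.uniform(0, 1, 20))
        other = single_channel_segment(np.arange(20), rng.uniform(5, 6, 20))
        refs = [build_reference([seg], 10, adl="same"),
                build_reference([other], 10, adl="other")]
        winner, totals = classify(seg, refs, grid_len=10)
        assert winner == "same"
        assert totals["same"] == pytest.approx(0.0, abs=1e-9)

    def test_ramp_segment_prefers_ramp_reference(self):
        flat = single_channel_segment(np.arange(30), np.full(30, 2.0))
        ramp = single_channel_segment(np.arange(30), np.linspace(0, 5, 30))
        probe = single_channel_segment(np.arange(25), np.linspace(1, 4, 25))
        refs = [build_reference([flat], 12, adl="flat"),
                build_reference([ramp], 12, adl="ramp")]
        winner, totals = classify(probe, refs, grid_len=12)
        assert winner == "ramp"
        assert totals["ramp"] < totals["flat"]

    def test_znorm_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(znorm(np.full(6, 3.0)), np.zeros(6))

    def test_no_references_rejected(self):
        seg = single_channel_segment(np.arange(5), np.arange(5.0))
        with pytest.raises(ValueError):
            classify(seg, [])
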