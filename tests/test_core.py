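"""Unit and property tests for the greedy splitting engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stepfinder import (
    Trace,
    best_split,
    best_split_sad,
    fit_from_breakpoints,
    iterative_fit,
    segment_stats,
)
from stepfinder.core import InvalidRangeError, ParameterError, split_scan_operations

from .conftest import (
    brute_force_best_split,
    brute_force_best_split_sad,
    brute_force_sse,
)

finite_signals = arrays(
    np.float64,
    st.integers(2, 64),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
)


class TestTrace:
    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            Trace(np.array([1.0]))
        with pytest.raises(ParameterError):
            Trace(np.array([1.0, np.nan, 2.0]))
        with pytest.raises(ParameterError):
            Trace(np.array([1.0, 2.0]), time=np.array([1.0, 0.5]))

    def test_time_base(self):
        tr = Trace(np.array([1.0, 2.0, 3.0]))
        assert tr.dt == 1.0
        assert np.array_equal(tr.sample_times(), [0, 1, 2])
        tr = Trace(np.array([1.0, 2.0, 3.0]), time=np.array([0.0, 0.1, 0.2]))
        assert tr.dt == pytest.approx(0.1)


class TestSegmentStats:
    def test_two_level_segment(self, two_level_trace):
        seg = segment_stats(two_level_trace, 0, 4)
        assert seg.mean_level == 2.0
        assert seg.sse == pytest.approx(16.0)

    def test_single_point_has_zero_sse(self):
        tr = Trace(np.array([5.0, 7.0]))
        seg = segment_stats(tr, 0, 1)
        assert seg.sse == 0.0
        assert seg.mean_level == 5.0

    def test_invalid_ranges(self, two_level_trace):
        for start, end in [(2, 2), (3, 1), (-1, 2), (0, 5)]:
            with pytest.raises(InvalidRangeError):
                segment_stats(two_level_trace, start, end)

    def test_matches_two_pass_computation(self, rng):
        x = rng.normal(size=20)
        tr = Trace(x)
        for _ in range(50):
            a, b = sorted(rng.choice(21, size=2, replace=False))
            seg = segment_stats(tr, a, b)
            expected = brute_force_sse(x[a:b])
            assert seg.sse == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestBestSplit:
    def test_perfect_two_level_signal(self):
        tr = Trace(np.array([0.0, 0.0, 1.0, 1.0]))
        res = best_split(tr, segment_stats(tr, 0, 4))
        assert res.split_index == 2
        assert res.gain == pytest.approx(1.0)

    def test_constant_signal_ties_to_lowest_index(self):
        tr = Trace(np.array([5.0] * 4))
        res = best_split(tr, segment_stats(tr, 0, 4))
        assert res.gain == pytest.approx(0.0)
        assert res.split_index == 1

    def test_unsplittable_segment(self, two_level_trace):
        assert best_split(two_level_trace, segment_stats(two_level_trace, 0, 1)) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(finite_signals)
    def test_matches_exhaustive_search(self, x):
        """Oracle equivalence against O(n^2) recomputation of every split."""
        tr = Trace(x)
        seg = segment_stats(tr, 0, len(x))
        res = best_split(tr, seg)
        idx, gain = brute_force_best_split(x)
        assert res.gain == pytest.approx(gain, rel=1e-9, abs=1e-6)
        # assert the position only when the optimum is unambiguous
        others = [
            brute_force_sse(x[:i]) + brute_force_sse(x[i:])
            for i in range(1, len(x))
            if i != idx
        ]
        margin = min(others) - (seg.sse - gain) if others else np.inf
        if gain > 1e-6 and margin > 1e-6:
            assert res.split_index == idx

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(finite_signals)
    def test_gain_identity(self, x):
        """gain = delta^2/(1/N_L + 1/N_R) and equals the SSE reduction."""
        tr = Trace(x)
        seg = segment_stats(tr, 0, len(x))
        res = best_split(tr, seg)
        delta = res.right_mean - res.left_mean
        formula = delta**2 / (1.0 / res.left_length + 1.0 / res.right_length)
        assert res.gain == pytest.approx(formula, rel=1e-9, abs=1e-9)
        i = res.split_index
        sse_split = brute_force_sse(x[:i]) + brute_force_sse(x[i:])
        assert res.gain == pytest.approx(seg.sse - sse_split, rel=1e-9, abs=1e-6)


class TestBestSplitSad:
    def test_perfect_two_level_signal(self):
        # total absolute deviation of [0,0,1,1] about its median is 2.0
        # (|x - m| sums to 2 for any m in [0, 1]); the split removes all of it
        tr = Trace(np.array([0.0, 0.0, 1.0, 1.0]))
        res = best_split_sad(tr, segment_stats(tr, 0, 4))
        assert res.split_index == 2
        assert res.gain == pytest.approx(2.0)

    def test_constant_signal(self):
        tr = Trace(np.array([5.0] * 4))
        res = best_split_sad(tr, segment_stats(tr, 0, 4))
        assert res.gain == pytest.approx(0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(finite_signals)
    def test_matches_exhaustive_sad_search(self, x):
        tr = Trace(x)
        res = best_split_sad(tr, segment_stats(tr, 0, len(x)))
        idx, gain = brute_force_best_split_sad(x)
        assert res.gain == pytest.approx(gain, rel=1e-9, abs=1e-6)


class TestIterativeFit:
    def test_largest_gain_first(self):
        # noiseless staircase 0 -> 10 -> 11: the size-10 step wins iteration 1
        x = np.concatenate([np.zeros(10), np.full(10, 10.0), np.full(10, 11.0)])
        fit = iterative_fit(Trace(x), 2)
        order = [bp for _, bp, _ in fit.insertion_order]
        assert order[0] == 10
        assert order[1] == 20

    def test_residual_variance_monotone(self, rng):
        x = rng.normal(size=120) + np.repeat([0, 3, 1, 5], 30)
        tr = Trace(x)
        variances = [iterative_fit(tr, k).residual_variance for k in range(1, 12)]
        assert all(a >= b - 1e-12 for a, b in zip(variances, variances[1:]))
        gains = [g for _, _, g in iterative_fit(tr, 11).insertion_order]
        assert all(g >= -1e-9 for g in gains)

    def test_recovers_known_breakpoints(self):
        """5 well-separated steps at SNR 5: breakpoints within +-1 sample."""
        true_bps = np.array([40, 80, 120, 160])
        sizes = np.array([2.0, -1.5, 3.0, 2.5])
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            g = np.random.default_rng(seed)
            ideal = np.zeros(200)
            for b, s in zip(true_bps, sizes):
                ideal[b:] += s
            tr = Trace(ideal + g.normal(0, 0.15, 200))
            fit = iterative_fit(tr, 4)
            found = np.sort(fit.breakpoints)
            if np.all(np.abs(found - true_bps) <= 1):
                hits += 1
        assert hits >= 95

    def test_invalid_max_steps(self, two_level_trace):
        with pytest.raises(ParameterError):
            iterative_fit(two_level_trace, 0)

    def test_cusp_stability(self):
        """A wrong earlier breakpoint does not move later SSE minima.

        On a noiseless multi-step trace the optimal split of any segment that
        contains a true step falls exactly on a true step, regardless of how
        the rest of the trace was partitioned; this is what licenses the
        greedy scheme.
        """
        x = np.repeat([0.0, 4.0, 7.0, 12.0], 25)  # true steps at 25, 50, 75
        tr = Trace(x)
        wrong = 40  # force a mis-placed first breakpoint mid-plateau
        left = best_split(tr, segment_stats(tr, 0, wrong))
        assert left.split_index == 25
        right = best_split(tr, segment_stats(tr, wrong, 100))
        assert right.split_index == 75
        inner = best_split(tr, segment_stats(tr, wrong, right.split_index))
        assert inner.split_index == 50

    def test_sad_metric_fit(self):
        x = np.repeat([0.0, 5.0, 2.0], 20)
        fit = iterative_fit(Trace(x), 2, metric="sad")
        assert sorted(fit.breakpoints) == [20, 40]


class TestFitFromBreakpoints:
    def test_no_breakpoints(self):
        fit = fit_from_breakpoints(Trace(np.array([1.0, 2.0, 3.0])), [])
        assert fit.levels == pytest.approx([2.0])
        assert fit.residual_variance == pytest.approx(2.0 / 3.0)

    def test_exact_fit(self, two_level_trace):
        fit = fit_from_breakpoints(two_level_trace, [2])
        assert fit.levels == pytest.approx([0.0, 4.0])
        assert fit.residual_variance == 0.0
        assert np.array_equal(fit.fitted_signal(), [0, 0, 4, 4])

    def test_sse_is_sum_of_plateau_sses(self, rng):
        x = rng.normal(size=50)
        tr = Trace(x)
        bps = [7, 19, 33]
        fit = fit_from_breakpoints(tr, bps)
        edges = [0, *bps, 50]
        expected = sum(brute_force_sse(x[a:b]) for a, b in zip(edges, edges[1:]))
        assert fit.residual_variance * 50 == pytest.approx(expected, rel=1e-9)

    def test_validates_breakpoints(self, two_level_trace):
        for bad in ([3, 1], [0], [4], [2, 2]):
            with pytest.raises(ParameterError):
                fit_from_breakpoints(two_level_trace, bad)


def test_split_scan_count_grows_linearly():
    """Counted split-scan work scales near-linearly over a 100x size range."""
    counts = []
    ns = [1_000, 4_000, 16_000]
    for n in ns:
        g = np.random.default_rng(3)
        counts.append(split_scan_operations(Trace(g.normal(size=n))))
    ratio01 = counts[1] / counts[0]
    ratio12 = counts[2] / counts[1]
    # quadratic scanning would give ~16x per 4x step; observe ~4-6x
    assert ratio01 < 8 and ratio12 < 8
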