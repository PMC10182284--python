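import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from f1rotary import changepoint as cp
from f1rotary.simulate import tf1_saturating, simulate_trace


def brute_force_split(values):
    """O(n^2) oracle: exhaustive SSE scan over all split points."""
    n = len(values)
    best_k, best_sse = None, np.inf
    for k in range(1, n):
        left, right = values[:k], values[k:]
        sse = np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2)
        if sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    return best_k


class TestCusum:
    def test_constant_series(self):
        np.testing.assert_allclose(cp.cusum_series([5.0, 5, 5, 5]), np.zeros(4))
        assert cp.cusum_statistic([5.0, 5, 5, 5]) == 0.0

    def test_hand_computed_example(self):
        np.testing.assert_allclose(cp.cusum_series([1.0, 3, 2, 6]), [-2, -2, -3, 0])
        assert cp.cusum_statistic([1.0, 3, 2, 6]) == pytest.approx(3.0)

    def test_reversal_leaves_D_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=57)
        assert cp.cusum_statistic(x) == pytest.approx(cp.cusum_statistic(x[::-1]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=100
        )
    )
    def test_telescoping_identity(self, xs):
        """The CUSUM series always returns to zero at its last element."""
        c = cp.cusum_series(xs)
        bound = 1e-9 * len(xs) * max(1.0, np.max(np.abs(xs)))
        assert abs(c[-1]) <= bound

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=50),
        st.floats(min_value=-50, max_value=50),
        st.floats(min_value=-5, max_value=5),
    )
    def test_shift_invariance_and_scaling(self, xs, shift, scale):
        d = cp.cusum_statistic(xs)
        assert cp.cusum_statistic(np.asarray(xs) + shift) == pytest.approx(d, abs=1e-6)
        assert cp.cusum_statistic(np.asarray(xs) * scale) == pytest.approx(
            abs(scale) * d, abs=1e-6
        )


class TestPermutationTest:
    def test_constant_segment_p_one(self):
        assert cp.permutation_test(np.full(20, 3.0), n_perm=99, seed=0) == 1.0

    def test_clear_step_minimal_p(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 5, 100), rng.normal(80, 5, 100)])
        p = cp.permutation_test(x, n_perm=999, seed=2)
        assert p == pytest.approx(1 / 1000)

    def test_type_I_error_near_alpha(self):
        """Empirical rejection rate on iid noise ~ alpha (within 3 binomial SE)."""
        rng = np.random.default_rng(3)
        alpha, trials, n_perm = 0.05, 2000, 199
        rejections = 0
        for _ in range(trials):
            x = rng.normal(size=30)
            if cp.permutation_test(x, n_perm=n_perm, seed=rng) < alpha:
                rejections += 1
        # add-one estimator: exact rejection prob is 9/200 = 0.045
        expected = np.floor(alpha * (n_perm + 1)) / (n_perm + 1)
        se = np.sqrt(expected * (1 - expected) / trials)
        assert abs(rejections / trials - expected) < 3 * se

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(4).normal(size=50)
        assert cp.permutation_test(x, n_perm=199, seed=7) == cp.permutation_test(
            x, n_perm=199, seed=7
        )


class TestLocate:
    def test_clean_step(self):
        assert cp.locate_changepoint(np.repeat([0.0, 10.0], 3)) == 3

    def test_nearly_clean_step(self):
        assert cp.locate_changepoint(np.array([0.0, 0, 1, 9, 10, 10])) == 3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(2, 60)
            x = rng.normal(size=n)
            if rng.random() < 0.7:  # often include a real step
                x[rng.integers(1, n) :] += rng.uniform(-30, 30)
            assert cp.locate_changepoint(x) == brute_force_split(x)


class TestDetect:
    def test_noiseless_staircase(self, staircase):
        res = cp.detect_changepoints(staircase, n_perm=199, seed=0)
        assert res.changepoints == [50, 100]

    def test_two_constant_segments_single_cp(self):
        x = np.concatenate([np.full(20, 0.0), np.full(20, 50.0)])
        res = cp.detect_changepoints(x, n_perm=199, seed=1)
        assert res.changepoints == [20]

    def test_degenerate_constant_trace(self):
        res = cp.detect_changepoints(np.full(100, 7.0), n_perm=199, seed=2)
        assert res.changepoints == []

    def test_intervals_tile_trace(self, staircase):
        res = cp.detect_changepoints(staircase, n_perm=199, seed=3)
        bounds = [(i.start, i.stop) for i in res.intervals]
        assert bounds[0][0] == 0 and bounds[-1][1] == len(staircase)
        assert all(a[1] == b[0] for a, b in zip(bounds, bounds[1:]))

    def test_recovers_true_transitions(self):
        """Transitions flanked by >= 7 usable frames on both sides are found
        within +-3 frames at least 95% of the time."""
        fps = 10_000.0
        tr, truth = simulate_trace(tf1_saturating(), 2.0, fps, seed=7, return_truth=True)
        res = cp.detect_changepoints(tr, seed=1)
        cps = np.asarray(res.changepoints)
        starts = truth["start_s"].to_numpy()
        ends = truth["end_s"].to_numpy()
        nframes = np.floor(ends * fps) - np.ceil(starts * fps) + 1
        qual = (nframes[:-1] >= 7) & (nframes[1:] >= 7)
        k_true = np.ceil(starts[1:] * fps)[qual]
        matched = [np.any(np.abs(cps - k) <= 3) for k in k_true]
        assert len(matched) > 50
        assert np.mean(matched) >= 0.95

    def test_spurious_rate_on_pure_noise(self):
        """False change points on iid noise stay rare at alpha = 0.01."""
        x = np.random.default_rng(8).normal(0, 8, 10_000)
        res = cp.detect_changepoints(x, alpha=0.01, n_perm=999, seed=9)
        assert len(res.changepoints) <= 20


class TestMergeAndSweep:
    def make_intervals(self, values, bounds):
        return [
            cp.CPInterval.from_values(np.asarray(values, float), a, b)
            for a, b in zip(bounds, bounds[1:])
        ]

    def test_merge_criterion(self):
        # medians 10 and 12, MADs 3 and 2
        left = np.array([7.0, 10, 13, 10, 7, 13])  # median 10, MAD 3
        right = np.array([10.0, 12, 14, 12, 10, 14])  # median 12, MAD 2
        values = np.concatenate([left, right])
        intervals = self.make_intervals(values, [0, 6, 12])
        assert len(cp.merge_intervals(values, intervals, A=1.0)) == 1  # 2 < 5
        assert len(cp.merge_intervals(values, intervals, A=0.3)) == 2  # 2 >= 1.5

    def test_A_zero_never_merges_distinct_medians(self):
        values = np.repeat([0.0, 5.0, 9.0], 10)
        intervals = self.make_intervals(values, [0, 10, 20, 30])
        assert len(cp.merge_intervals(values, intervals, A=0.0)) == 3

    def test_merge_preserves_tiling(self, short_tf1_trace):
        x = short_tf1_trace.angle[:20_000]
        res = cp.detect_changepoints(x, n_perm=199, seed=4)
        merged = cp.merge_intervals(x, res.intervals, A=2.0)
        assert merged[0].start == 0 and merged[-1].stop == x.size
        assert all(a.stop == b.start for a, b in zip(merged, merged[1:]))

    def test_sweep_monotonic_and_limits(self, short_tf1_trace):
        x = short_tf1_trace.angle[:20_000]
        res = cp.detect_changepoints(x, n_perm=199, seed=5)
        grid = np.arange(0.0, 8.0, 0.5)
        curve = cp.a_factor_sweep(x, res.intervals, grid)
        errs = np.array([e for _, e in curve])
        assert np.all(np.diff(errs) >= -1e-6 * errs.max())
        # A=0 leaves the raw segmentation untouched
        base = np.sum(
            (x - np.concatenate([np.full(i.n, i.median_angle) for i in res.intervals]))
            ** 2
        )
        assert errs[0] == pytest.approx(base)

    def test_sweep_full_merge_limit(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(30, 1, 50)])
        intervals = self.make_intervals(x, [0, 50, 100])
        curve = cp.a_factor_sweep(x, intervals, np.array([0.0, 1.0, 100.0]))
        assert curve[-1][1] == pytest.approx(np.sum((x - np.median(x)) ** 2))

    def test_select_A_flat_then_jump(self):
        curve = [(0.0, 100.0), (0.5, 100.0), (1.0, 100.0), (1.5, 5000.0), (2.0, 5000.0)]
        assert cp.select_A(curve) == 1.0

    def test_select_A_flat_curve_falls_back_to_max(self):
        curve = [(0.0, 10.0), (1.0, 10.0), (2.0, 10.0)]
        assert cp.select_A(curve) == 2.0
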