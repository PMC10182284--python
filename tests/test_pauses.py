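import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from f1rotary import pauses as ps
from f1rotary.changepoint import CPInterval


def make_interval(median, n=20, start=0, mad=2.0):
    return CPInterval(start=start, stop=start + n, median_angle=median, mad=mad)


def interval_sequence(medians, n=20):
    out, pos = [], 0
    for m in medians:
        out.append(make_interval(m, n=n, start=pos))
        pos += n
    return out


class TestHistogram:
    def test_one_count_per_interval(self):
        intervals = interval_sequence([10, 130, 250, 370, 490])
        counts, _ = ps.interval_angle_histogram(intervals)
        assert counts.sum() == 5

    def test_three_occupied_bins(self):
        counts, edges = ps.interval_angle_histogram(interval_sequence([0, 120, 240]))
        assert np.count_nonzero(counts) == 3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ps.interval_angle_histogram([])


class TestFilters:
    def test_seven_point_boundary(self):
        kept = ps.filter_short_intervals(
            [make_interval(0, n=6), make_interval(10, n=7)]
        )
        assert [i.n for i in kept] == [7]

    def test_min_len_one_is_identity(self):
        intervals = interval_sequence([0, 50, 100])
        assert ps.filter_short_intervals(intervals, min_len=1) == intervals

    def test_backstep_removed(self):
        intervals = interval_sequence([100, 90, 180])
        kept = ps.filter_nonprogressive(intervals)
        assert [i.median_angle for i in kept] == [100, 180]

    def test_progressive_forty_degree_steps_kept(self):
        intervals = interval_sequence([100, 140, 180])
        assert len(ps.filter_nonprogressive(intervals)) == 3  # 40 not < 40

    def test_monotone_large_staircase_identity(self):
        intervals = interval_sequence([0, 50, 100, 150, 200])
        assert ps.filter_nonprogressive(intervals) == intervals

    def test_small_progressive_wiggle_kept(self):
        # strictly increasing medians under 40 degrees apart: progressive, kept
        intervals = interval_sequence([100, 110, 120])
        assert len(ps.filter_nonprogressive(intervals)) == 3


class TestCountPauses:
    def test_three_pause_scheme(self):
        medians = [a + d for a in (0, 120, 240) for d in np.linspace(-2, 2, 10)]
        n, peaks = ps.count_pauses_per_turn(interval_sequence(medians))
        assert n == 3
        assert peaks == pytest.approx([0, 120, 240], abs=1.0)

    def test_six_pause_scheme(self):
        medians = [
            a + d for a in (0, 80, 120, 200, 240, 320) for d in np.linspace(-2, 2, 10)
        ]
        n, peaks = ps.count_pauses_per_turn(interval_sequence(medians))
        assert n == 6

    def test_all_identical_medians(self):
        n, peaks = ps.count_pauses_per_turn(interval_sequence([90.0] * 12))
        assert n == 1
        assert peaks[0] == pytest.approx(90.0)

    def test_stragglers_do_not_chain_peaks(self):
        # two strong peaks 40 degrees apart plus 3 bridging stragglers
        medians = [80.0] * 50 + [120.0] * 30 + [95.0, 100.0, 107.0]
        n, peaks = ps.count_pauses_per_turn(interval_sequence(medians))
        assert n == 2

    def test_no_intervals_ambiguous(self):
        assert ps.count_pauses_per_turn([]) == (0, [])


class TestClassify:
    @pytest.mark.parametrize(
        "n_km,n_sat,expected",
        [
            (3, None, "3"),
            (6, None, "6-or-9"),
            (6, 6, "9"),
            (6, 3, "6"),
            (9, 6, "9"),
            (4, None, "ambiguous"),
            (6, 5, "ambiguous"),
        ],
    )
    def test_rule_table(self, n_km, n_sat, expected):
        cls, evidence = ps.classify_stepper(n_km, n_sat)
        assert cls == expected
        assert evidence


class TestMainSubAndRatio:
    def six_peak_intervals(self, sub_offset=40.0, n_turns=12, main_n=30, sub_n=8):
        """Alternating main/sub occurrences with mains at 80+120k."""
        intervals, pos = [], 0
        for t in range(n_turns * 3):
            main = 80.0 + 120.0 * t
            intervals.append(make_interval(main, n=main_n, start=pos))
            pos += main_n
            intervals.append(make_interval(main + sub_offset, n=sub_n, start=pos))
            pos += sub_n
        return intervals

    def test_labels_follow_occupancy(self):
        intervals = self.six_peak_intervals()
        n, peaks = ps.count_pauses_per_turn(intervals)
        assert n == 6
        labels, bounds = ps.label_main_sub(peaks, intervals)
        mains = [p for p, l in zip(sorted(peaks), labels) if l == "main"]
        assert mains == pytest.approx([80, 200, 320], abs=1.0)
        assert len(bounds) == 6

    def test_ratio_tf1_geometry(self):
        intervals = self.six_peak_intervals(sub_offset=40.0)
        _, peaks = ps.count_pauses_per_turn(intervals)
        labels, _ = ps.label_main_sub(peaks, intervals)
        ratios = ps.angular_distance_ratio(intervals, peaks, labels)
        assert np.mean(ratios) == pytest.approx(0.5, abs=1e-9)

    def test_ratio_bmf1_geometry(self):
        intervals = self.six_peak_intervals(sub_offset=60.0)
        _, peaks = ps.count_pauses_per_turn(intervals)
        labels, _ = ps.label_main_sub(peaks, intervals)
        ratios = ps.angular_distance_ratio(intervals, peaks, labels)
        assert np.mean(ratios) == pytest.approx(1.0, abs=1e-9)

    def test_a_plus_b_is_120(self):
        rng = np.random.default_rng(0)
        intervals = self.six_peak_intervals()
        # jitter medians slightly; a + b still spans main-to-main = 120
        for itv in intervals:
            itv.median_angle += rng.normal(0, 1.0)
        _, peaks = ps.count_pauses_per_turn(intervals)
        labels, _ = ps.label_main_sub(peaks, intervals)
        ratios = ps.angular_distance_ratio(intervals, peaks, labels)
        assert len(ratios) > 10
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)

    def test_label_requires_six_peaks(self):
        with pytest.raises(ValueError):
            ps.label_main_sub([0, 120, 240], [])


class TestMeanRatio:
    def test_constant_ratios(self):
        assert ps.mean_ratio([0.5] * 5) == (0.5, 0.0)

    def test_tukey_outlier_removed(self):
        mean, se = ps.mean_ratio([0.5] * 20 + [5.0])
        assert mean == pytest.approx(0.5)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            ps.mean_ratio([0.5, 0.6])


class TestClusterRatios:
    def test_first_merge_closest_pair(self):
        Z, names = ps.cluster_ratios({"A": 0.5, "B": 0.52, "C": 1.0})
        # first merge joins A and B at height 0.02
        assert sorted(Z[0, :2]) == [names.index("A"), names.index("B")]
        assert Z[0, 2] == pytest.approx(0.02)
        # cutting below the top merge separates C
        flat = fcluster(Z, t=2, criterion="maxclust")
        assert flat[names.index("A")] == flat[names.index("B")] != flat[names.index("C")]

    def test_two_items_single_merge(self):
        Z, _ = ps.cluster_ratios({"X": 0.4, "Y": 1.0})
        assert Z.shape[0] == 1
        assert Z[0, 2] == pytest.approx(0.6)

    def test_order_invariant_heights(self):
        a = ps.cluster_ratios({"A": 0.5, "B": 0.52, "C": 1.0})[0]
        b = ps.cluster_ratios({"C": 1.0, "A": 0.5, "B": 0.52})[0]
        np.testing.assert_allclose(np.sort(a[:, 2]), np.sort(b[:, 2]))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ps.cluster_ratios([("A", 0.5), ("A", 0.6)])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            ps.cluster_ratios({"A": 0.5})
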