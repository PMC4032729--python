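"""Length grouping, error statistics, proportions and the selection index."""

import math

import numpy as np
import pandas as pd
import pytest

from leafmetric.morphometry import LeafMeasurement
from leafmetric.stats_selection import (
    GroupStats,
    LeafRecord,
    assign_groups,
    build_partition,
    cohort_deviations,
    cohort_stats,
    group_deviations,
    included_groups,
    leaf_errors,
    proportions,
    rmsd,
    select_optimal_st,
    selection_index,
    selection_index_mc,
    truncate,
)


def record(leaf_id, l_o, h_o, x=10, l_d=None, h_d=None, a_mc=None):
    """A leaf record with one synthetic measurement at tolerance x."""
    l_d = l_o if l_d is None else l_d
    h_d = h_o if h_d is None else h_d
    a_d = l_d * h_d
    a_mc = a_d if a_mc is None else a_mc
    m = LeafMeasurement(
        x=x, np_l=int(l_d), np_h=int(h_d), l_d=l_d, h_d=h_d, a_d=a_d,
        lpn=0, upn=1.0, a_mc=a_mc, flooded=False,
    )
    return LeafRecord(leaf_id=leaf_id, l_o=l_o, h_o=h_o, measurements={x: m})


class TestPartition:
    def test_reference_partition(self):
        p = build_partition(460, 46)
        assert p.q == 10
        assert len(p.intervals) == 46
        assert p.interval(1) == (0, 10)
        assert p.interval(46) == (450, 460)

    def test_intervals_are_half_open(self):
        p = build_partition(100, 10)
        assert p.interval(3) == (20, 30)
        assert p.index_of(10) == 2  # boundary belongs to the upper interval
        assert p.index_of(9.999) == 1

    def test_longest_leaf_falls_in_last_interval(self):
        p = build_partition(460, 46)
        assert p.index_of(460) == 46

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_partition(0, 10)
        with pytest.raises(ValueError):
            build_partition(100, 0)


class TestAssignGroups:
    def test_direct_binning_with_exclusion(self):
        p = build_partition(100, 10)
        leaves = [record("a", 5, 1), record("b", 7, 1), record("c", 15, 1)]
        groups, out = assign_groups(leaves, p)
        assert not out
        by_k = {g.k: g for g in groups}
        assert by_k[1].n_k == 2 and by_k[1].included
        assert by_k[2].n_k == 1 and not by_k[2].included
        assert sum(g.n_k for g in groups) == 3

    def test_empty_cohort(self):
        p = build_partition(100, 10)
        groups, out = assign_groups([], p)
        assert included_groups(groups) == []

    def test_out_of_range_reported_not_dropped(self):
        p = build_partition(100, 10)
        leaves = [record("in", 50, 1), record("beyond", 150, 1)]
        groups, out = assign_groups(leaves, p)
        assert [l.leaf_id for l in out] == ["beyond"]
        assert sum(g.n_k for g in groups) == 1


def test_leaf_errors_signs():
    r = record("a", 100, 5, l_d=90, h_d=5, a_mc=505)
    e_l, e_h, e_a, e_mc = leaf_errors(r, 10)
    assert e_l == 10         # image underestimates length
    assert e_h == 0
    assert e_a == 100 * 5 - 90 * 5
    assert e_mc == pytest.approx(-5)  # overestimation is negative

    with pytest.raises(KeyError):
        leaf_errors(r, 99)


class TestGroupDeviations:
    def test_mean_of_errors(self):
        p = build_partition(100, 10)
        leaves = [record("a", 12, 1, l_d=10), record("b", 14, 1, l_d=10)]
        groups, _ = assign_groups(leaves, p)
        g = included_groups(groups)[0]
        st = group_deviations(g, 10)
        assert st.delta_l == pytest.approx(3)  # errors {2, 4}

    def test_cancellation(self):
        p = build_partition(100, 10)
        leaves = [record("a", 10, 1, l_d=11), record("b", 12, 1, l_d=11)]
        groups, _ = assign_groups(leaves, p)
        st = group_deviations(included_groups(groups)[0], 10)
        assert st.delta_l == pytest.approx(0)  # errors {-1, +1}

    def test_excluded_group_rejected(self):
        p = build_partition(100, 10)
        groups, _ = assign_groups([record("a", 5, 1)], p)
        with pytest.raises(ValueError):
            group_deviations(groups[0], 10)


def gstat(k, e_l, e_h=None, e_a=None, e_mc=None):
    e_l = np.asarray(e_l, dtype=float)
    e_h = np.zeros_like(e_l) if e_h is None else np.asarray(e_h, dtype=float)
    e_a = np.ones_like(e_l) if e_a is None else np.asarray(e_a, dtype=float)
    e_mc = e_a if e_mc is None else np.asarray(e_mc, dtype=float)
    return GroupStats(
        k=k, n_k=len(e_l), e_l=e_l, e_h=e_h, e_a=e_a, e_mc=e_mc,
        delta_l=float(e_l.mean()), delta_h=float(e_h.mean()), delta_a=float(e_a.mean()),
    )


class TestCohortDeviations:
    def test_mean_over_groups(self):
        stats = [gstat(1, [1, 3]), gstat(2, [3, 5])]  # deltas 2 and 4
        dbl, dbh, sdl, sdh = cohort_deviations(stats)
        assert dbl == pytest.approx(3)

    def test_identical_errors_zero_sd(self):
        stats = [gstat(1, [2, 2]), gstat(2, [2, 2])]
        _, _, sdl, _ = cohort_deviations(stats)
        assert sdl == 0

    def test_pooled_sd_hand_example(self):
        """Groups with errors {0,2} and {10,14}: pooled SD sqrt((2+8)/2)."""
        stats = [gstat(1, [0, 2]), gstat(2, [10, 14])]
        _, _, sdl, _ = cohort_deviations(stats)
        assert sdl == pytest.approx(math.sqrt(5))

    def test_no_groups_rejected(self):
        with pytest.raises(ValueError):
            cohort_deviations([])


class TestProportions:
    def test_all_pass_all_underestimated(self):
        stats = [gstat(1, [1, 1]), gstat(2, [1, 1])]
        p = proportions(stats, 1.0, 0.0, 1.0, 1.0)
        assert p["lambda_l"] == 1 and p["theta_l"] == 0
        assert p["lambda_h"] == 1 and p["theta_h"] == 0
        assert p["lambda_a"] == 1 and p["beta_a"] == 0

    def test_single_group_always_passes_its_band(self):
        stats = [gstat(1, [4, 6])]
        dbl, dbh, sdl, sdh = cohort_deviations(stats)
        p = proportions(stats, dbl, dbh, sdl, sdh)
        assert p["lambda_l"] == 1

    def test_three_group_hand_enumeration(self):
        """Groups with length deltas 0, 1, 2 and pooled sigma sqrt(0.5):
        only the middle group lies in [1 - 0.707, 1 + 0.707], so its two
        leaves of six pass: lambda_l = 1/3.  Width errors are all zero
        (degenerate band, every group passes) and all area errors are
        nonnegative, so lambda_a = 1/3 as well.
        """
        stats = [
            gstat(1, [-0.5, 0.5]),
            gstat(2, [0.5, 1.5]),
            gstat(3, [1.5, 2.5]),
        ]
        dbl, dbh, sdl, sdh = cohort_deviations(stats)
        assert dbl == pytest.approx(1.0)
        assert sdl == pytest.approx(math.sqrt(0.5))
        p = proportions(stats, dbl, dbh, sdl, sdh)
        assert p["lambda_l"] == pytest.approx(1 / 3)
        assert p["theta_l"] == pytest.approx(2 / 3)
        assert p["lambda_a"] == pytest.approx(1 / 3)
        assert p["beta_a"] == pytest.approx(2 / 3)

    def test_overestimated_area_moves_leaf_to_beta(self):
        stats = [gstat(1, [0.0, 0.0], e_a=[1.0, -1.0])]
        dbl, dbh, sdl, sdh = cohort_deviations(stats)
        p = proportions(stats, dbl, dbh, sdl, sdh)
        assert p["lambda_a"] == pytest.approx(0.5)
        assert p["beta_a"] == pytest.approx(0.5)

    def test_complements_sum_to_one(self):
        stats = [gstat(1, [-0.5, 0.5]), gstat(2, [3.0, 4.0], e_a=[-1, 2])]
        dbl, dbh, sdl, sdh = cohort_deviations(stats)
        p = proportions(stats, dbl, dbh, sdl, sdh)
        assert p["lambda_l"] + p["theta_l"] == pytest.approx(1)
        assert p["lambda_h"] + p["theta_h"] == pytest.approx(1)
        assert p["lambda_a"] + p["beta_a"] == pytest.approx(1)
        assert p["lambda_amc"] + p["beta_amc"] == pytest.approx(1)

    def test_scale_free_in_group_sizes(self):
        """Replicating every leaf r times leaves all proportions unchanged."""
        base = [gstat(1, [-0.5, 0.5]), gstat(2, [0.5, 1.5]), gstat(3, [1.5, 2.5])]
        tripled = [gstat(g.k, np.repeat(g.e_l, 3), np.repeat(g.e_h, 3),
                         np.repeat(g.e_a, 3), np.repeat(g.e_mc, 3)) for g in base]
        dbl, dbh, sdl, sdh = cohort_deviations(base)
        p1 = proportions(base, dbl, dbh, sdl, sdh)
        p2 = proportions(tripled, dbl, dbh, sdl, sdh)
        for key in p1:
            assert p1[key] == pytest.approx(p2[key])


class TestSelectionIndex:
    @pytest.mark.parametrize(
        "lam,beta,expected",
        [
            (0.6820, 0.3180, 0.4662),
            (0.7005, 0.2995, 0.4275),
            (1.0, 0.0, 0.0),
        ],
    )
    def test_reference_values(self, lam, beta, expected):
        assert truncate(selection_index(lam, beta)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "lam,beta,expected",
        [
            (0.7197, 0.2803, 0.3894),
            (0.4917, 0.5083, 1.0337),
            (1.0, 0.0, 0.0),
        ],
    )
    def test_monte_carlo_reference_values(self, lam, beta, expected):
        assert truncate(selection_index_mc(lam, beta)) == pytest.approx(expected)

    def test_undefined_when_lambda_zero(self):
        with pytest.raises(ValueError):
            selection_index(0.0, 1.0)


class TestRmsd:
    def test_identical_sequences(self):
        assert rmsd([1, 2, 3], [1, 2, 3]) == 0

    def test_constant_offset(self):
        assert rmsd([1, 2], [2, 3]) == pytest.approx(1)

    def test_hand_computation(self):
        assert rmsd([0, 0], [3, 4]) == pytest.approx(math.sqrt(25 / 2))

    def test_mismatched_or_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd([1, 2], [1])
        with pytest.raises(ValueError):
            rmsd([], [])


class TestSelectOptimal:
    def make_table(self, rows):
        return pd.DataFrame(
            [{"x": x, "is_x": v} for x, v in rows]
        ).set_index("x")

    def test_reference_pattern(self):
        table = self.make_table([(68, 0.4662), (128, 0.4275), (192, 1.0072)])
        assert select_optimal_st(table) == 128

    def test_single_row(self):
        assert select_optimal_st(self.make_table([(5, 2.0)])) == 5

    def test_tie_broken_toward_smaller_x(self):
        assert select_optimal_st(self.make_table([(10, 0.5), (20, 0.5)])) == 10

    def test_inadmissible_rows_skipped(self):
        table = self.make_table([(10, math.inf), (20, 0.7)])
        assert select_optimal_st(table) == 20

    def test_all_inadmissible_rejected(self):
        with pytest.raises(ValueError):
            select_optimal_st(self.make_table([(10, math.inf)]))


def test_cohort_stats_requires_an_included_group():
    p = build_partition(100, 10)
    groups, _ = assign_groups([record("a", 5, 1), record("b", 15, 1)], p)
    with pytest.raises(ValueError):
        cohort_stats(groups, 10)


def test_truncate_matches_reported_convention():
    assert truncate(0.2995 / 0.7005) == 0.4275
    assert truncate(0.99999) == 0.9999
    assert truncate(1.0) == 1.0
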