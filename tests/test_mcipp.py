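"""Pair-partition model: moves, heuristic, exact searches, validators."""

import pytest

from pedcmp import mcipp
from pedcmp.mcipp import (
    InfeasibleInstanceError,
    as_pair_multiset,
    best_heuristic_size,
    bounds,
    completable_by_dominating,
    dominates,
    dominating_partition_step,
    exact_mcip_fpt,
    exact_mcipp_fpt,
    heuristic_mcipp,
    mcip_optimize,
    mcipp_optimize,
    non_dominating_partition_step,
    nondominating_pairs,
    preprocess_common_tuples,
    projection_sums,
    validate_common_pair_partition,
    validate_common_partition,
)

from conftest import WORKED_S, WORKED_T


class TestDominance:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((4, 5), (2, 4), "u_dominates"),
            ((2, 4), (4, 5), "v_dominates"),
            ((1, 4), (2, 3), "non_dominating"),
            ((3, 3), (3, 3), "both_equal"),
            ((2, 0), (2, 4), "v_dominates"),
        ],
    )
    def test_classification(self, u, v, expected):
        assert dominates(u, v) == expected


class TestPartitionSteps:
    def test_dominating_split_of_printed_pair(self):
        piece, S2, T2 = dominating_partition_step([(2, 4)], [(4, 5)], (2, 4), (4, 5))
        assert piece == (2, 4)
        assert S2 == () and T2 == ((2, 1),)

    def test_equal_tuples_consume_both_sides(self):
        piece, S2, T2 = dominating_partition_step([(3, 3)], [(3, 3)], (3, 3), (3, 3))
        assert piece == (3, 3) and S2 == () and T2 == ()

    def test_non_dominating_split_both_orientations(self):
        piece, S2, T2 = non_dominating_partition_step(
            [(6, 3)], [(2, 9)], (6, 3), (2, 9)
        )
        assert piece == (2, 3) and S2 == ((4, 0),) and T2 == ((0, 6),)
        piece, S2, T2 = non_dominating_partition_step(
            [(1, 4)], [(2, 3)], (1, 4), (2, 3)
        )
        assert piece == (1, 3) and S2 == ((0, 1),) and T2 == ((1, 0),)

    def test_steps_reject_wrong_pair_kind(self):
        with pytest.raises(ValueError):
            dominating_partition_step([(1, 4)], [(2, 3)], (1, 4), (2, 3))
        with pytest.raises(ValueError):
            non_dominating_partition_step([(2, 4)], [(4, 5)], (2, 4), (4, 5))

    def test_axis_tuples_cannot_be_split(self):
        # the exchanged piece would be the forbidden (0, 0)
        with pytest.raises(ValueError, match="0, 0"):
            non_dominating_partition_step([(4, 0)], [(0, 6)], (4, 0), (0, 6))

    @pytest.mark.parametrize(
        "s, t",
        [((6, 3), (2, 9)), ((1, 4), (2, 3)), ((9, 4), (2, 8)), ((5, 5), (5, 5))],
    )
    def test_every_step_conserves_projection_sums(self, s, t):
        S, T = [s, (3, 3)], [t, (3, 3)]
        # make the instance feasible by padding: conservation is per-step,
        # so feasibility of the whole instance is not required here
        if dominates(s, t) == "non_dominating":
            piece, S2, T2 = non_dominating_partition_step(S, T, s, t)
        else:
            piece, S2, T2 = dominating_partition_step(S, T, s, t)
        for before, after in ((S, S2), (T, T2)):
            ps = projection_sums(after)
            assert (ps[0] + piece[0], ps[1] + piece[1]) == projection_sums(before)


class TestPreprocessing:
    def test_identical_sides_fully_consumed(self):
        common, S2, T2 = preprocess_common_tuples([(1, 2), (3, 4)], [(3, 4), (1, 2)])
        assert common == ((1, 2), (3, 4)) and S2 == () and T2 == ()

    def test_multiset_intersection_respects_multiplicity(self):
        common, S2, T2 = preprocess_common_tuples(
            [(1, 2), (3, 4)], [(3, 4), (0, 3)]
        )
        assert common == ((3, 4),)
        assert S2 == ((1, 2),) and T2 == ((0, 3),)


class TestBounds:
    def test_three_by_three(self):
        assert bounds(WORKED_S, WORKED_T) == (3, 6)

    def test_singleton(self):
        assert bounds([(3, 2)], [(3, 2)]) == (1, 2)

    def test_infeasible_rejected(self):
        with pytest.raises(InfeasibleInstanceError):
            bounds([(2, 4)], [(4, 5)])


class TestHeuristic:
    def test_forced_start_on_worked_instance_gives_six(self):
        res = heuristic_mcipp(WORKED_S, WORKED_T, start=((6, 3), (2, 9)))
        assert res.size == 6
        assert res.partition.is_valid_for(WORKED_S, WORKED_T)
        assert res.lower_bound == 3 and res.upper_bound == 6

    def test_singleton_instance(self):
        res = heuristic_mcipp([(3, 2)], [(3, 2)])
        assert res.size == 1 and res.partition.pieces == ((3, 2),)

    def test_unforced_run_is_deterministic_and_within_bounds(self):
        a = heuristic_mcipp(WORKED_S, WORKED_T)
        b = heuristic_mcipp(WORKED_S, WORKED_T)
        assert a.partition == b.partition
        assert 3 <= a.size <= 6

    def test_random_tie_break_still_validates(self):
        for seed in range(5):
            res = heuristic_mcipp(WORKED_S, WORKED_T, tie_break="random", seed=seed)
            assert res.partition.is_valid_for(WORKED_S, WORKED_T)
            assert res.size <= 6

    def test_start_rejected_when_not_nondominating(self):
        with pytest.raises(ValueError, match="non-dominating"):
            heuristic_mcipp(WORKED_S, WORKED_T, start=((9, 4), (1, 1)))

    def test_infeasible_rejected(self):
        with pytest.raises(InfeasibleInstanceError):
            heuristic_mcipp([(2, 4)], [(4, 5)])


class TestExactSearches:
    def test_singleton_k1(self):
        res = exact_mcipp_fpt([(3, 2)], [(3, 2)], k=1)
        assert res is not None and res.partition.pieces == ((3, 2),)

    def test_k_below_lower_bound_is_immediate_no(self):
        assert exact_mcipp_fpt(WORKED_S, WORKED_T, k=2) is None

    def test_worked_instance_optimum_is_six(self):
        assert exact_mcipp_fpt(WORKED_S, WORKED_T, k=5) is None
        res = exact_mcipp_fpt(WORKED_S, WORKED_T, k=6)
        assert res is not None and res.size == 6
        assert res.partition.is_valid_for(WORKED_S, WORKED_T)

    def test_optimizer_reaches_decision_threshold(self):
        res = mcipp_optimize(WORKED_S, WORKED_T, method="fpt")
        assert res.size == 6 and res.lower_bound == 3

    def test_mcip_printed_example_optimum_four(self):
        assert exact_mcip_fpt([2, 5, 5], [6, 6], k=3) is None
        res = exact_mcip_fpt([2, 5, 5], [6, 6], k=4)
        assert res is not None and res.size == 4
        assert res.partition.is_valid_for((2, 5, 5), (6, 6))

    def test_mcip_identical_sides(self):
        res = mcip_optimize([3, 3, 7], [3, 3, 7], method="fpt")
        assert res.size == 3

    def test_optimal_partition_uses_each_source_pair_once(self):
        # normal form: no two pieces of an optimal partition share both sources
        res = mcipp_optimize(WORKED_S, WORKED_T, method="fpt")
        pairs = list(zip(res.partition.s_assign, res.partition.t_assign))
        assert len(pairs) == len(set(pairs))


class TestValidators:
    def test_printed_common_partition_accepted(self):
        assert validate_common_partition([5, 8], [3, 10], [1, 2, 2, 4, 4])

    def test_smaller_partition_accepted(self):
        assert validate_common_partition([5, 8], [3, 10], [3, 2, 8])

    def test_identity_partition_accepted(self):
        assert validate_common_partition([4, 9], [4, 9], [4, 9])

    def test_wrong_multiset_rejected(self):
        assert not validate_common_partition([5, 8], [3, 10], [1, 2, 2, 4, 3])
        assert not validate_common_partition([5, 8], [3, 10], [5, 8])

    def test_pair_partition_validator(self):
        H = [(2, 3), (0, 6), (1, 5), (4, 0), (1, 3), (8, 1)]
        assert validate_common_pair_partition(WORKED_S, WORKED_T, H)
        assert not validate_common_pair_partition(WORKED_S, WORKED_T, H[:-1])


class TestStepChoiceAnalysis:
    def test_four_starts_complete_with_dominating_splits_alone(self):
        completable = 0
        for s, t in nondominating_pairs(WORKED_S, WORKED_T):
            _, S2, T2 = non_dominating_partition_step(WORKED_S, WORKED_T, s, t)
            completable += completable_by_dominating(S2, T2)
        assert completable == 4

    def test_remaining_starts_all_bottom_out_at_seven(self):
        sizes = set()
        for s, t in nondominating_pairs(WORKED_S, WORKED_T):
            _, S2, T2 = non_dominating_partition_step(WORKED_S, WORKED_T, s, t)
            if not completable_by_dominating(S2, T2):
                sizes.add(1 + best_heuristic_size(S2, T2))
        assert sizes == {7}

    def test_heuristic_matches_exhaustive_best_from_good_starts(self):
        for s, t in nondominating_pairs(WORKED_S, WORKED_T):
            _, S2, T2 = non_dominating_partition_step(WORKED_S, WORKED_T, s, t)
            expected = 1 + best_heuristic_size(S2, T2)
            res = heuristic_mcipp(WORKED_S, WORKED_T, start=(s, t))
            assert res.size == expected
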