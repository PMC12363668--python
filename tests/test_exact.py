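"""Closed forms, full and lumped chain solvers, fixation probabilities."""

from fractions import Fraction

import numpy as np
import pytest
from sympy.utilities.iterables import partitions as int_partitions

from divtime import (
    CapacityError,
    InvalidParameterError,
    absorption_time_full,
    absorption_time_lumped,
    b_profile,
    complete_time,
    cycle_time,
    enumerate_connected_graphs,
    fixation_probability_two_type,
    harmonic_number,
    lumped_absorption_times,
    make_complete,
    make_cycle,
    make_double_star,
    make_path,
    make_star,
    maximal_diversity,
    partition_state_count,
    star_time_conjecture,
)
from divtime.exact import canonical_partition, restricted_growth_strings

from conftest import random_strongly_connected_digraph

REL = 1e-9


def _abundances(N):
    """All integer partitions of N as sorted abundance tuples."""
    for p in int_partitions(N):
        yield tuple(sorted((k for k, mult in p.items() for _ in range(mult)), reverse=True))


class TestBProfile:
    @pytest.mark.parametrize("lam,h,expect", [((3, 2), 0, 5), ((3, 2), 1, 3), ((3, 2), 3, 0)])
    def test_examples(self, lam, h, expect):
        assert b_profile(lam, h) == expect

    def test_b0_is_population_size(self):
        for lam in _abundances(7):
            assert b_profile(lam, 0) == 7


class TestCompleteClosedForm:
    @pytest.mark.parametrize("N", [2, 3, 5, 8])
    def test_maximal_diversity_is_N_times_Nminus1(self, N):
        assert complete_time([1] * N).fraction == N * (N - 1)

    def test_homogeneous_is_zero(self):
        assert complete_time([6]).expected_time == 0

    def test_two_type_gamblers_ruin(self):
        # lazy +-1 walk on abundance k with move prob k(N-k)/N^2 per direction:
        # expected absorption from k=1, N=3 is 2 active steps * 9/4 each
        assert complete_time([2, 1]).expected_time == pytest.approx(4.5)

    def test_31_partition(self):
        assert complete_time([3, 1]).fraction == Fraction(22, 3)

    def test_no_loops_maximal_diversity(self):
        assert complete_time([1] * 5, self_loops=False).fraction == 16

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            complete_time([])

    @pytest.mark.parametrize("N", range(1, 13))
    def test_double_sum_equals_histogram_form_exhaustively(self, N):
        """The two closed-form expressions agree (exact rationals) on every
        partition of every N <= 12; complete_time cross-asserts internally."""
        for lam in _abundances(N):
            complete_time(lam)

    def test_brute_force_two_type_oracle(self):
        # independent oracle: scalar first-step recursion on abundance k
        N = 6
        # tau[k] for k=0..N absorbed at 0 and N; move prob p = k(N-k)/N^2 each way
        A = np.zeros((N - 1, N - 1))
        rhs = np.ones(N - 1)
        for k in range(1, N):
            p = k * (N - k) / N**2
            A[k - 1, k - 1] = 2 * p
            if k - 2 >= 0:
                A[k - 1, k - 2] = -p
            if k < N - 1:
                A[k - 1, k] = -p
        tau = np.linalg.solve(A, rhs)
        for k in range(1, N):
            lam = (max(k, N - k), min(k, N - k))
            assert complete_time(lam).expected_time == pytest.approx(tau[k - 1], rel=1e-12)


class TestCycleClosedForm:
    @pytest.mark.parametrize("N,expect", [(3, 4), (10, 165)])
    def test_maximal_diversity(self, N, expect):
        assert cycle_time([1] * N).fraction == expect

    def test_triangle_equals_complete_no_loops(self):
        assert cycle_time([1] * 3).fraction == complete_time([1] * 3, self_loops=False).fraction

    def test_homogeneous_is_zero(self):
        assert cycle_time([9]).expected_time == 0

    @pytest.mark.parametrize(
        "blocks,lam",
        [
            ([[0, 1], [2], [3, 4]], (2, 2, 1)),
            ([[0, 1, 2], [3, 4]], (3, 2)),
            ([[0], [1], [2], [3, 4]], (2, 1, 1, 1)),
        ],
    )
    def test_clustered_configurations_match_solver(self, blocks, lam):
        g = make_cycle(5)
        cf = cycle_time(lam).expected_time
        sv = absorption_time_lumped(g, "bd", omega0=blocks).expected_time
        assert sv == pytest.approx(cf, rel=REL)


class TestStarConjecture:
    @pytest.mark.parametrize("n,expect", [(1, 1), (2, 7), (3, Fraction(47, 2))])
    def test_small_values(self, n, expect):
        res = star_time_conjecture(n)
        assert res.fraction == expect
        assert res.conjecture

    def test_harmonic_numbers(self):
        assert harmonic_number(4) == Fraction(25, 12)


class TestFullChain:
    def test_complete3_maximal_diversity(self):
        g = make_complete(3)
        assert absorption_time_full(g, "bd", [0, 1, 2]).expected_time == pytest.approx(6, rel=REL)

    def test_homogeneous_start(self):
        g = make_cycle(4)
        assert absorption_time_full(g, "db", [2, 2, 2, 2]).expected_time == 0

    def test_path3_first_step_analysis(self):
        # hand first-step analysis on the 27-state labelled chain gives 7
        g = make_path(3)
        assert absorption_time_full(g, "bd", [0, 1, 2]).expected_time == pytest.approx(7, rel=REL)

    def test_capacity(self):
        with pytest.raises(CapacityError):
            absorption_time_full(make_cycle(6), "bd", [0] * 6)


class TestLumpedChain:
    @pytest.mark.parametrize("N,expect", [(4, 12), (5, 20), (6, 30)])
    def test_complete_with_loops(self, N, expect):
        res = absorption_time_lumped(make_complete(N), "bd")
        assert res.expected_time == pytest.approx(expect, rel=REL)
        assert res.state_count == partition_state_count(N)

    @pytest.mark.parametrize("N,expect", [(4, 10), (5, 20), (6, 35)])
    def test_cycle(self, N, expect):
        assert absorption_time_lumped(make_cycle(N), "bd").expected_time == pytest.approx(
            expect, rel=REL
        )

    def test_complete_no_loops_is_Nminus1_squared(self):
        for N in (3, 4, 5):
            res = absorption_time_lumped(make_complete(N, self_loops=False), "db")
            assert res.expected_time == pytest.approx((N - 1) ** 2, rel=REL)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_star_conjecture_verified_small_n(self, n):
        solver = absorption_time_lumped(make_star(n + 1), "bd").expected_time
        conj = float(star_time_conjecture(n).expected_time)
        assert solver == pytest.approx(conj, rel=REL), (
            f"star conjecture violated at n={n}: solver {solver}, formula {conj}"
        )

    def test_rational_mode_star4(self):
        res = absorption_time_lumped(make_star(4), "bd", exact=True)
        assert res.fraction == Fraction(47, 2)

    def test_regular_graphs_rule_invariant(self):
        for g in (make_cycle(7), make_cycle(8), make_complete(7), make_complete(8)):
            b = absorption_time_lumped(g, "bd").expected_time
            d = absorption_time_lumped(g, "db").expected_time
            assert d == pytest.approx(b, rel=REL)

    def test_two_block_starts_absorb_no_slower(self):
        for g in (make_star(5), make_double_star(6), make_cycle(6)):
            for rule in ("bd", "db"):
                states, times = lumped_absorption_times(g, rule)
                tmax = times[
                    list(states).index(tuple(range(g.n_vertices)))
                ]
                for s, t in zip(states, times):
                    if max(s) == 1:  # exactly two blocks
                        assert t <= tmax + 1e-9

    def test_capacity(self):
        with pytest.raises(CapacityError):
            absorption_time_lumped(make_cycle(13), "bd")
        with pytest.raises(CapacityError):
            absorption_time_lumped(make_cycle(7), "bd", exact=True)


class TestLumpability:
    def test_full_equals_lumped_all_connected_n4(self):
        x0 = maximal_diversity(4)
        for g in enumerate_connected_graphs(4):
            for rule in ("bd", "db"):
                f = absorption_time_full(g, rule, x0).expected_time
                l = absorption_time_lumped(g, rule).expected_time
                assert f == pytest.approx(l, rel=REL)

    def test_full_equals_lumped_random_digraphs(self):
        rng = np.random.default_rng(20250925)
        x0 = maximal_diversity(4)
        for _ in range(50):
            g = random_strongly_connected_digraph(4, 0.5, rng)
            for rule in ("bd", "db"):
                f = absorption_time_full(g, rule, x0).expected_time
                l = absorption_time_lumped(g, rule).expected_time
                assert f == pytest.approx(l, rel=REL)


class TestPartitionStates:
    @pytest.mark.parametrize("N,expect", [(1, 1), (3, 5), (8, 4140)])
    def test_bell_numbers(self, N, expect):
        assert partition_state_count(N) == expect

    @pytest.mark.parametrize("N", range(1, 9))
    def test_bell_matches_enumerated_states(self, N):
        assert len(restricted_growth_strings(N)) == partition_state_count(N)

    def test_canonical_partition_relabels_by_first_appearance(self):
        assert canonical_partition([5, 5, 2, 5, 9]) == (0, 0, 1, 0, 2)


class TestFixation:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_star_centre_bd(self, n):
        p = fixation_probability_two_type(make_star(n + 1), "bd", [0])
        assert p == pytest.approx(1 / (1 + n * n), rel=REL)

    @pytest.mark.parametrize("N", [3, 5, 8, 10])
    def test_neutral_symmetry_on_complete(self, N):
        g = make_complete(N, self_loops=False)
        assert fixation_probability_two_type(g, "bd", [1]) == pytest.approx(1 / N, rel=1e-8)

    def test_full_set_fixes(self):
        g = make_star(4)
        assert fixation_probability_two_type(g, "db", range(4)) == 1.0

    @pytest.mark.parametrize("rule", ["bd", "db"])
    def test_singleton_probabilities_sum_to_one(self, rule):
        for g in (make_double_star(6), make_star(8), make_path(5)):
            s = sum(
                fixation_probability_two_type(g, rule, [v]) for v in range(g.n_vertices)
            )
            assert s == pytest.approx(1.0, rel=1e-8)

    def test_capacity(self):
        with pytest.raises(CapacityError):
            fixation_probability_two_type(make_cycle(15), "bd", [0])
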