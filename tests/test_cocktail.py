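"""Cocktail search tests, anchored by an independent set-cover oracle.

The oracle enumerates every subset of phages as frozensets of host labels
and returns the minimum cardinality achieving union coverage — no bitmask
machinery shared with the implementation under test.
"""

from itertools import chain, combinations

import numpy as np
import pytest

from conftest import matrix_from_host_sets, random_binary_matrix
from phagenet.cocktail import compare_methods, exhaustive_cocktail, heuristic_cocktail
from phagenet.io import HostRangeMatrix
from phagenet.network import build_pbin


def brute_force_mcs(matrix):
    """Minimum number of phages covering every susceptible strain."""
    host_sets = {
        p: frozenset(
            matrix.bacteria_ids[i] for i in np.nonzero(matrix.binary[:, j])[0]
        )
        for j, p in enumerate(matrix.phage_ids)
    }
    susceptible = frozenset(chain.from_iterable(host_sets.values()))
    if not susceptible:
        return 0
    phages = [p for p, hs in host_sets.items() if hs]
    best = len(phages)
    for k in range(1, len(phages) + 1):
        for combo in combinations(phages, k):
            if frozenset(chain.from_iterable(host_sets[p] for p in combo)) == susceptible:
                return k
    return best


def nested_matrix_5x4():
    # totally ordered host sets: p1 ⊇ p2 ⊇ p3 ⊇ p4
    return matrix_from_host_sets([[0, 1, 2, 3, 4], [0, 1, 2], [0, 1], [0]], 5)


class TestHeuristic:
    def test_generalist_alone_suffices(self):
        m = matrix_from_host_sets([[0, 1, 2, 3, 4], [0], [1], [2]], 5)
        c = heuristic_cocktail(build_pbin(m))
        assert c.phages == ("p1",)
        assert c.complete and len(c.covered_bacteria) == 5

    def test_identity_selects_all_in_stage_one(self, identity_matrix):
        c = heuristic_cocktail(build_pbin(identity_matrix(3)))
        assert sorted(c.phages) == ["p1", "p2", "p3"]

    def test_worked_matrix_greedy_trace(self, worked_pbin):
        # no unique lysers; greedy adds A (highest EI), then B (adds b5),
        # skips C only after... C still adds b6, so {A, B, C}
        c = heuristic_cocktail(worked_pbin)
        assert c.phages == ("A", "B", "C")
        assert c.complete

    def test_unique_lyser_is_mandatory(self):
        # b4 is lysed only by p3, which otherwise has the lowest EI
        m = matrix_from_host_sets([[0, 1, 2], [0, 1], [3]], 4)
        c = heuristic_cocktail(build_pbin(m))
        assert "p3" in c.phages

    def test_all_resistant_network_yields_empty_cocktail(self):
        m = HostRangeMatrix(("b1", "b2"), ("p1", "p2"), np.zeros((2, 2)))
        c = heuristic_cocktail(build_pbin(m))
        assert c.phages == () and c.complete

    def test_skips_phage_adding_nothing(self, worked_pbin):
        # D = {b5, b6} is fully covered once B and C are in
        assert "D" not in heuristic_cocktail(worked_pbin).phages


class TestExhaustive:
    def test_worked_matrix_mcs_two(self, worked_pbin):
        c = exhaustive_cocktail(worked_pbin)
        assert c.size == 2 and c.complete
        assert c.per_size_trace == (4, 6)
        # {B, C} is an equally optimal cover of the same size
        assert len(c.covered_bacteria) == 6

    def test_identity_mcs_equals_n(self, identity_matrix):
        for n in (2, 4, 6):
            c = exhaustive_cocktail(build_pbin(identity_matrix(n)))
            assert c.size == n and c.complete

    def test_nested_matrix_mcs_one(self):
        m = nested_matrix_5x4()
        assert brute_force_mcs(m) == 1
        c = exhaustive_cocktail(build_pbin(m))
        assert c.size == 1 and c.phages == ("p1",)

    def test_trace_is_nondecreasing(self, worked_pbin):
        trace = exhaustive_cocktail(worked_pbin).per_size_trace
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_cap_returns_best_incomplete(self, identity_matrix):
        c = exhaustive_cocktail(build_pbin(identity_matrix(5)), max_size=3)
        assert c.size == 3 and not c.complete
        assert len(c.covered_bacteria) == 3

    def test_max_size_below_one_rejected(self, worked_pbin):
        with pytest.raises(ValueError):
            exhaustive_cocktail(worked_pbin, max_size=0)

    def test_inert_phages_never_selected(self):
        m = matrix_from_host_sets([[0, 1], [], [2]], 3)
        c = exhaustive_cocktail(build_pbin(m))
        assert "p2" not in c.phages and c.complete


class TestOracleEquivalence:
    def test_random_matrices_match_brute_force(self):
        """Exhaustive MCS equals an independent set-cover oracle and the
        greedy is never smaller, over a seeded sweep of random networks."""
        rng = np.random.default_rng(2022)
        n_checked = 0
        for fill in (0.1, 0.2, 0.3, 0.5, 0.7, 0.9):
            for _ in range(40):
                m = random_binary_matrix(
                    rng, int(rng.integers(1, 9)), int(rng.integers(1, 9)), fill
                )
                pbin = build_pbin(m)
                expected = brute_force_mcs(m)
                exh = exhaustive_cocktail(pbin)
                heur = heuristic_cocktail(pbin)
                assert exh.size == expected
                assert exh.complete
                assert heur.size >= exh.size
                n_checked += 1
        assert n_checked == 240

    def test_pruned_enumeration_is_exact(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            m = random_binary_matrix(rng, 7, 7, float(rng.uniform(0.1, 0.9)))
            pbin = build_pbin(m)
            plain = exhaustive_cocktail(pbin, prune=False)
            pruned = exhaustive_cocktail(pbin, prune=True)
            assert plain.phages == pruned.phages
            assert plain.per_size_trace == pruned.per_size_trace


class TestStructuralProperties:
    def test_mcs_invariant_under_permutation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_binary_matrix(rng, 6, 6, 0.4)
            perm_b = rng.permutation(m.n_bacteria)
            perm_p = rng.permutation(m.n_phages)
            permuted = HostRangeMatrix(
                tuple(m.bacteria_ids[i] for i in perm_b),
                tuple(m.phage_ids[j] for j in perm_p),
                m.values[np.ix_(perm_b, perm_p)],
            )
            assert (
                exhaustive_cocktail(build_pbin(m)).size
                == exhaustive_cocktail(build_pbin(permuted)).size
            )

    def test_extra_edge_to_susceptible_strain_never_raises_mcs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = random_binary_matrix(rng, 6, 5, 0.35)
            pbin = build_pbin(m)
            before = exhaustive_cocktail(pbin).size
            susceptible_rows = np.nonzero(pbin.in_degree >= 1)[0]
            empty = [
                (i, j)
                for i in susceptible_rows
                for j in range(m.n_phages)
                if m.binary[i, j] == 0
            ]
            if not empty:
                continue
            i, j = empty[rng.integers(len(empty))]
            values = m.values.copy()
            values[i, j] = 1.0
            augmented = HostRangeMatrix(m.bacteria_ids, m.phage_ids, values)
            assert exhaustive_cocktail(build_pbin(augmented)).size <= before

    def test_complete_cocktail_covers_union_of_host_sets(self, worked_pbin):
        for cocktail in (
            heuristic_cocktail(worked_pbin),
            exhaustive_cocktail(worked_pbin),
        ):
            assert cocktail.covered_bacteria == frozenset(
                worked_pbin.susceptible_bacteria
            )


class TestCompareMethods:
    def test_worked_matrix_gap_one(self, worked_pbin):
        report = compare_methods(worked_pbin)
        assert (report["heuristic_size"], report["exhaustive_size"]) == (3, 2)
        assert report["size_gap"] == 1

    def test_nested_matrix_gap_zero(self):
        pbin = build_pbin(nested_matrix_5x4())
        report = compare_methods(pbin)
        assert report["heuristic_size"] == report["exhaustive_size"] == 1
        assert report["size_gap"] == 0

    def test_all_zero_matrix_both_empty(self):
        m = HostRangeMatrix(("b1", "b2"), ("p1", "p2"), np.zeros((2, 2)))
        report = compare_methods(build_pbin(m))
        assert report["heuristic_size"] == report["exhaustive_size"] == 0
        assert report["size_gap"] == 0
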