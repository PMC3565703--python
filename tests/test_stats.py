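"""Group-conserved overlap test: counts, exact and Monte-Carlo p-values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixbridge.errors import NoOverlapError
from helixbridge.families import AlignedFamily, HelixRegion
from helixbridge.stats import (
    GroupConservedSet,
    detect_group_conserved,
    overlap_count,
    overlap_pvalue_exact,
    overlap_pvalue_mc,
    overlap_test,
)


def gset(positions, L=20, family="A", helix="TM1"):
    return GroupConservedSet(family, helix, frozenset(positions), L)


class TestOverlapCount:
    def test_zero_shift(self):
        assert overlap_count(gset({3, 7}), gset({3, 9}), 0) == 1

    def test_positive_shift_displaces_second_family(self):
        # position 5 in A aligns with 3 in B under shift +2
        assert overlap_count(gset({5}), gset({3}), 2) == 1

    def test_empty_set_counts_zero(self):
        assert overlap_count(gset(set()), gset({1, 2, 3}), 0) == 0

    def test_no_overlap_errors(self):
        with pytest.raises(NoOverlapError):
            overlap_count(gset({1}, L=5), gset({1}, L=5), 10)

    @settings(deadline=None, max_examples=50)
    @given(
        st.sets(st.integers(1, 15), max_size=6),
        st.sets(st.integers(1, 15), max_size=6),
        st.integers(-10, 10),
    )
    def test_swap_antisymmetry(self, a, b, shift):
        """count(a, b, s) == count(b, a, -s) whenever windows overlap."""
        try:
            forward = overlap_count(gset(a, L=15), gset(b, L=15), shift)
        except NoOverlapError:
            return
        assert forward == overlap_count(gset(b, L=15), gset(a, L=15), -shift)


def enumerate_exact(L, n_a, n_b, k):
    """Exhaustive-enumeration oracle for P(overlap >= k)."""
    fixed = set(range(n_b))
    total = hits = 0
    for placed in itertools.combinations(range(L), n_a):
        total += 1
        if len(fixed & set(placed)) >= k:
            hits += 1
    return hits / total


class TestExactPValue:
    def test_reference_configuration_is_one_in_fortyfive(self):
        assert overlap_pvalue_exact(10, 2, 2, 2) == pytest.approx(1 / 45)

    def test_upper_tail_at_zero_is_one(self):
        assert overlap_pvalue_exact(17, 4, 3, 0) == 1.0

    def test_small_case_five_sixths(self):
        assert overlap_pvalue_exact(4, 2, 2, 1) == pytest.approx(5 / 6)

    @pytest.mark.parametrize(
        "L,n_a,n_b,k",
        [(10, 2, 2, 2), (8, 3, 4, 1), (12, 5, 3, 2), (6, 2, 4, 0), (9, 4, 4, 3)],
    )
    def test_matches_exhaustive_enumeration(self, L, n_a, n_b, k):
        assert overlap_pvalue_exact(L, n_a, n_b, k) == pytest.approx(
            enumerate_exact(L, n_a, n_b, k)
        )

    def test_monotone_nonincreasing_in_k(self):
        values = [overlap_pvalue_exact(15, 5, 6, k) for k in range(6)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_impossible_k_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue_exact(10, 2, 2, 3)
        with pytest.raises(ValueError):
            overlap_pvalue_exact(5, 6, 2, 1)


class TestMonteCarlo:
    def test_converges_to_exact_oracle(self):
        a, b = gset({2, 7}, L=10), gset({2, 7}, L=10)
        p_mc = overlap_pvalue_mc(a, b, 0, replicates=10_000, seed=11)
        p = 1 / 45
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(p_mc - p) <= 3 * se + 2 / 10_001  # slack for the +1 correction

    def test_deterministic_for_fixed_seed(self):
        a, b = gset({1, 5, 9}, L=12), gset({3, 5, 11}, L=12)
        kwargs = dict(replicates=500, seed=99)
        assert overlap_pvalue_mc(a, b, 0, **kwargs) == overlap_pvalue_mc(
            a, b, 0, **kwargs
        )

    def test_observed_zero_gives_p_one(self):
        a, b = gset(set(), L=10), gset({1, 2}, L=10)
        assert overlap_pvalue_mc(a, b, 0, replicates=200, seed=1) == 1.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            overlap_pvalue_mc(gset({1}), gset({1}), 0, replicates=50)

    def test_randomization_directions_can_be_chosen(self):
        a, b = gset({1, 2, 3}, L=10), gset({1, 2}, L=10)
        pa = overlap_pvalue_mc(a, b, 0, replicates=2000, seed=3, randomize="a")
        pb = overlap_pvalue_mc(a, b, 0, replicates=2000, seed=3, randomize="b")
        exact = overlap_pvalue_exact(10, 3, 2, 2)
        for p in (pa, pb):
            assert abs(p - exact) < 0.05

    def test_mc_exact_agreement_over_random_configs(self):
        """|p_mc - p_exact| <= 3 binomial SE across random configurations."""
        rng = np.random.default_rng(2024)
        replicates = 2000
        for _ in range(10):
            L = int(rng.integers(6, 20))
            n_a = int(rng.integers(1, min(6, L)))
            n_b = int(rng.integers(1, min(6, L)))
            a = gset(rng.choice(L, n_a, replace=False) + 1, L=L)
            b = gset(rng.choice(L, n_b, replace=False) + 1, L=L)
            k = overlap_count(a, b, 0)
            p = overlap_pvalue_exact(L, n_a, n_b, k)
            p_mc = overlap_pvalue_mc(
                a, b, 0, replicates=replicates, seed=int(rng.integers(2**31))
            )
            se = math.sqrt(max(p * (1 - p), 1e-12) / replicates)
            assert abs(p_mc - p) <= 3 * se + 2 / (replicates + 1)


class TestOverlapTest:
    def test_reported_p_is_max_of_directions(self):
        t = overlap_test(gset({2, 7}, L=10), gset({2, 7}, L=10), 0,
                         replicates=2000, seed=5)
        assert t.observed == 2
        assert t.reported_p == max(t.p_mc_randomize_a, t.p_mc_randomize_b)
        assert 0 <= t.reported_p <= 1
        assert t.p_exact == pytest.approx(1 / 45)

    def test_shift_restricts_to_overlap_window(self):
        a = gset({1, 10}, L=10)
        b = gset({5}, L=10)
        t = overlap_test(a, b, 5, replicates=200, seed=0)
        assert t.overlap_length == 5  # A positions 6..10 vs B 1..5
        assert t.observed == 1  # A 10 pairs with B 5


class TestDetectGroupConserved:
    def _family(self, columns):
        seqs = ["".join(col[j] for col in columns) for j in range(len(columns[0]))]
        return AlignedFamily(
            "fam", [f"s{j}" for j in range(len(columns[0]))], seqs,
            regions={"TM1": HelixRegion("TM1", 1, len(columns))},
        )

    def test_small_group_conservation_detected(self):
        # col1: 60% A + 40% G -> small-group frequency 1.0
        fam = self._family(["AAAGG", "LKEWT", "AGSCA"])
        out = detect_group_conserved(fam, "TM1", min_group_freq=0.9)
        assert out.positions == frozenset({1, 3})

    def test_split_across_groups_excluded(self):
        fam = self._family(["AALLL", "AAAAA", "AAAAA"])
        out = detect_group_conserved(fam, "TM1", min_group_freq=0.9)
        assert 1 not in out.positions

    def test_zero_threshold_includes_every_column(self):
        fam = self._family(["ALWKE", "GITYD", "SVHRC"])
        out = detect_group_conserved(fam, "TM1", min_group_freq=0.0)
        assert out.positions == frozenset({1, 2, 3})

    def test_empty_groups_rejected(self):
        fam = self._family(["AAA", "AAA", "AAA"])
        with pytest.raises(ValueError):
            detect_group_conserved(fam, "TM1", residue_groups={})
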