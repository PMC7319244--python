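"""Pairwise differentiation indices: N_L, N_A, Bruvo's D, strata, clones."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igvar.distances import (
    all_pairwise,
    bruvo_distance,
    bruvo_distance_bruteforce,
    clone_match,
    comparable_loci,
    compare_mlgs,
    intracolonial_pairs,
    mutation_steps,
    n_different_alleles,
)
from igvar.model import LocusDef, MultilocusGenotype, Nubbin, Panel
from igvar.simulate import CloneSpec, SimulationConfig, generate_dataset

from helpers import edited_mlg, make_colony, make_panel, uniform_mlg


def mlg_of(panel, *pairs):
    return MultilocusGenotype(panel, tuple(pairs))


class TestComparableLoci:
    def test_complete_missing_and_disjoint_support(self, panel12, base_mlg):
        assert comparable_loci(base_mlg, base_mlg) == 12
        holey = edited_mlg(base_mlg, [(i, None) for i in range(3)])
        assert comparable_loci(holey, base_mlg) == 9
        left = edited_mlg(base_mlg, [(i, None) for i in range(6)])
        right = edited_mlg(base_mlg, [(i, None) for i in range(6, 12)])
        assert comparable_loci(left, right) == 0


class TestNDifferentAlleles:
    @pytest.mark.parametrize(
        "ga,gb,expected",
        [
            ((100, 104), (100, 104), 0),
            ((100, 104), (100, 108), 1),
            ((100, 104), (108, 112), 2),
            ((100, 100), (100, 104), 1),  # shared homozygote vs heterozygote
            ((100, 100), (104, 104), 2),
            ((100, 104), (104, 104), 1),
        ],
    )
    def test_single_locus_multiset_oracle(self, ga, gb, expected):
        panel = make_panel(1)
        assert n_different_alleles(mlg_of(panel, ga), mlg_of(panel, gb)) == expected

    def test_upper_bound_over_disjoint_loci(self):
        panel = make_panel(12)
        a = MultilocusGenotype(panel, tuple((100, 104) for _ in range(12)))
        b = MultilocusGenotype(panel, tuple((108, 112) for _ in range(12)))
        assert n_different_alleles(a, b) == 24  # 2 * N_L upper bound

    def test_no_comparable_locus_is_non_evaluable(self, base_mlg):
        left = edited_mlg(base_mlg, [(i, None) for i in range(6)])
        right = edited_mlg(base_mlg, [(i, None) for i in range(6, 12)])
        assert n_different_alleles(left, right) is None
        n1 = Nubbin("a", "c", left)
        n2 = Nubbin("b", "c", right)
        cmp = compare_mlgs(n1, n2)
        assert not cmp.evaluable and cmp.N_L == 0


class TestMutationSteps:
    def test_repeat_count_definition(self):
        assert mutation_steps(100, 100) == 0
        assert mutation_steps(10, 13) == 3

    def test_bp_policy_table(self):
        locus = LocusDef("A", motif_length=2, encoding="bp_size")
        assert mutation_steps(100, 104, locus) == 2
        with pytest.raises(ValueError):
            mutation_steps(100, 103, locus, policy="strict")
        with pytest.warns(UserWarning):
            assert mutation_steps(100, 103, locus, policy="tolerant") == 2


class TestBruvo:
    def test_minimum_pairing_example(self):
        """(100,104) vs (102,104) on motif 2: bijection costs are
        {0.5, 1.25}; the cheaper one gives D = 0.5 / 2 = 0.25."""
        panel = make_panel(1)
        a = mlg_of(panel, (50, 52))
        b = mlg_of(panel, (51, 52))
        assert bruvo_distance(a, b) == pytest.approx(0.25)

    def test_normalises_by_comparable_loci_not_panel(self, base_mlg):
        varied = edited_mlg(base_mlg, [(0, 0, 2)])
        full = bruvo_distance(base_mlg, varied)
        masked = edited_mlg(varied, [(i, None) for i in range(6, 12)])
        half = bruvo_distance(base_mlg, masked)
        assert full == pytest.approx(0.75 / 24)
        assert half == pytest.approx(0.75 / 12)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.tuples(st.integers(5, 20), st.integers(5, 20)),
                st.tuples(st.integers(5, 20), st.integers(5, 20)),
            ),
            min_size=1,
            max_size=3,
        )
    )
    def test_min_pairing_equals_bruteforce_bijection_minimum(self, loci):
        panel = make_panel(len(loci))
        a = MultilocusGenotype(panel, tuple(g[0] for g in loci))
        b = MultilocusGenotype(panel, tuple(g[1] for g in loci))
        assert bruvo_distance(a, b) == pytest.approx(bruvo_distance_bruteforce(a, b))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.tuples(st.integers(5, 30), st.integers(5, 30)),
                st.tuples(st.integers(5, 30), st.integers(5, 30)),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_symmetry_bounds_and_zero_equivalence(self, loci):
        panel = make_panel(len(loci))
        a = MultilocusGenotype(panel, tuple(g[0] for g in loci))
        b = MultilocusGenotype(panel, tuple(g[1] for g in loci))
        d_ab, d_ba = bruvo_distance(a, b), bruvo_distance(b, a)
        na_ab, na_ba = n_different_alleles(a, b), n_different_alleles(b, a)
        assert d_ab == pytest.approx(d_ba)
        assert na_ab == na_ba
        assert 0 <= d_ab <= 1 and 0 <= na_ab <= 2 * len(loci)
        assert (na_ab == 0) == (d_ab == 0)
        identical = all(sorted(x) == sorted(y) for x, y in loci)
        assert (na_ab == 0) == identical

    def test_monotone_in_step_size_and_extra_allele(self, base_mlg):
        d_prev = 0.0
        for steps in range(1, 8):
            d = bruvo_distance(base_mlg, edited_mlg(base_mlg, [(0, 0, steps)]))
            assert d > d_prev
            d_prev = d
        one = edited_mlg(base_mlg, [(0, 0, 2)])
        two = edited_mlg(base_mlg, [(0, 0, 2), (1, 0, 2)])
        assert bruvo_distance(base_mlg, two) > bruvo_distance(base_mlg, one)
        assert n_different_alleles(base_mlg, two) > n_different_alleles(base_mlg, one)

    def test_bound_sharpness_large_steps(self):
        panel = make_panel(2)
        a = mlg_of(panel, (10, 10), (10, 10))
        b = mlg_of(panel, (60, 60), (60, 60))
        assert bruvo_distance(a, b) > 0.999

    def test_restriction_never_increases_NA(self, base_mlg, panel12):
        varied = edited_mlg(base_mlg, [(0, 0, 2), (5, 1, 1)])
        sub = panel12.without(["L01"])
        assert n_different_alleles(
            base_mlg.restrict(sub), varied.restrict(sub)
        ) <= n_different_alleles(base_mlg, varied)


class TestAllPairwise:
    def _nubbins(self, panel, groups_sizes):
        nubbins, groups = [], {}
        k = 0
        for group, size in groups_sizes:
            for _ in range(size):
                nid = f"n{k}"
                nubbins.append(Nubbin(nid, f"c{k}", uniform_mlg(panel, (10 + k, 12 + k))))
                groups[nid] = group
                k += 1
        return nubbins, groups

    def test_study_stratified_counts(self, panel12):
        """116 complete MLGs in clusters 99/17 -> 6,670 pairs =
        4,987 intracluster + 1,683 intercluster."""
        nubbins, groups = self._nubbins(
            panel12, [("SSH05c-1", 99), ("SSH05c-2", 17)]
        )
        pairs = all_pairwise(nubbins, groups)
        assert len(pairs) == 6670
        strata = [p.stratum for p in pairs]
        assert strata.count("intracluster") == 4987
        assert strata.count("intercluster") == 1683

    def test_inter_ssh_counts(self, panel12):
        """Adding a 4-member second SSH to 99+17 -> 464 inter-SSH pairs."""
        nubbins, groups = self._nubbins(
            panel12, [("SSH05c-1", 99), ("SSH05c-2", 17), ("SSH13a", 4)]
        )
        pairs = all_pairwise(nubbins, groups)
        assert sum(p.stratum == "inter_SSH" for p in pairs) == 464

    def test_two_nubbins_one_pair_and_incomplete_excluded(self, panel12, base_mlg):
        incomplete = edited_mlg(base_mlg, [(0, None)])
        nubbins = [
            Nubbin("a", "c1", base_mlg),
            Nubbin("b", "c2", base_mlg),
            Nubbin("x", "c3", incomplete),
        ]
        groups = {"a": "G", "b": "G", "x": "G"}
        assert len(all_pairwise(nubbins, groups)) == 1
        with pytest.warns(UserWarning):
            assert all_pairwise(nubbins[:1], groups) == []


class TestIntracolonialPairs:
    def test_three_identical_nubbins(self, panel12, base_mlg):
        colony = make_colony("c1", [base_mlg] * 3)
        pairs = intracolonial_pairs(colony)
        assert len(pairs) == 3
        assert all((p.N_L, p.N_A, p.D) == (12, 0, 0.0) for p in pairs)

    def test_disjoint_nubbins_flagged_non_evaluable(self, panel12, base_mlg):
        left = edited_mlg(base_mlg, [(i, None) for i in range(6)])
        right = edited_mlg(base_mlg, [(i, None) for i in range(6, 12)])
        pairs = intracolonial_pairs(make_colony("c1", [left, right]))
        assert len(pairs) == 1 and not pairs[0].evaluable


class TestCloneMatch:
    def test_exact_identity_grouping(self, panel12, base_mlg):
        mutated = edited_mlg(base_mlg, [(0, 0, 1)])
        incomplete = edited_mlg(base_mlg, [(0, None)])
        nubbins = [
            Nubbin("a", "c1", base_mlg),
            Nubbin("b", "c2", base_mlg),
            Nubbin("c", "c3", mutated),
            Nubbin("d", "c4", incomplete),
        ]
        groups = clone_match(nubbins)
        assert [len(g) for g in groups] == [2, 1]
        assert {n.id for n in groups[0]} == {"a", "b"}

    def test_planted_dominant_clone_recovered(self):
        """A genotype planted at 81% founder frequency dominates the
        clonal partition at roughly that fraction."""
        cfg = SimulationConfig(
            colonies_per_site=40,
            dropout=0.0,
            mosaic_rate=0.0,
            chimera_rate=0.0,
            clone_spec=CloneSpec(frequency=0.81),
            seed=9,
        )
        ds, truth = generate_dataset(cfg)
        groups = clone_match(ds.nubbins)
        planted = sum(t.is_dominant_clone for t in truth.colonies.values())
        assert len(groups[0]) == 3 * planted
        frac = planted / len(ds.colonies)
        assert abs(frac - 0.81 * 0.85) < 0.1  # clone restricted to cluster 1
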