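"""Colony classification cascade, QC flags, sensitivity, shared MLGs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igvar.classify import (
    CATEGORIES,
    ColonyNotEvaluable,
    classification_frame,
    classify_colony,
    classify_dataset,
    count_distinct_mlgs,
    sensitivity_analysis,
    shared_mlg_across_colonies,
)
from igvar.model import Dataset
from igvar.simulate import CloneSpec, SimulationConfig, generate_dataset
from igvar.thresholds import ThresholdSet

from helpers import edited_mlg, make_colony, make_panel, uniform_mlg

T = ThresholdSet(N_L_min=9, N_A_chi_mos=4, D_chi_mos=0.12)


def colony_of(mlgs, cid="c1"):
    return make_colony(cid, mlgs)


class TestCascade:
    def test_identical_complete_nubbins_invariable(self, base_mlg):
        c = classify_colony(colony_of([base_mlg] * 3), T)
        assert c.category == "invariable"
        assert c.n_distinct_mlgs == 1 and not c.also_mosaic

    def test_low_NL_zero_difference_possibly_variable(self, base_mlg):
        holed = edited_mlg(base_mlg, [(i, None) for i in range(5)])  # N_L = 7
        c = classify_colony(colony_of([base_mlg, base_mlg, holed]), T)
        assert c.category == "possibly_variable"

    def test_discordant_pair_is_mosaic_by_AND_rule(self, base_mlg):
        """N_A = 4 with D = 0.15 exceeds only the D cutoff: mosaic."""
        varied = edited_mlg(base_mlg, [(i, 0, 5) for i in range(4)])
        pair_d = 4 * (1 - 2**-5) / 24
        assert pair_d == pytest.approx(0.1614583)
        c = classify_colony(colony_of([base_mlg, base_mlg, varied]), T)
        assert c.category == "mosaic"

    def test_equality_at_thresholds_is_mosaic(self, base_mlg):
        """A pair at exactly N_A = 4 and exactly D = 0.12 stays mosaic."""
        # N_A = 4, D just above: still mosaic because N_A not > 4
        varied_na4 = edited_mlg(base_mlg, [(i, 0, 10) for i in range(4)])
        c = classify_colony(colony_of([base_mlg, varied_na4]), T)
        assert c.pairs[0].N_A == 4 and c.pairs[0].D > 0.12
        assert c.category == "mosaic"
        # N_A = 5 > 4 but D exactly at the threshold value: mosaic
        t_exact = ThresholdSet(9, 4, 5 * (1 - 2**-1) / 24)
        varied5 = edited_mlg(base_mlg, [(i, 0, 1) for i in range(5)])
        c2 = classify_colony(colony_of([base_mlg, varied5]), t_exact)
        assert c2.pairs[0].D == pytest.approx(t_exact.D_chi_mos)
        assert c2.category == "mosaic"

    def test_chimeric_with_also_mosaic_third_nubbin(self, base_mlg):
        """Two strongly differentiated genets plus a slightly mutated copy:
        chimeric, flagged also-mosaic."""
        genet2 = edited_mlg(base_mlg, [(i, 0, 3) for i in range(11)])
        mutated = edited_mlg(base_mlg, [(0, 1, 1)])
        c = classify_colony(colony_of([base_mlg, genet2, mutated]), T)
        assert c.category == "chimeric"
        assert c.also_mosaic
        assert c.n_distinct_mlgs == 3
        pure = classify_colony(colony_of([base_mlg, base_mlg, genet2]), T)
        assert pure.category == "chimeric" and not pure.also_mosaic

    def test_variable_low_NL_possibly_chimeric(self, base_mlg):
        varied = edited_mlg(base_mlg, [(0, 0, 1)])
        holed = edited_mlg(varied, [(i, None) for i in range(1, 6)])  # N_L = 7
        c = classify_colony(colony_of([base_mlg, base_mlg, holed]), T)
        assert c.category == "possibly_chimeric"

    def test_single_locus_differences_raise_qc_flag(self, base_mlg):
        two_on_one = edited_mlg(base_mlg, [(0, 0, -1), (0, 1, 1)])
        c = classify_colony(colony_of([base_mlg, base_mlg, two_on_one]), T)
        assert c.category == "mosaic" and c.qc_single_locus_flag
        spread = edited_mlg(base_mlg, [(0, 0, 1), (1, 0, 1)])
        c2 = classify_colony(colony_of([base_mlg, base_mlg, spread]), T)
        assert not c2.qc_single_locus_flag

    def test_no_evaluable_pair_excluded(self, base_mlg):
        left = edited_mlg(base_mlg, [(i, None) for i in range(6)])
        right = edited_mlg(base_mlg, [(i, None) for i in range(6, 12)])
        with pytest.raises(ColonyNotEvaluable):
            classify_colony(colony_of([left, right]), T)
        panel = base_mlg.panel
        ds = Dataset(
            panel,
            [colony_of([base_mlg] * 2, "ok"), colony_of([left, right], "bad")],
        )
        cls, excluded = classify_dataset(ds, T)
        assert [c.colony_id for c in cls] == ["ok"] and excluded == ["bad"]

    def test_classification_invariant_to_nubbin_order(self, base_mlg):
        genet2 = edited_mlg(base_mlg, [(i, 0, 3) for i in range(11)])
        mutated = edited_mlg(base_mlg, [(0, 1, 1)])
        mlgs = [base_mlg, genet2, mutated]
        cats = set()
        for order in ([0, 1, 2], [2, 1, 0], [1, 0, 2]):
            c = classify_colony(colony_of([mlgs[i] for i in order]), T)
            cats.add((c.category, c.also_mosaic, c.n_distinct_mlgs))
        assert len(cats) == 1


class TestDistinctMlgs:
    def test_counts(self, base_mlg):
        mutated = edited_mlg(base_mlg, [(0, 0, 1)])
        other = edited_mlg(base_mlg, [(1, 0, 2)])
        assert count_distinct_mlgs(colony_of([base_mlg] * 3)) == 1
        assert count_distinct_mlgs(colony_of([base_mlg, base_mlg, mutated])) == 2
        assert count_distinct_mlgs(colony_of([base_mlg, mutated, other])) == 3


class TestPartitionProperty:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_categories_partition_retained_colonies(self, seed):
        cfg = SimulationConfig(colonies_per_site=10, seed=seed)
        ds, _ = generate_dataset(cfg)
        cls, excluded = classify_dataset(ds, T)
        assert len(cls) + len(excluded) == len(ds.colonies)
        counts = {cat: sum(c.category == cat for c in cls) for cat in CATEGORIES}
        assert sum(counts.values()) == len(cls)
        frame = classification_frame(cls)
        assert set(frame["category"]) <= set(CATEGORIES)


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(colonies_per_site=30, dropout=0.0, seed=21)
    return generate_dataset(cfg)


class TestSensitivity:
    def test_identity_perturbation_is_baseline(self, sim):
        ds, _ = sim
        cls, _ = classify_dataset(ds, T)
        baseline = sum(c.category == "chimeric" for c in cls)
        table = sensitivity_analysis(ds, T, na_deltas=(0,))
        assert table.loc[0, "n_chimeric"] == baseline

    def test_chimera_count_monotone_in_thresholds(self, sim):
        ds, _ = sim
        table = sensitivity_analysis(
            ds, T, na_deltas=range(-2, 9), d_alternatives=(0.05, 0.083, 0.146, 0.3)
        )
        by_na = table[table["perturbation"].str.startswith("N_A")]
        assert (np.diff(by_na["n_chimeric"]) <= 0).all()
        by_d = table[~table["perturbation"].str.startswith("N_A")].sort_values(
            "D_chi_mos"
        )
        assert (np.diff(by_d["n_chimeric"]) <= 0).all()

    def test_raising_NA_threshold_absorbs_planted_chimeras(self):
        """Fusions planted just above N_A = 6 disappear from the chimera
        class once the cutoff is raised to meet them."""
        cfg = SimulationConfig(
            colonies_per_site=20,
            dropout=0.0,
            chimera_rate=1.0,
            mosaic_rate=0.0,
            chimera_min_NA=6,
            seed=13,
        )
        ds, truth = generate_dataset(cfg)
        max_na = max(t.fusion_NA for t in truth.colonies.values())
        table = sensitivity_analysis(
            ds, ThresholdSet(9, 6, 0.12), na_deltas=(0, max_na - 6)
        )
        assert table.loc[0, "n_chimeric"] == len(ds.colonies)
        assert table.loc[1, "n_chimeric"] == 0

    def test_low_recruit_style_threshold_inflates_chimerism(self):
        """With the cutoff dropped to N_A >= 2 (a recruit-scale rule),
        ordinary two-allele mosaics in an adult-style dataset are
        mislabelled chimeric and the chimera fraction inflates."""
        cfg = SimulationConfig(
            colonies_per_site=30,
            dropout=0.0,
            mosaic_rate=0.5,
            chimera_rate=0.05,
            mosaic_n_allele_probs=(0.0, 1.0),  # always 2 mutated alleles
            seed=29,
        )
        ds, truth = generate_dataset(cfg)
        strict = sensitivity_analysis(ds, T, na_deltas=(0,))
        lax = sensitivity_analysis(ds, ThresholdSet(9, 1, 0.01), na_deltas=(0,))
        true_chi = sum(t.category == "chimeric" for t in truth.colonies.values())
        assert strict.loc[0, "n_chimeric"] == true_chi
        assert lax.loc[0, "n_chimeric"] >= true_chi + sum(
            t.category == "mosaic" for t in truth.colonies.values()
        )

    def test_invalid_perturbation_skipped(self, sim):
        ds, _ = sim
        table = sensitivity_analysis(ds, ThresholdSet(9, 1, 0.12), na_deltas=(-1, 0))
        assert len(table) == 1


class TestSharedMlgs:
    def test_no_shared_mlgs_empty_table(self, base_mlg):
        panel = base_mlg.panel
        other = edited_mlg(base_mlg, [(i, 0, 4) for i in range(12)])
        mut_a = edited_mlg(base_mlg, [(0, 0, 1)])
        mut_b = edited_mlg(other, [(1, 0, 1)])
        ds = Dataset(
            panel,
            [
                make_colony("c1", [base_mlg, base_mlg, mut_a]),
                make_colony("c2", [other, other, mut_b]),
            ],
        )
        cls, _ = classify_dataset(ds, T)
        assert shared_mlg_across_colonies(ds, cls).empty

    def test_planted_clone_shared_among_chimeras(self, base_mlg):
        panel = base_mlg.panel
        genet2 = edited_mlg(base_mlg, [(i, 0, 3) for i in range(11)])
        genet3 = edited_mlg(base_mlg, [(i, 1, -3) for i in range(11)])
        ds = Dataset(
            panel,
            [
                make_colony("c1", [base_mlg, base_mlg, genet2]),
                make_colony("c2", [base_mlg, genet3, genet3]),
            ],
        )
        cls, _ = classify_dataset(ds, T)
        assert all(c.category == "chimeric" for c in cls)
        table = shared_mlg_across_colonies(ds, cls)
        assert len(table) == 1
        assert table.loc[0, "colonies"] == "c1,c2"
        assert table.loc[0, "categories"] == "chimeric,chimeric"

    def test_dominant_clone_row_spans_many_colonies(self):
        cfg = SimulationConfig(
            colonies_per_site=20,
            dropout=0.0,
            mosaic_rate=0.6,
            chimera_rate=0.2,
            clone_spec=CloneSpec(frequency=0.8),
            seed=31,
        )
        ds, truth = generate_dataset(cfg)
        cls, _ = classify_dataset(ds, T)
        table = shared_mlg_across_colonies(ds, cls)
        variable_clone_colonies = sum(
            t.is_dominant_clone and t.category != "invariable"
            for t in truth.colonies.values()
        )
        assert not table.empty
        assert table["colonies"].str.split(",").map(len).max() >= min(
            variable_clone_colonies, 2
        )
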