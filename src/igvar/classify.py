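"""Five-way colony classification from intracolonial comparisons.

Decision cascade for one colony, given thresholds
``(N_L_min, N_A_chi_mos, D_chi_mos)``:

1. *variable* iff any evaluable pair has ``N_A >= 1`` and ``D > 0``;
2. non-variable colonies split on the minimum ``N_L`` over evaluable
   pairs: ``invariable`` (all pairs at ``N_L >= N_L_min``) vs
   ``possibly_variable``;
3. variable colonies are ``chimeric`` iff some pair exceeds *both*
   cutoffs strictly — a pair sitting exactly at a cutoff counts as
   mosaic, as does the discordant case where only one index exceeds;
4. non-chimeric variable colonies split on minimum ``N_L``: ``mosaic``
   vs ``possibly_chimeric``;
5. a chimeric colony is flagged ``also_mosaic`` when another pair shows a
   small but non-zero difference (``0 < N_A <= N_A_chi_mos`` or
   ``0 < D <= D_chi_mos``);
6. a variable colony whose differences all sit on a single locus gets a
   QC flag (the wet-lab protocol re-amplifies that locus to rule out
   genotyping error; here it is surfaced as a flag only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .distances import PairwiseComparison, intracolonial_pairs, clone_match
from .model import Colony, Dataset
from .thresholds import ThresholdSet

__all__ = [
    "CATEGORIES",
    "ColonyClassification",
    "ColonyNotEvaluable",
    "classify_colony",
    "classify_dataset",
    "count_distinct_mlgs",
    "sensitivity_analysis",
    "shared_mlg_across_colonies",
    "classification_frame",
]

logger = logging.getLogger(__name__)

#: absolute tolerance absorbing float noise in D-threshold comparisons
D_TOL = 1e-9

CATEGORIES = (
    "invariable",
    "possibly_variable",
    "mosaic",
    "possibly_chimeric",
    "chimeric",
)


class ColonyNotEvaluable(ValueError):
    """Raised when no nubbin pair of a colony shares a typed locus."""


@dataclass
class ColonyClassification:
    colony_id: str
    category: str
    also_mosaic: bool
    n_distinct_mlgs: int
    qc_single_locus_flag: bool
    pairs: list[PairwiseComparison]
    site: Optional[str] = None
    group: Optional[str] = None

    @property
    def variable(self) -> bool:
        return self.category in ("mosaic", "possibly_chimeric", "chimeric")

    @property
    def min_NL(self) -> int:
        return min(p.N_L for p in self.pairs if p.evaluable)

    @property
    def max_NA(self) -> int:
        return max(p.N_A for p in self.pairs if p.evaluable)

    @property
    def max_D(self) -> float:
        return max(p.D for p in self.pairs if p.evaluable)


def _is_chimeric_pair(p: PairwiseComparison, t: ThresholdSet) -> bool:
    return p.N_A > t.N_A_chi_mos and p.D > t.D_chi_mos + D_TOL


def _single_differing_locus(colony: Colony) -> bool:
    """True when every intracolonial difference sits on one locus."""
    differing: set[int] = set()
    nubs = colony.nubbins
    for i in range(len(nubs)):
        for j in range(i + 1, len(nubs)):
            for k, (ga, gb) in enumerate(
                zip(nubs[i].mlg.genotypes, nubs[j].mlg.genotypes)
            ):
                if ga is None or gb is None:
                    continue
                if ga != gb:
                    differing.add(k)
    return len(differing) == 1


def count_distinct_mlgs(
    colony: Colony, pairs: Optional[Sequence[PairwiseComparison]] = None
) -> int:
    """Number of distinct genotypes among the nubbins.

    Nubbins are merged when their pairwise ``N_A = 0`` over comparable
    loci (union-find, so identity can propagate through a shared partner
    when missing data make the relation non-transitive).
    """
    if pairs is None:
        pairs = intracolonial_pairs(colony)
    ids = [n.id for n in colony.nubbins]
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        if p.evaluable and p.N_A == 0:
            parent[find(p.id_a)] = find(p.id_b)
    return len({find(i) for i in ids})


def classify_colony(
    colony: Colony,
    thresholds: ThresholdSet,
    pairs: Optional[Sequence[PairwiseComparison]] = None,
) -> ColonyClassification:
    """Apply the decision cascade to one colony.

    Raises :class:`ColonyNotEvaluable` when no pair shares a typed locus;
    callers exclude such colonies and log them.
    """
    if pairs is None:
        pairs = intracolonial_pairs(colony)
    pairs = list(pairs)
    evaluable = [p for p in pairs if p.evaluable]
    if not evaluable:
        raise ColonyNotEvaluable(
            f"colony {colony.id!r}: no nubbin pair shares a typed locus"
        )
    min_nl = min(p.N_L for p in evaluable)
    variable = any(p.N_A >= 1 and p.D > 0 for p in evaluable)

    if not variable:
        category = "invariable" if min_nl >= thresholds.N_L_min else "possibly_variable"
        also_mosaic = False
    else:
        chimeric = any(_is_chimeric_pair(p, thresholds) for p in evaluable)
        if chimeric:
            category = "chimeric"
            also_mosaic = any(
                (0 < p.N_A <= thresholds.N_A_chi_mos)
                or (0 < p.D <= thresholds.D_chi_mos + D_TOL)
                for p in evaluable
            )
        else:
            category = "mosaic" if min_nl >= thresholds.N_L_min else "possibly_chimeric"
            also_mosaic = False

    qc = variable and _single_differing_locus(colony)
    return ColonyClassification(
        colony_id=colony.id,
        category=category,
        also_mosaic=also_mosaic,
        n_distinct_mlgs=count_distinct_mlgs(colony, pairs),
        qc_single_locus_flag=qc,
        pairs=pairs,
        site=colony.site,
        group=colony.group,
    )


def classify_dataset(
    dataset: Dataset, thresholds: ThresholdSet
) -> tuple[list[ColonyClassification], list[str]]:
    """Classify every colony; returns (classifications, excluded colony ids)."""
    out, excluded = [], []
    for colony in dataset:
        try:
            out.append(classify_colony(colony, thresholds))
        except ColonyNotEvaluable:
            logger.warning(
                "colony %s excluded: no comparison between nubbin pairs possible",
                colony.id,
            )
            excluded.append(colony.id)
    assert len(out) + len(excluded) == len(dataset.colonies)
    return out, excluded


def classification_frame(
    classifications: Sequence[ColonyClassification],
) -> pd.DataFrame:
    """Tabular view matching the classification TSV interface."""
    rows = [
        {
            "colony_id": c.colony_id,
            "site": c.site,
            "group": c.group,
            "category": c.category,
            "also_mosaic": c.also_mosaic,
            "n_distinct_mlgs": c.n_distinct_mlgs,
            "qc_single_locus_flag": c.qc_single_locus_flag,
            "min_NL": c.min_NL,
            "max_NA": c.max_NA,
            "max_D": c.max_D,
        }
        for c in classifications
    ]
    return pd.DataFrame(rows)


def sensitivity_analysis(
    dataset: Dataset,
    thresholds: ThresholdSet,
    na_deltas: Sequence[int] = (-1, 0, 1),
    d_alternatives: Sequence[float] = (),
) -> pd.DataFrame:
    """Chimera counts under perturbed mosaic/chimera cutoffs.

    Re-runs only the chimera step of the cascade for each perturbed
    threshold set: every ``na_deltas`` shift of ``N_A_chi_mos`` (at the
    baseline ``D_chi_mos``) and every alternative ``D_chi_mos`` in
    ``d_alternatives`` (at the baseline ``N_A_chi_mos``).
    """
    variants: list[tuple[str, ThresholdSet]] = []
    for dna in na_deltas:
        na = thresholds.N_A_chi_mos + dna
        if na < 1:
            logger.warning("skipping N_A delta %+d: threshold would be < 1", dna)
            continue
        variants.append(
            (
                f"N_A_chi_mos{dna:+d}",
                ThresholdSet(thresholds.N_L_min, na, thresholds.D_chi_mos),
            )
        )
    for d in d_alternatives:
        variants.append(
            (
                f"D_chi_mos={d:g}",
                ThresholdSet(thresholds.N_L_min, thresholds.N_A_chi_mos, d),
            )
        )

    rows = []
    for label, ts in variants:
        classifications, _ = classify_dataset(dataset, ts)
        n_var = sum(c.variable for c in classifications)
        n_chi = sum(c.category == "chimeric" for c in classifications)
        rows.append(
            {
                "perturbation": label,
                "N_A_chi_mos": ts.N_A_chi_mos,
                "D_chi_mos": ts.D_chi_mos,
                "n_variable": n_var,
                "n_chimeric": n_chi,
                "chimeric_frac_of_variable": n_chi / n_var if n_var else float("nan"),
                "chimeric_frac_of_all": n_chi / len(classifications)
                if classifications
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def shared_mlg_across_colonies(
    dataset: Dataset,
    classifications: Sequence[ColonyClassification],
) -> pd.DataFrame:
    """Complete MLGs occurring in >= 2 *variable* colonies.

    One row per shared MLG with the colonies, their categories and sites —
    the signature of a clone participating in several chimeras or of a
    locally dominant genet.
    """
    by_colony = {c.colony_id: c for c in classifications}
    groups = clone_match(dataset.nubbins)
    rows = []
    for idx, group in enumerate(groups):
        colony_ids = sorted(
            {
                n.colony_id
                for n in group
                if n.colony_id in by_colony and by_colony[n.colony_id].variable
            }
        )
        if len(colony_ids) < 2:
            continue
        rows.append(
            {
                "mlg_index": idx,
                "n_nubbins": len(group),
                "colonies": ",".join(colony_ids),
                "categories": ",".join(
                    by_colony[cid].category for cid in colony_ids
                ),
                "sites": ",".join(
                    dataset.colony(cid).site for cid in colony_ids
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["mlg_index", "n_nubbins", "colonies", "categories", "sites"]
    )
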