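"""Pairwise multilocus-genotype differentiation under two mutation models.

For a pair of diploid MLGs, over the loci successfully typed in *both*
(``N_L``, the comparable loci):

* ``N_A`` — the number of different alleles, an infinite-allele-model
  index: per locus ``2 - |multiset intersection|`` of the two diploid
  allele multisets, summed over comparable loci.
* ``D`` — Bruvo's distance, a stepwise-mutation-model index: each allele
  contributes ``1 - 2**(-x)`` where ``x`` is the repeat-unit step count to
  its counterpart; within a locus the two possible allele pairings are
  tried and the cheaper one kept (the known-ploidy minimum-pairing rule);
  ``D`` is the total contribution divided by ``2 * N_L``, so ``D`` lies in
  ``[0, 1]`` and missing data never deflate it.

A pair with ``N_L = 0`` is *non-evaluable* and carries an explicit flag
rather than NaN sentinel values.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional, Sequence

from .model import Colony, LocusDef, MultilocusGenotype, Nubbin, ssh_of_group

__all__ = [
    "PairwiseComparison",
    "comparable_loci",
    "n_different_alleles",
    "mutation_steps",
    "bruvo_distance",
    "compare_mlgs",
    "all_pairwise",
    "intracolonial_pairs",
    "clone_match",
    "bruvo_distance_bruteforce",
]

logger = logging.getLogger(__name__)

STRATA = ("intracolony", "intracluster", "intercluster", "inter_SSH")


@dataclass(frozen=True)
class PairwiseComparison:
    """Differentiation indices for one unordered nubbin pair."""

    id_a: str
    id_b: str
    N_L: int
    N_A: Optional[int]
    D: Optional[float]
    stratum: Optional[str] = None
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.evaluable:
            if not (0 <= self.N_A <= 2 * self.N_L):
                raise ValueError("N_A out of [0, 2*N_L]")
            if not (0.0 <= self.D <= 1.0 + 1e-12):
                raise ValueError("D out of [0, 1]")


def comparable_loci(mlg_a: MultilocusGenotype, mlg_b: MultilocusGenotype) -> int:
    """Number of loci typed in both MLGs (``N_L``)."""
    if mlg_a.panel.names != mlg_b.panel.names:
        raise ValueError("MLGs are on different panels")
    return sum(
        ga is not None and gb is not None
        for ga, gb in zip(mlg_a.genotypes, mlg_b.genotypes)
    )


def _locus_na(ga: tuple[int, int], gb: tuple[int, int]) -> int:
    shared = sum((Counter(ga) & Counter(gb)).values())
    return 2 - shared


def n_different_alleles(
    mlg_a: MultilocusGenotype, mlg_b: MultilocusGenotype
) -> Optional[int]:
    """``N_A`` over comparable loci; None when no locus is comparable."""
    if mlg_a.panel.names != mlg_b.panel.names:
        raise ValueError("MLGs are on different panels")
    total = 0
    any_comparable = False
    for ga, gb in zip(mlg_a.genotypes, mlg_b.genotypes):
        if ga is None or gb is None:
            continue
        any_comparable = True
        total += _locus_na(ga, gb)
    return total if any_comparable else None


def mutation_steps(
    allele_a: int,
    allele_b: int,
    locus_def: Optional[LocusDef] = None,
    policy: str = "strict",
) -> int:
    """Stepwise-mutation step count ``x`` between two alleles.

    Alleles already expressed as repeat counts (or with no locus given)
    differ by ``|a - b|`` steps.  bp-sized alleles are divided by the motif
    length; an off-ladder difference errors under ``strict`` and rounds
    half away from zero with a warning under ``tolerant``.
    """
    diff = abs(allele_a - allele_b)
    if locus_def is None or locus_def.encoding == "repeat_count":
        return diff
    steps = diff / locus_def.motif_length
    if steps == int(steps):
        return int(steps)
    if policy == "strict":
        raise ValueError(
            f"alleles {allele_a} and {allele_b} differ by {diff} bp, not a "
            f"multiple of motif {locus_def.motif_length}"
        )
    warnings.warn(
        f"off-ladder step {steps} rounded to nearest integer", stacklevel=2
    )
    import math

    return int(math.floor(steps + 0.5))


def _step_cost(x: int) -> float:
    return 1.0 - 2.0 ** (-x)


def _locus_bruvo(ga: tuple[int, int], gb: tuple[int, int]) -> float:
    """Min-pairing per-locus Bruvo contribution (sum over the two alleles)."""
    a1, a2 = ga
    b1, b2 = gb
    straight = _step_cost(abs(a1 - b1)) + _step_cost(abs(a2 - b2))
    crossed = _step_cost(abs(a1 - b2)) + _step_cost(abs(a2 - b1))
    return min(straight, crossed)


def bruvo_distance(
    mlg_a: MultilocusGenotype, mlg_b: MultilocusGenotype
) -> Optional[float]:
    """Bruvo's distance ``D`` over comparable loci; None when ``N_L = 0``."""
    if mlg_a.panel.names != mlg_b.panel.names:
        raise ValueError("MLGs are on different panels")
    total = 0.0
    n_l = 0
    for ga, gb in zip(mlg_a.genotypes, mlg_b.genotypes):
        if ga is None or gb is None:
            continue
        n_l += 1
        total += _locus_bruvo(ga, gb)
    if n_l == 0:
        return None
    return total / (2 * n_l)


def bruvo_distance_bruteforce(
    mlg_a: MultilocusGenotype, mlg_b: MultilocusGenotype
) -> Optional[float]:
    """Reference Bruvo: minimise over all allele bijections per locus.

    Exponential in ploidy; used as an independent oracle for the
    minimum-pairing shortcut in tests.
    """
    total = 0.0
    n_l = 0
    for ga, gb in zip(mlg_a.genotypes, mlg_b.genotypes):
        if ga is None or gb is None:
            continue
        n_l += 1
        best = min(
            sum(_step_cost(abs(x - y)) for x, y in zip(ga, perm))
            for perm in permutations(gb)
        )
        total += best
    return None if n_l == 0 else total / (2 * n_l)


def compare_mlgs(
    nubbin_a: Nubbin, nubbin_b: Nubbin, stratum: Optional[str] = None
) -> PairwiseComparison:
    """Full (N_L, N_A, D) comparison for one nubbin pair."""
    n_l = comparable_loci(nubbin_a.mlg, nubbin_b.mlg)
    if n_l == 0:
        return PairwiseComparison(
            nubbin_a.id, nubbin_b.id, 0, None, None, stratum, evaluable=False
        )
    return PairwiseComparison(
        nubbin_a.id,
        nubbin_b.id,
        n_l,
        n_different_alleles(nubbin_a.mlg, nubbin_b.mlg),
        bruvo_distance(nubbin_a.mlg, nubbin_b.mlg),
        stratum,
    )


def _pair_stratum(group_a: str, group_b: str) -> str:
    """Stratify an intercolony (or all-pairs) comparison by group labels.

    Same cluster label -> intracluster (the study pools intracolonial and
    intercolonial pairs of one cluster when fitting thresholds); same SSH
    but different cluster -> intercluster; different SSH -> inter_SSH.
    """
    if group_a == group_b:
        return "intracluster"
    if ssh_of_group(group_a) == ssh_of_group(group_b):
        return "intercluster"
    return "inter_SSH"


def all_pairwise(
    nubbins: Sequence[Nubbin],
    groups: dict[str, str],
    require_complete: bool = True,
) -> list[PairwiseComparison]:
    """All unordered pairwise comparisons, tagged with their stratum.

    Parameters
    ----------
    nubbins:
        Candidate nubbins; with ``require_complete`` only those whose MLG
        has no missing locus enter (the convention used for threshold
        fitting).
    groups:
        Map nubbin id -> cluster label used for stratification.
    """
    eligible = [n for n in nubbins if (not require_complete) or n.mlg.complete()]
    if len(eligible) < 2:
        warnings.warn("fewer than 2 eligible nubbins; no pairs", stacklevel=2)
        return []
    out = []
    for a, b in combinations(eligible, 2):
        stratum = _pair_stratum(groups[a.id], groups[b.id])
        out.append(compare_mlgs(a, b, stratum))
    counts = Counter(p.stratum for p in out)
    logger.info("all_pairwise: %d pairs (%s)", len(out), dict(counts))
    return out


def intracolonial_pairs(colony: Colony) -> list[PairwiseComparison]:
    """All C(n, 2) comparisons among the nubbins of one colony.

    Pairs sharing no typed locus are returned flagged non-evaluable; the
    caller decides whether the colony as a whole can be classified.
    """
    if len(colony.nubbins) < 2:
        raise ValueError(f"colony {colony.id!r} has fewer than 2 nubbins")
    return [
        compare_mlgs(a, b, "intracolony")
        for a, b in combinations(colony.nubbins, 2)
    ]


def clone_match(nubbins: Sequence[Nubbin]) -> list[list[Nubbin]]:
    """Partition complete MLGs into clonal groups by exact identity.

    Incomplete MLGs are excluded (missing data make exact matching
    undefined).  Groups are returned largest first.
    """
    groups: dict[tuple, list[Nubbin]] = {}
    for n in nubbins:
        key = n.mlg.key()
        if key is None:
            continue
        groups.setdefault(key, []).append(n)
    out = sorted(groups.values(), key=len, reverse=True)
    logger.info(
        "clone_match: %d complete MLGs in %d clonal groups",
        sum(len(g) for g in out),
        len(out),
    )
    return out
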