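"""Synthetic colony genotype datasets with known ground truth.

The generator emulates the sampling design the analysis assumes: several
sites of threefold-sampled colonies, a microsatellite panel of ~12 loci,
two sympatric genetic clusters with differentiated allele frequencies (so
pooled pairwise-distance distributions are multimodal), somatic mutations
of 1-2 repeat steps creating mosaics, within-cluster fusions creating
chimeras, per-locus allelic dropout, and optionally a locally dominant
clonal genotype.

Allele frequencies follow a discretized normal over repeat counts per
locus and cluster; the second cluster is shifted by a configurable number
of repeat units, which controls intercluster divergence with a single
parameter.  Everything is driven by one :class:`numpy.random.Generator`,
so a fixed seed reproduces the dataset exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .distances import bruvo_distance, compare_mlgs, n_different_alleles
from .model import Colony, Dataset, LocusDef, MultilocusGenotype, Nubbin, Panel

__all__ = [
    "ClusterSpec",
    "CloneSpec",
    "SimulationConfig",
    "ColonyTruth",
    "GroundTruth",
    "generate_dataset",
    "truth_confusion",
    "mosaic_miss_rate_at_NL",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterSpec:
    """Allele-frequency model of one genetic cluster."""

    label: str
    weight: float
    mean_repeats: tuple[float, ...]  # per-locus mean repeat count
    sd_repeats: float = 1.5


@dataclass(frozen=True)
class CloneSpec:
    """A dominant multilocus genotype over-represented in the sample."""

    frequency: float  # probability a colony founder is the dominant clone
    sites: Optional[tuple[str, ...]] = None  # restrict to these sites; None = all
    cluster_index: int = 0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the field design the pipeline targets: 3 sites x 32
    threefold-sampled colonies, 12 loci, two clusters in roughly 85/15
    proportion, mosaics of 1-2 repeat steps, within-cluster chimeric
    fusions, and per-locus dropout spanning 11.8%-41.7%.
    """

    n_sites: int = 3
    colonies_per_site: int = 32
    nubbins_per_colony: int = 3
    n_loci: int = 12
    motif_lengths: Optional[tuple[int, ...]] = None  # default cycles 2,3,4
    clusters: Optional[tuple[ClusterSpec, ...]] = None
    inter_cluster_offset: float = 5.0
    clone_spec: Optional[CloneSpec] = None
    mosaic_rate: float = 0.40
    #: P(1 vs 2 mutated alleles) and P(1 vs 2 repeat steps) per mutation
    mosaic_n_allele_probs: tuple[float, float] = (0.7, 0.3)
    mosaic_step_probs: tuple[float, float] = (0.8, 0.2)
    #: P(a mosaic colony has a second independently mutated nubbin)
    mosaic_second_nubbin_prob: float = 0.15
    chimera_rate: float = 0.10
    chimera_min_NA: int = 4
    chimera_min_D: float = 0.12
    chimera_three_genets: bool = False  # 1+1+1 split instead of 2+1
    #: per-locus dropout probability: scalar, or (lo, hi) uniform range
    dropout: Union[float, tuple[float, float]] = (0.118, 0.417)
    seed: int = 0

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationConfig":
        """Build a config from plain YAML/JSON-style mappings."""
        kwargs = dict(mapping)
        if isinstance(kwargs.get("clone_spec"), dict):
            cs = dict(kwargs["clone_spec"])
            if cs.get("sites") is not None:
                cs["sites"] = tuple(cs["sites"])
            kwargs["clone_spec"] = CloneSpec(**cs)
        if kwargs.get("clusters") is not None:
            kwargs["clusters"] = tuple(
                c
                if isinstance(c, ClusterSpec)
                else ClusterSpec(
                    c["label"],
                    c["weight"],
                    tuple(c["mean_repeats"]),
                    c.get("sd_repeats", 1.5),
                )
                for c in kwargs["clusters"]
            )
        for key in ("motif_lengths", "dropout"):
            if isinstance(kwargs.get(key), list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def resolved_motifs(self) -> tuple[int, ...]:
        if self.motif_lengths is not None:
            if len(self.motif_lengths) != self.n_loci:
                raise ValueError("motif_lengths length != n_loci")
            return self.motif_lengths
        return tuple((2, 3, 4)[i % 3] for i in range(self.n_loci))

    def resolved_clusters(self) -> tuple[ClusterSpec, ...]:
        if self.clusters is not None:
            total = sum(c.weight for c in self.clusters)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("cluster weights must sum to 1")
            return self.clusters
        base = tuple(10.0 + 3 * (i % 4) for i in range(self.n_loci))
        shifted = tuple(m + self.inter_cluster_offset for m in base)
        return (
            ClusterSpec("SSH05c-1", 0.85, base),
            ClusterSpec("SSH05c-2", 0.15, shifted),
        )


@dataclass
class ColonyTruth:
    colony_id: str
    category: str  # invariable | mosaic | chimeric
    cluster: str
    founder: MultilocusGenotype
    second_founders: list[MultilocusGenotype] = field(default_factory=list)
    #: (nubbin_id, locus_index, allele_index, signed step) per injected mutation
    mutations: list[tuple[str, int, int, int]] = field(default_factory=list)
    #: genet index per nubbin id (0 = founder)
    genet_of: dict[str, int] = field(default_factory=dict)
    fusion_NA: Optional[int] = None
    fusion_D: Optional[float] = None
    is_dominant_clone: bool = False


@dataclass
class GroundTruth:
    colonies: dict[str, ColonyTruth]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "colony_id": t.colony_id,
                "true_category": t.category,
                "cluster": t.cluster,
                "n_mutations": len(t.mutations),
                "fusion_NA": t.fusion_NA,
                "fusion_D": t.fusion_D,
                "is_dominant_clone": t.is_dominant_clone,
            }
            for t in self.colonies.values()
        ]
        return pd.DataFrame(rows)


def _draw_mlg(
    rng: np.random.Generator, cluster: ClusterSpec, panel: Panel
) -> MultilocusGenotype:
    genos = []
    for mean in cluster.mean_repeats:
        a, b = np.round(rng.normal(mean, cluster.sd_repeats, size=2)).astype(int)
        genos.append((max(int(a), 2), max(int(b), 2)))
    return MultilocusGenotype(panel, tuple(genos))


def _mutate(
    rng: np.random.Generator,
    mlg: MultilocusGenotype,
    config: SimulationConfig,
) -> tuple[MultilocusGenotype, list[tuple[int, int, int]]]:
    """Inject 1-2 somatic repeat-step mutations, each on a distinct locus.

    Distinct loci guarantee every injected mutation is visible in the
    founder/mutant comparison (two opposite-sign steps on the two alleles
    of one locus could otherwise cancel into an identical multiset).
    """
    n_alleles = rng.choice([1, 2], p=config.mosaic_n_allele_probs)
    loci = rng.choice(config.n_loci, size=n_alleles, replace=False)
    genos = list(mlg.genotypes)
    log = []
    for locus in loci:
        locus = int(locus)
        allele_idx = int(rng.integers(2))
        step = int(rng.choice([1, 2], p=config.mosaic_step_probs))
        sign = int(rng.choice([-1, 1]))
        pair = list(genos[locus])
        new = pair[allele_idx] + sign * step
        if new < 2:  # reflect at the short-allele boundary
            sign = 1
            new = pair[allele_idx] + step
        pair[allele_idx] = new
        genos[locus] = (pair[0], pair[1])
        log.append((locus, allele_idx, sign * step))
    return MultilocusGenotype(mlg.panel, tuple(genos)), log


def _draw_chimera_partner(
    rng: np.random.Generator,
    founder: MultilocusGenotype,
    cluster: ClusterSpec,
    panel: Panel,
    config: SimulationConfig,
    max_redraws: int = 200,
) -> tuple[MultilocusGenotype, int, float]:
    for _ in range(max_redraws):
        partner = _draw_mlg(rng, cluster, panel)
        na = n_different_alleles(founder, partner)
        d = bruvo_distance(founder, partner)
        if na > config.chimera_min_NA and d > config.chimera_min_D:
            return partner, na, d
    raise RuntimeError(
        f"could not draw a fusion partner with N_A > {config.chimera_min_NA} "
        f"and D > {config.chimera_min_D} within {max_redraws} redraws; the "
        "cluster's allele-frequency spread is too narrow"
    )


def generate_dataset(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[Dataset, GroundTruth]:
    """Simulate a colony genotype dataset plus its ground truth.

    Colony construction: draw a cluster (or the dominant clone), draw a
    founder MLG from the cluster allele frequencies; mosaic colonies copy
    the founder to every nubbin then inject mutations into one (sometimes
    two) nubbins; chimeric colonies draw a second same-cluster genet,
    redrawing until it is distant enough, and split the nubbins between
    the two genets (2+1, or 1+1+1 when configured).  Per-locus dropout is
    applied independently per nubbin afterwards.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    motifs = config.resolved_motifs()
    panel = Panel(
        [LocusDef(f"L{i + 1:02d}", motifs[i], "repeat_count") for i in range(config.n_loci)]
    )
    clusters = config.resolved_clusters()
    weights = np.array([c.weight for c in clusters])

    if isinstance(config.dropout, (tuple, list)):
        lo, hi = config.dropout
        locus_dropout = rng.uniform(lo, hi, size=config.n_loci)
    else:
        locus_dropout = np.full(config.n_loci, float(config.dropout))

    dominant: Optional[MultilocusGenotype] = None
    if config.clone_spec is not None:
        dominant = _draw_mlg(rng, clusters[config.clone_spec.cluster_index], panel)

    sites = [f"S{k + 1}" for k in range(config.n_sites)]
    colonies: list[Colony] = []
    truths: dict[str, ColonyTruth] = {}
    counter = 0
    for site in sites:
        for _ in range(config.colonies_per_site):
            counter += 1
            cid = f"C{counter:04d}"
            ci = int(rng.choice(len(clusters), p=weights))
            cluster = clusters[ci]
            is_clone = False
            if (
                dominant is not None
                and (config.clone_spec.sites is None or site in config.clone_spec.sites)
                and ci == config.clone_spec.cluster_index
                and rng.random() < config.clone_spec.frequency
            ):
                founder, is_clone = dominant, True
            else:
                founder = _draw_mlg(rng, cluster, panel)

            u = rng.random()
            if u < config.chimera_rate:
                category = "chimeric"
            elif u < config.chimera_rate + config.mosaic_rate:
                category = "mosaic"
            else:
                category = "invariable"

            truth = ColonyTruth(cid, category, cluster.label, founder, is_dominant_clone=is_clone)
            n_nub = config.nubbins_per_colony
            nubbin_ids = [f"{cid}.{chr(ord('a') + k)}" for k in range(n_nub)]
            mlgs: list[MultilocusGenotype]

            if category == "invariable":
                mlgs = [founder] * n_nub
                truth.genet_of = {nid: 0 for nid in nubbin_ids}
            elif category == "mosaic":
                mlgs = [founder] * n_nub
                truth.genet_of = {nid: 0 for nid in nubbin_ids}
                n_mutated = 1
                if n_nub > 2 and rng.random() < config.mosaic_second_nubbin_prob:
                    n_mutated = 2
                which = rng.choice(n_nub, size=n_mutated, replace=False)
                for k in which:
                    mutated, log = _mutate(rng, founder, config)
                    mlgs[int(k)] = mutated
                    truth.mutations.extend(
                        (nubbin_ids[int(k)], locus, ai, step) for locus, ai, step in log
                    )
            else:
                partner, na, d = _draw_chimera_partner(rng, founder, cluster, panel, config)
                truth.second_founders.append(partner)
                truth.fusion_NA, truth.fusion_D = na, d
                if config.chimera_three_genets and n_nub >= 3:
                    third, _, _ = _draw_chimera_partner(rng, founder, cluster, panel, config)
                    truth.second_founders.append(third)
                    genets = [0, 1, 2] + [0] * (n_nub - 3)
                else:
                    # 2+1 split; which genet is in the majority is random
                    minority = int(rng.integers(n_nub))
                    genets = [1 if k == minority else 0 for k in range(n_nub)]
                    if rng.random() < 0.5:
                        genets = [1 - g for g in genets]
                pool = [founder, partner] + truth.second_founders[1:]
                mlgs = [pool[g] for g in genets]
                truth.genet_of = dict(zip(nubbin_ids, genets))

            nubbins = []
            for nid, mlg in zip(nubbin_ids, mlgs):
                genos = list(mlg.genotypes)
                drop = rng.random(config.n_loci) < locus_dropout
                for li in np.nonzero(drop)[0]:
                    genos[int(li)] = None
                nubbins.append(
                    Nubbin(nid, cid, MultilocusGenotype(panel, tuple(genos)))
                )
            colonies.append(Colony(cid, site, cluster.label, nubbins))
            truths[cid] = truth

    logger.info(
        "simulated %d colonies (%s)",
        len(colonies),
        dict(pd.Series([t.category for t in truths.values()]).value_counts()),
    )
    return Dataset(panel, colonies), GroundTruth(truths)


def truth_confusion(
    classifications: Sequence,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, dict]:
    """Truth x called confusion matrix plus chimera detection rates.

    Rows are the three generated categories, columns the five called ones.
    Chimera sensitivity = called chimeric among true chimeras; specificity
    = not called chimeric among true non-chimeras.
    """
    from .classify import CATEGORIES

    called = {c.colony_id: c.category for c in classifications}
    ids = set(called)
    truth_ids = set(truth.colonies)
    if not ids <= truth_ids:
        raise ValueError(f"classified colonies missing from truth: {sorted(ids - truth_ids)}")
    true_cats = ("invariable", "mosaic", "chimeric")
    mat = pd.DataFrame(0, index=list(true_cats), columns=list(CATEGORIES))
    for cid in ids:
        mat.loc[truth.colonies[cid].category, called[cid]] += 1

    n_true_chi = int(mat.loc["chimeric"].sum())
    n_true_not = int(mat.drop(index="chimeric").to_numpy().sum())
    tp = int(mat.loc["chimeric", "chimeric"])
    fp = int(mat.drop(index="chimeric")["chimeric"].sum())
    metrics = {
        "chimera_sensitivity": tp / n_true_chi if n_true_chi else float("nan"),
        "chimera_specificity": (n_true_not - fp) / n_true_not
        if n_true_not
        else float("nan"),
        "n_colonies": len(ids),
    }
    return mat, metrics


def mosaic_miss_rate_at_NL(
    n_pairs: int,
    n_l: int,
    n_loci: int = 12,
    seed: int = 0,
    n_mutated_alleles: int = 1,
) -> float:
    """Empirical false-negative rate of mosaic detection at a fixed N_L.

    Simulates ``n_pairs`` founder/mutant nubbin pairs (each mutant carrying
    ``n_mutated_alleles`` single-step mutations), masks a uniformly random
    subset of ``n_loci - n_l`` loci in one member, and reports the fraction
    of pairs whose surviving comparable loci show no difference.  Validates
    the combinatorial closed form empirically.
    """
    config = SimulationConfig(
        n_loci=n_loci,
        mosaic_n_allele_probs=(1.0, 0.0) if n_mutated_alleles == 1 else (0.0, 1.0),
        dropout=0.0,
    )
    rng = np.random.default_rng(seed)
    motifs = config.resolved_motifs()
    panel = Panel([LocusDef(f"L{i + 1:02d}", motifs[i]) for i in range(n_loci)])
    cluster = config.resolved_clusters()[0]
    missed = 0
    for _ in range(n_pairs):
        founder = _draw_mlg(rng, cluster, panel)
        mutated, _ = _mutate(rng, founder, config)
        masked = list(mutated.genotypes)
        for li in rng.choice(n_loci, size=n_loci - n_l, replace=False):
            masked[int(li)] = None
        na = n_different_alleles(founder, MultilocusGenotype(panel, tuple(masked)))
        if na == 0:
            missed += 1
    return missed / n_pairs
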