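"""Core data model: loci, multilocus genotypes, nubbins, colonies.

Alleles are stored internally as integer *repeat counts*.  Fragment sizes
in base pairs are converted at read time (see :mod:`igvar.io`), which makes
the stepwise-mutation step count ``x = |a - b|`` integral by construction
and centralises the allele-ladder check in one place.

A diploid locus genotype is either a sorted pair of repeat counts or
missing as a whole: a locus with only one readable allele is coerced to
missing, mirroring the wet-lab convention of discarding ambiguous peak
profiles wholesale rather than inventing a single-allele distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "LocusDef",
    "Panel",
    "MultilocusGenotype",
    "Nubbin",
    "Colony",
    "Dataset",
    "ssh_of_group",
]

#: A diploid genotype at one locus: sorted (low, high) repeat counts, or None.
GenotypePair = Optional[tuple[int, int]]


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus.

    Parameters
    ----------
    name:
        Unique locus identifier within a panel (e.g. ``"Pd3-009"``).
    motif_length:
        Repeat-unit length in bp (>= 1); defines the mutation-step metric.
    encoding:
        ``"repeat_count"`` if the input table already holds repeat counts,
        ``"bp_size"`` if it holds fragment sizes in base pairs.
    offset:
        For ``bp_size`` input, the bp residue of the allele ladder
        (``size = offset + motif_length * repeat_count``).  Recorded at
        read time so that writing a dataset back reproduces the input.
    """

    name: str
    motif_length: int = 1
    encoding: str = "repeat_count"
    offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"locus {self.name!r}: motif_length must be >= 1")
        if self.encoding not in ("repeat_count", "bp_size"):
            raise ValueError(f"locus {self.name!r}: unknown encoding {self.encoding!r}")


class Panel(tuple):
    """An ordered, immutable collection of :class:`LocusDef` with unique names."""

    def __new__(cls, loci: Iterable[LocusDef]) -> "Panel":
        loci = tuple(loci)
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in panel")
        if not loci:
            raise ValueError("empty panel")
        return super().__new__(cls, loci)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"locus {name!r} not in panel") from None

    def without(self, names: Sequence[str]) -> "Panel":
        names = set(names)
        unknown = names - set(self.names)
        if unknown:
            raise KeyError(f"cannot drop unknown loci: {sorted(unknown)}")
        kept = [l for l in self if l.name not in names]
        if not kept:
            raise ValueError("dropping all loci would leave an empty panel")
        return Panel(kept)


@dataclass(frozen=True)
class MultilocusGenotype:
    """A diploid multilocus genotype over a fixed locus panel.

    ``genotypes[i]`` is the genotype at ``panel[i]``: a sorted
    ``(low, high)`` repeat-count pair, or ``None`` for a missing locus.
    """

    panel: Panel
    genotypes: tuple[GenotypePair, ...]

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.panel):
            raise ValueError("genotype vector length does not match panel")
        norm = tuple(
            None if g is None else (min(g), max(g)) for g in self.genotypes
        )
        object.__setattr__(self, "genotypes", norm)

    def __getitem__(self, locus_name: str) -> GenotypePair:
        return self.genotypes[self.panel.index_of(locus_name)]

    def complete(self) -> bool:
        """True iff no locus is missing."""
        return all(g is not None for g in self.genotypes)

    @property
    def n_typed(self) -> int:
        return sum(g is not None for g in self.genotypes)

    def restrict(self, panel: Panel) -> "MultilocusGenotype":
        """Re-project onto a sub-panel (e.g. after dropping loci)."""
        idx = [self.panel.index_of(n) for n in panel.names]
        return MultilocusGenotype(panel, tuple(self.genotypes[i] for i in idx))

    def key(self) -> Optional[tuple[GenotypePair, ...]]:
        """Hashable identity for exact clone matching; None unless complete."""
        return self.genotypes if self.complete() else None


@dataclass(frozen=True)
class Nubbin:
    """One replicate sample (branch fragment) of a colony."""

    id: str
    colony_id: str
    mlg: MultilocusGenotype
    color: Optional[str] = None


@dataclass
class Colony:
    """A sampled colony: >= 2 genotyped nubbins plus site/group metadata.

    ``group`` is the species/cluster label assigned upstream (e.g.
    ``"SSH05c-1"``); it is consumed as metadata, never inferred here.
    """

    id: str
    site: str
    group: str
    nubbins: list[Nubbin] = field(default_factory=list)

    def __post_init__(self) -> None:
        for n in self.nubbins:
            if n.colony_id != self.id:
                raise ValueError(
                    f"nubbin {n.id!r} carries colony_id {n.colony_id!r} != {self.id!r}"
                )


def ssh_of_group(group: str) -> str:
    """Species-level (SSH) label of a cluster label.

    Cluster labels follow the ``<SSH>-<cluster>`` convention
    (``"SSH05c-1"`` -> ``"SSH05c"``); a label without a dash is its own SSH.
    """
    return group.rsplit("-", 1)[0]


@dataclass
class Dataset:
    """A panel plus a list of colonies sharing that panel."""

    panel: Panel
    colonies: list[Colony]

    def __iter__(self) -> Iterator[Colony]:
        return iter(self.colonies)

    def __len__(self) -> int:
        return len(self.colonies)

    @property
    def nubbins(self) -> list[Nubbin]:
        return [n for c in self.colonies for n in c.nubbins]

    def colony(self, colony_id: str) -> Colony:
        for c in self.colonies:
            if c.id == colony_id:
                return c
        raise KeyError(colony_id)

    def drop_loci(self, names: Sequence[str]) -> "Dataset":
        """Remove loci from the panel and re-project every genotype.

        Dropping an empty list returns an equivalent dataset; dropping all
        loci is an error.
        """
        if not names:
            return Dataset(self.panel, [replace(c) for c in self.colonies])
        new_panel = self.panel.without(names)
        new_colonies = []
        for c in self.colonies:
            nubs = [
                Nubbin(n.id, n.colony_id, n.mlg.restrict(new_panel), n.color)
                for n in c.nubbins
            ]
            new_colonies.append(Colony(c.id, c.site, c.group, nubs))
        return Dataset(new_panel, new_colonies)
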