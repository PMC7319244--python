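"""Readers and writers for genotype tables and locus configuration.

Genotype CSV dialect (UTF-8, comma separated, header row): metadata columns
``colony_id,nubbin_id,site,group,color`` followed by two columns per locus
named ``<locus>_1`` and ``<locus>_2`` holding integer allele values (bp
fragment sizes or repeat counts, per the locus config).  An empty cell or
``0`` encodes a missing allele; a locus with any missing allele is treated
as missing as a whole.

Locus config (YAML): a list of ``{name, motif_length, encoding}`` mappings.

For bp-sized alleles the reader places every allele of a locus on a common
ladder ``size = offset + motif * repeat``.  Under the default ``strict``
policy a size off that ladder is an error; under ``tolerant`` it is rounded
to the nearest rung (half away from zero) with a warning.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .model import Colony, Dataset, LocusDef, MultilocusGenotype, Nubbin, Panel

__all__ = [
    "read_locus_config",
    "write_locus_config",
    "read_genotype_table",
    "write_genotype_table",
    "read_genepop",
    "missingness_report",
    "drop_loci",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ["colony_id", "nubbin_id", "site", "group", "color"]


def read_locus_config(path: Union[str, Path]) -> Panel:
    """Read a YAML locus configuration into a :class:`Panel`."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    loci = [
        LocusDef(
            name=str(e["name"]),
            motif_length=int(e.get("motif_length", 1)),
            encoding=str(e.get("encoding", "repeat_count")),
        )
        for e in entries
    ]
    return Panel(loci)


def write_locus_config(panel: Panel, path: Union[str, Path]) -> None:
    entries = [
        {"name": l.name, "motif_length": l.motif_length, "encoding": l.encoding}
        for l in panel
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def _parse_cell(value) -> Optional[int]:
    """One allele cell: int, or None for blank/0/NA."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.upper() in ("NA", "NAN"):
            return None
    iv = int(float(value))
    return None if iv == 0 else iv


def _ladder_offset(sizes: Sequence[int], locus: LocusDef, policy: str) -> int:
    """Common bp residue of the allele ladder at one locus.

    Strict policy requires all observed sizes to share one residue modulo
    the motif length; tolerant picks the modal residue (smallest on ties).
    """
    residues = Counter(s % locus.motif_length for s in sizes)
    if len(residues) > 1:
        if policy == "strict":
            raise ValueError(
                f"locus {locus.name!r}: allele sizes {sorted(set(sizes))} are not "
                f"on a single ladder of motif {locus.motif_length} "
                "(use policy='tolerant' to round)"
            )
        top = max(residues.values())
        return min(r for r, c in residues.items() if c == top)
    return next(iter(residues))


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _to_repeats(size: int, locus: LocusDef, offset: int, policy: str) -> int:
    steps = (size - offset) / locus.motif_length
    if steps != int(steps):
        if policy == "strict":
            raise ValueError(
                f"locus {locus.name!r}: size {size} off the ladder "
                f"(offset {offset}, motif {locus.motif_length})"
            )
        warnings.warn(
            f"locus {locus.name}: size {size} off ladder, rounded to nearest repeat",
            stacklevel=2,
        )
        return _round_half_away(steps)
    return int(steps)


def read_genotype_table(
    path: Union[str, Path],
    locus_config: Union[Panel, str, Path],
    policy: str = "strict",
) -> Dataset:
    """Read a genotype CSV into colonies of nubbins.

    Half-called genotypes (exactly one readable allele) are coerced to
    missing.  Nubbins with no readable locus are dropped with a log entry.
    Conflicting group labels within a colony are a hard error.
    """
    panel = (
        locus_config
        if isinstance(locus_config, Panel)
        else read_locus_config(locus_config)
    )
    df = pd.read_csv(path, dtype=str)
    expected = [f"{n}_{i}" for n in panel.names for i in (1, 2)]
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks locus columns: {missing_cols}")
    extra = [
        c
        for c in df.columns
        if c not in META_COLUMNS and c not in expected
    ]
    if extra:
        raise ValueError(f"unknown locus columns in genotype table: {extra}")

    # resolve bp ladders per locus before building genotypes
    offsets: dict[str, int] = {}
    resolved: list[LocusDef] = []
    for locus in panel:
        if locus.encoding == "bp_size":
            sizes = []
            for i in (1, 2):
                sizes.extend(
                    v
                    for v in (_parse_cell(x) for x in df[f"{locus.name}_{i}"])
                    if v is not None
                )
            off = _ladder_offset(sizes, locus, policy) if sizes else 0
            offsets[locus.name] = off
            resolved.append(
                LocusDef(locus.name, locus.motif_length, locus.encoding, off)
            )
        else:
            offsets[locus.name] = 0
            resolved.append(locus)
    panel = Panel(resolved)

    colonies: dict[str, Colony] = {}
    seen_nubbins: set[str] = set()
    for _, row in df.iterrows():
        genos = []
        for locus in panel:
            a = _parse_cell(row[f"{locus.name}_1"])
            b = _parse_cell(row[f"{locus.name}_2"])
            if a is None or b is None:
                genos.append(None)  # half-calls count as missing wholesale
                continue
            if locus.encoding == "bp_size":
                a = _to_repeats(a, locus, locus.offset, policy)
                b = _to_repeats(b, locus, locus.offset, policy)
            genos.append((a, b))
        nid = str(row["nubbin_id"])
        if nid in seen_nubbins:
            raise ValueError(f"duplicate nubbin id {nid!r}")
        seen_nubbins.add(nid)
        mlg = MultilocusGenotype(panel, tuple(genos))
        if mlg.n_typed == 0:
            logger.warning("nubbin %s has no readable locus; dropped", nid)
            continue
        cid = str(row["colony_id"])
        color = row.get("color")
        color = None if (color is None or pd.isna(color) or color == "") else str(color)
        nubbin = Nubbin(nid, cid, mlg, color)
        if cid not in colonies:
            colonies[cid] = Colony(cid, str(row["site"]), str(row["group"]), [])
        else:
            if colonies[cid].group != str(row["group"]):
                raise ValueError(
                    f"colony {cid!r}: conflicting group labels "
                    f"{colonies[cid].group!r} vs {row['group']!r}"
                )
        colonies[cid].nubbins.append(nubbin)

    ds = Dataset(panel, list(colonies.values()))
    for name, prop in missingness_report(ds)["missing_prop"].items():
        logger.info("locus %s: missing proportion %.3f", name, prop)
    return ds


def write_genotype_table(dataset: Dataset, path: Union[str, Path]) -> None:
    """Write a dataset back to the genotype CSV dialect.

    Repeat counts are converted back to bp sizes for ``bp_size`` loci using
    the recorded ladder offset, so write-then-read round-trips exactly.
    """
    rows = []
    for colony in dataset:
        for n in colony.nubbins:
            row: dict = {
                "colony_id": colony.id,
                "nubbin_id": n.id,
                "site": colony.site,
                "group": colony.group,
                "color": n.color if n.color is not None else "",
            }
            for locus, g in zip(dataset.panel, n.mlg.genotypes):
                if g is None:
                    row[f"{locus.name}_1"] = ""
                    row[f"{locus.name}_2"] = ""
                else:
                    a, b = g
                    if locus.encoding == "bp_size":
                        a = locus.offset + a * locus.motif_length
                        b = locus.offset + b * locus.motif_length
                    row[f"{locus.name}_1"] = a
                    row[f"{locus.name}_2"] = b
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genepop(path: Union[str, Path], panel: Optional[Panel] = None) -> Dataset:
    """Minimal GenePop reader mapped onto the same model.

    2- or 3-digit diploid allele codes; ``00``/``000`` is missing.  Each POP
    block becomes a site; sample labels ``<colony>_<nubbin>`` (or
    ``<colony>-<nubbin>``) group rows into colonies, otherwise each sample
    is its own single-nubbin colony.  Allele codes are taken as repeat
    counts unless a panel says otherwise.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    # line 0: title; locus names until first POP
    i = 1
    locus_names: list[str] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if panel is None:
        panel = Panel([LocusDef(n) for n in locus_names])
    elif list(panel.names) != locus_names:
        raise ValueError("panel does not match GenePop locus list")

    colonies: dict[str, Colony] = {}
    pop_idx = 0
    for ln in lines[i:]:
        if ln.strip().lower() == "pop":
            pop_idx += 1
            continue
        label, _, geno_part = ln.partition(",")
        label = label.strip()
        codes = geno_part.split()
        if len(codes) != len(panel):
            raise ValueError(f"sample {label!r}: {len(codes)} loci, expected {len(panel)}")
        genos = []
        for code in codes:
            w = len(code) // 2
            a, b = int(code[:w]), int(code[w:])
            genos.append(None if a == 0 or b == 0 else (a, b))
        for sep in ("_", "-"):
            if sep in label:
                cid, nid = label.rsplit(sep, 1)
                nid = label
                break
        else:
            cid, nid = label, f"{label}.1"
        mlg = MultilocusGenotype(panel, tuple(genos))
        if mlg.n_typed == 0:
            logger.warning("sample %s has no readable locus; dropped", label)
            continue
        site = f"POP{pop_idx}"
        if cid not in colonies:
            colonies[cid] = Colony(cid, site, site, [])
        colonies[cid].nubbins.append(Nubbin(nid, cid, mlg))
    return Dataset(panel, list(colonies.values()))


def missingness_report(dataset: Dataset) -> pd.DataFrame:
    """Per-locus missing proportion over all nubbins, indexed by locus name."""
    nubbins = dataset.nubbins
    if not nubbins:
        raise ValueError("empty dataset")
    rows = []
    for i, locus in enumerate(dataset.panel):
        n_missing = sum(n.mlg.genotypes[i] is None for n in nubbins)
        rows.append(
            {
                "locus": locus.name,
                "n_missing": n_missing,
                "n_total": len(nubbins),
                "missing_prop": n_missing / len(nubbins),
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def drop_loci(dataset: Dataset, names: Sequence[str]) -> Dataset:
    """Functional alias of :meth:`Dataset.drop_loci`."""
    return dataset.drop_loci(names)
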