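"""Shared builders for tests: panels, genotypes, colonies."""

from igvar.model import Colony, LocusDef, MultilocusGenotype, Nubbin, Panel


def make_panel(n_loci=12, motif=2, encoding="repeat_count"):
    return Panel([LocusDef(f"L{i + 1:02d}", motif, encoding) for i in range(n_loci)])


def uniform_mlg(panel, pair=(10, 12)):
    """An MLG with the same genotype at every locus."""
    return MultilocusGenotype(panel, tuple(pair for _ in panel))


def edited_mlg(mlg, edits):
    """Copy of ``mlg`` with per-slot repeat-step edits.

    ``edits``: iterable of (locus_index, allele_index, signed_steps) or,
    with allele_index None, (locus_index, None) meaning set locus missing.
    """
    genos = [None if g is None else list(g) for g in mlg.genotypes]
    for edit in edits:
        if edit[1] is None:
            genos[edit[0]] = None
            continue
        locus, allele_idx, steps = edit
        genos[locus][allele_idx] += steps
    return MultilocusGenotype(
        mlg.panel, tuple(None if g is None else tuple(g) for g in genos)
    )


def make_colony(colony_id, mlgs, site="S1", group="SSH05c-1", colors=None):
    colors = colors or [None] * len(mlgs)
    nubbins = [
        Nubbin(f"{colony_id}.{chr(ord('a') + k)}", colony_id, mlg, color)
        for k, (mlg, color) in enumerate(zip(mlgs, colors))
    ]
    return Colony(colony_id, site, group, nubbins)
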