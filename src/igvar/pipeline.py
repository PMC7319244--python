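"""End-to-end pipeline driver: read/simulate -> distances -> thresholds ->
classify -> sensitivity -> summaries -> tests, with all artifacts written
to a run directory.

The run configuration is a YAML mapping with either an ``input`` section
(``genotype_csv`` + ``locus_config`` paths, optional ``drop_loci`` list)
or a ``simulate`` section (:class:`igvar.simulate.SimulationConfig`
fields), plus::

    thresholds:
      mode: fit | fixed
      N_L_min: 9          # used when fixed, or as fallback
      N_A_chi_mos: 4
      D_chi_mos: 0.12
      max_fn: 0.20
      bandwidth: silverman
    seed: 0
    out: runs/example
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .classify import (
    classification_frame,
    classify_dataset,
    sensitivity_analysis,
    shared_mlg_across_colonies,
)
from .distances import all_pairwise, intracolonial_pairs
from .io import read_genotype_table, write_genotype_table, write_locus_config
from .model import Dataset
from .report import homogeneity_test, summarize
from .simulate import SimulationConfig, generate_dataset, truth_confusion
from .thresholds import (
    ThresholdSet,
    false_negative_curve,
    select_chi_mos_thresholds,
    select_NL_threshold,
)

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _pairwise_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "stratum": p.stratum,
                "N_L": p.N_L,
                "N_A": p.N_A,
                "D": round(p.D, 6) if p.D is not None else None,
                "evaluable": p.evaluable,
            }
            for p in pairs
        ]
    )


def _profile_dict(profile) -> dict:
    return {
        "kind": profile.kind,
        "bandwidth": profile.bandwidth,
        "modes": [list(m) if isinstance(m, tuple) else m for m in profile.modes],
        "antimodes": [
            list(a) if isinstance(a, tuple) else a for a in profile.antimodes
        ],
    }


def _fit_thresholds(dataset: Dataset, tcfg: dict, outdir: Path) -> ThresholdSet:
    groups = {n.id: c.group for c in dataset for n in c.nubbins}
    pairs = all_pairwise(dataset.nubbins, groups, require_complete=True)
    intra = [p for p in pairs if p.stratum == "intracluster"]
    na_t, d_t, na_prof, d_prof = select_chi_mos_thresholds(
        intra, bandwidth=tcfg.get("bandwidth")
    )

    # false-negative curve from complete variable intracolonial pairs
    l_total = len(dataset.panel)
    by_id = {n.id: n for n in dataset.nubbins}
    variable_pairs = []
    invariable_nls = []
    for colony in dataset:
        for p in intracolonial_pairs(colony):
            if not p.evaluable:
                continue
            if p.N_L == l_total and p.N_A > 0:
                variable_pairs.append((by_id[p.id_a].mlg, by_id[p.id_b].mlg))
            elif p.N_A == 0:
                invariable_nls.append(p.N_L)
    if not variable_pairs:
        raise ValueError(
            "no complete variable intracolonial pair; cannot fit N_L_min "
            "(supply thresholds.mode: fixed)"
        )
    curve = false_negative_curve(variable_pairs, l_total)
    nl_min, nl_profile = select_NL_threshold(
        curve,
        invariable_nls if len(invariable_nls) >= 2 else None,
        max_fn=tcfg.get("max_fn", 0.20),
    )

    pd.DataFrame(
        {
            "N_L": sorted(curve.probabilities),
            "probability": [curve.probabilities[k] for k in sorted(curve.probabilities)],
            "n_enumerated": [
                curve.n_enumerated.get(k, 0) for k in sorted(curve.probabilities)
            ],
        }
    ).to_csv(outdir / "fn_curve.tsv", sep="\t", index=False)
    report = {
        "N_L_min": nl_min,
        "N_A_chi_mos": na_t,
        "D_chi_mos": d_t,
        "n_fn_pairs": curve.n_pairs,
        "N_A_profile": _profile_dict(na_prof),
        "D_profile": _profile_dict(d_prof),
        "N_L_profile": _profile_dict(nl_profile) if nl_profile else None,
    }
    (outdir / "threshold_report.json").write_text(json.dumps(report, indent=2))
    _pairwise_frame(pairs).to_csv(outdir / "pairwise_all.tsv", sep="\t", index=False)
    return ThresholdSet(nl_min, na_t, d_t)


def run_pipeline(
    config: Union[dict, str, Path], seed: Optional[int] = None
) -> Path:
    """Execute the full analysis described by ``config``; returns the run dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(config.get("out", "igvar_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.get("seed", 0)

    truth = None
    if "simulate" in config:
        sim_cfg = SimulationConfig.from_dict({**config["simulate"], "seed": seed})
        dataset, truth = generate_dataset(sim_cfg)
        write_genotype_table(dataset, outdir / "genotypes.csv")
        write_locus_config(dataset.panel, outdir / "locus_config.yaml")
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    elif "input" in config:
        icfg = config["input"]
        dataset = read_genotype_table(
            icfg["genotype_csv"], icfg["locus_config"], icfg.get("policy", "strict")
        )
        if icfg.get("drop_loci"):
            dataset = dataset.drop_loci(icfg["drop_loci"])
    else:
        raise ValueError("config needs a 'simulate' or an 'input' section")

    tcfg = config.get("thresholds", {})
    mode = tcfg.get("mode", "fit")
    if mode == "fixed":
        thresholds = ThresholdSet(
            tcfg.get("N_L_min", 9),
            tcfg.get("N_A_chi_mos", 4),
            tcfg.get("D_chi_mos", 0.12),
        )
    elif mode == "fit":
        thresholds = _fit_thresholds(dataset, tcfg, outdir)
    else:
        raise ValueError(f"unknown thresholds.mode {mode!r}")

    classifications, excluded = classify_dataset(dataset, thresholds)
    intra_pairs = [p for c in classifications for p in c.pairs]
    _pairwise_frame(intra_pairs).to_csv(
        outdir / "pairwise_intracolonial.tsv", sep="\t", index=False
    )
    classification_frame(classifications).to_csv(
        outdir / "classification.tsv", sep="\t", index=False
    )

    sens = sensitivity_analysis(
        dataset, thresholds, d_alternatives=tcfg.get("d_alternatives", ())
    )
    sens.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
    shared_mlg_across_colonies(dataset, classifications).to_csv(
        outdir / "shared_mlgs.tsv", sep="\t", index=False
    )

    summaries = {}
    tests = {}
    for by in ("site", "group"):
        summarize(classifications, by=by).to_csv(
            outdir / f"summary_by_{by}.tsv", sep="\t", index=False
        )
        try:
            p, method, table = homogeneity_test(classifications, by=by, seed=seed)
            tests[by] = {"p_value": p, "method": method, "table": table.to_dict()}
        except ValueError as exc:
            tests[by] = {"error": str(exc)}
    (outdir / "fisher_tests.json").write_text(json.dumps(tests, indent=2))

    if truth is not None:
        confusion, metrics = truth_confusion(classifications, truth)
        confusion.to_csv(outdir / "confusion.tsv", sep="\t")
        (outdir / "recovery.json").write_text(json.dumps(metrics, indent=2))

    manifest = {
        "igvar_version": __version__,
        "seed": seed,
        "thresholds": asdict(thresholds),
        "threshold_mode": mode,
        "n_colonies": len(dataset.colonies),
        "n_loci": len(dataset.panel),
        "excluded_colonies": excluded,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", outdir)
    return outdir
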