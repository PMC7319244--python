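"""Category summaries and between-group homogeneity tests.

Summaries count the five classification categories per stratum (site or
cluster) and collapse them to the three biologically distinct states —
invariable (invariable + possibly_variable), mosaic (mosaic +
possibly_chimeric) and chimeric — which are what the Fisher homogeneity
tests compare between strata.

``fisher_exact_rxc`` computes the exact conditional p-value of an r x c
contingency table (probability mass of all tables with the observed
margins whose hypergeometric probability does not exceed the observed
one).  Tables too large to enumerate fall back to a seeded Monte-Carlo
estimate over tables drawn from the same null.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .classify import CATEGORIES, ColonyClassification

__all__ = [
    "COLLAPSED",
    "summarize",
    "collapse_counts",
    "fisher_exact_rxc",
    "homogeneity_test",
]

logger = logging.getLogger(__name__)

COLLAPSED = {
    "invariable": "invariable",
    "possibly_variable": "invariable",
    "mosaic": "mosaic",
    "possibly_chimeric": "mosaic",
    "chimeric": "chimeric",
}
COLLAPSED_ORDER = ("invariable", "mosaic", "chimeric")


def summarize(
    classifications: Sequence[ColonyClassification],
    by: Optional[str] = None,
) -> pd.DataFrame:
    """Category counts and proportions per stratum plus an overall row.

    ``by`` is ``"site"``, ``"group"`` or None (overall only).  Adds the
    collapsed three-way counts and the variable fraction.
    """
    if not classifications:
        raise ValueError("no classifications")
    df = pd.DataFrame(
        {
            "stratum": [getattr(c, by) if by else "all" for c in classifications],
            "category": [c.category for c in classifications],
        }
    )
    strata = sorted(df["stratum"].unique()) if by else []
    rows = []
    for stratum in strata + ["all"]:
        sub = df if stratum == "all" else df[df["stratum"] == stratum]
        n = len(sub)
        row: dict = {"stratum": stratum, "n": n}
        for cat in CATEGORIES:
            k = int((sub["category"] == cat).sum())
            row[cat] = k
            row[f"p_{cat}"] = k / n
        for coll in COLLAPSED_ORDER:
            row[f"collapsed_{coll}"] = sum(
                row[cat] for cat in CATEGORIES if COLLAPSED[cat] == coll
            )
        row["variable_frac"] = 1.0 - (row["p_invariable"] + row["p_possibly_variable"])
        rows.append(row)
    return pd.DataFrame(rows)


def collapse_counts(
    classifications: Sequence[ColonyClassification],
    by: str,
    min_stratum_size: int = 3,
) -> pd.DataFrame:
    """Strata x collapsed-category contingency table for homogeneity tests.

    Strata with fewer than ``min_stratum_size`` colonies are excluded with
    a log entry (too small to test).
    """
    summary = summarize(classifications, by=by)
    summary = summary[summary["stratum"] != "all"]
    small = summary[summary["n"] < min_stratum_size]
    for s in small["stratum"]:
        logger.warning("stratum %s excluded from tests (< %d colonies)", s, min_stratum_size)
    summary = summary[summary["n"] >= min_stratum_size]
    table = summary.set_index("stratum")[
        [f"collapsed_{c}" for c in COLLAPSED_ORDER]
    ]
    table.columns = list(COLLAPSED_ORDER)
    return table


def _log_table_prob(table: np.ndarray, log_denom: float) -> float:
    """Log hypergeometric probability of a table given fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    return (
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - log_denom
        - gammaln(table + 1).sum()
    )


class _TooManyTables(Exception):
    pass


def _enumerate_pvalue(
    observed: np.ndarray, max_tables: int
) -> float:
    """Exact p by depth-first enumeration of all tables with the margins."""
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    n = observed.sum()
    log_denom = gammaln(n + 1)
    log_p_obs = _log_table_prob(observed, log_denom)
    r, c = observed.shape
    count = 0
    p_total = 0.0

    def recurse(i: int, col_left: np.ndarray, partial: list[np.ndarray]) -> None:
        nonlocal count, p_total
        if i == r - 1:
            last = col_left
            if (last < 0).any():
                return
            count += 1
            if count > max_tables:
                raise _TooManyTables
            table = np.vstack(partial + [last])
            lp = _log_table_prob(table, log_denom)
            if lp <= log_p_obs + 1e-7:
                p_total += float(np.exp(lp))
            return

        def fill(j: int, remaining: int, row: list[int]) -> None:
            if j == c - 1:
                if remaining > col_left[j]:
                    return
                full = np.array(row + [remaining])
                recurse(i + 1, col_left - full, partial + [full])
                return
            for v in range(min(remaining, col_left[j]) + 1):
                fill(j + 1, remaining - v, row + [v])

        fill(0, int(rows[i]), [])

    recurse(0, cols.copy(), [])
    return min(p_total, 1.0)


def _montecarlo_pvalue(
    observed: np.ndarray, reps: int, rng: np.random.Generator
) -> float:
    """Seeded Monte-Carlo p over permutations of individual-level labels."""
    r, c = observed.shape
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    n = int(observed.sum())
    log_denom = gammaln(n + 1)
    log_p_obs = _log_table_prob(observed, log_denom)
    row_of = np.repeat(np.arange(r), rows)
    col_labels = np.repeat(np.arange(c), cols)
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - log_denom

    extreme = 0
    chunk = max(1, min(reps, 20000))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        # permute column labels within each replicate
        perms = np.argsort(rng.random((m, n)), axis=1)
        cells = row_of[None, :] * c + col_labels[perms]
        counts = np.zeros((m, r * c), dtype=np.int64)
        idx = np.arange(m)[:, None] * (r * c) + cells
        np.add.at(counts.reshape(-1), idx.ravel(), 1)
        lps = const - gammaln(counts + 1).sum(axis=1)
        extreme += int((lps <= log_p_obs + 1e-7).sum())
        done += m
    return (1 + extreme) / (1 + reps)


def fisher_exact_rxc(
    table,
    max_tables: int = 500_000,
    mc_reps: int = 100_000,
    seed: Optional[int] = 0,
) -> tuple[float, str]:
    """Fisher's exact test of independence for an r x c table.

    Returns ``(p_value, method)`` where method is ``"exact"`` (full
    enumeration of tables with the observed margins) or ``"monte-carlo"``
    (seeded, ``mc_reps`` replicates) when enumeration would exceed
    ``max_tables``.  Zero-margin rows/columns are dropped first.
    """
    observed = np.asarray(table, dtype=np.int64)
    if observed.ndim != 2 or (observed < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    observed = observed[observed.sum(axis=1) > 0][:, observed.sum(axis=0) > 0]
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        return 1.0, "degenerate"
    try:
        return _enumerate_pvalue(observed, max_tables), "exact"
    except _TooManyTables:
        rng = np.random.default_rng(seed)
        p = _montecarlo_pvalue(observed, mc_reps, rng)
        logger.info("fisher_exact_rxc: Monte-Carlo fallback (%d reps)", mc_reps)
        return p, "monte-carlo"


def homogeneity_test(
    classifications: Sequence[ColonyClassification],
    by: str,
    seed: Optional[int] = 0,
    **kwargs,
) -> tuple[float, str, pd.DataFrame]:
    """Fisher test of the collapsed category distribution across strata."""
    table = collapse_counts(classifications, by=by)
    p, method = fisher_exact_rxc(table.to_numpy(), seed=seed, **kwargs)
    return p, method, table
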