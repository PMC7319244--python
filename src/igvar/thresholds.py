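"""Data-driven decision thresholds.

Two thresholds control the classification cascade:

* ``N_L_min`` — the minimum number of comparable loci required to call a
  colony confidently invariable (or confidently mosaic).  It is selected
  from a *false-negative curve*: for pairs known to be variable at the
  full panel, the probability that removing loci down to a given ``N_L``
  hides every difference.  The smallest ``N_L`` whose false-negative
  probability stays at or below ``max_fn`` (default 20%) is the threshold.

* ``N_A_chi_mos`` / ``D_chi_mos`` — the mosaicism/chimerism cutoffs,
  located at the *first antimode* (the valley between the somatic-mutation
  mode and the distinct-genet mode) of the pairwise ``N_A`` and ``D``
  distributions among complete, intracluster MLG pairs.

Antimodes of integer-valued indices come from the exact histogram, with
plateaus reported as intervals (e.g. "between 4 and 5"); antimodes of the
continuous Bruvo distance come from a Gaussian KDE (Silverman bandwidth by
default) scanned on a dense grid.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import gaussian_kde

from .distances import PairwiseComparison
from .model import MultilocusGenotype

__all__ = [
    "ModeProfile",
    "ThresholdSet",
    "FalseNegativeCurve",
    "find_modes_antimodes",
    "false_negative_curve",
    "fn_probability_closed_form",
    "select_NL_threshold",
    "select_chi_mos_thresholds",
]

logger = logging.getLogger(__name__)

#: an extremum location: a point, or an (lo, hi) plateau interval
Location = Union[float, tuple[float, float]]


@dataclass
class ModeProfile:
    """Ordered local maxima (modes) and minima (antimodes) of a distribution."""

    modes: list[tuple[Location, float]]
    antimodes: list[tuple[Location, float]]
    kind: str  # "integer" | "continuous"
    bandwidth: Optional[float] = None

    @property
    def first_antimode(self) -> Optional[Location]:
        """Lowest-location local minimum flanked by two modes, if any."""
        return self.antimodes[0][0] if self.antimodes else None


@dataclass(frozen=True)
class ThresholdSet:
    """The fitted (or user-supplied) decision thresholds."""

    N_L_min: int
    N_A_chi_mos: int
    D_chi_mos: float

    def __post_init__(self) -> None:
        if self.N_L_min < 1:
            raise ValueError("N_L_min must be >= 1")
        if self.N_A_chi_mos < 1:
            raise ValueError("N_A_chi_mos must be >= 1")
        if not (0.0 < self.D_chi_mos < 1.0):
            raise ValueError("D_chi_mos must be in (0, 1)")


def _runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Compress a sequence into (start_idx, end_idx, value) runs."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i - 1, float(values[start])))
            start = i
    return runs


def _extrema_from_runs(
    runs: list[tuple[int, int, float]], locs: np.ndarray
) -> tuple[list, list]:
    """Interior plateau-aware local maxima/minima over run-compressed values."""
    modes, antimodes = [], []
    for k in range(len(runs)):
        s, e, v = runs[k]
        left = runs[k - 1][2] if k > 0 else None
        right = runs[k + 1][2] if k < len(runs) - 1 else None
        loc: Location
        loc = float(locs[s]) if s == e else (float(locs[s]), float(locs[e]))
        is_max = (left is None or left < v) and (right is None or right < v)
        is_min = left is not None and right is not None and left > v and right > v
        if is_max:
            modes.append((loc, v))
        elif is_min:
            antimodes.append((loc, v))
    return modes, antimodes


def _prune_minor_modes(
    modes: list, antimodes: list, min_density_frac: float
) -> tuple[list, list]:
    """Drop modes whose density is negligible next to the global maximum.

    A Gaussian KDE grows tiny bumps around stray tail observations; these
    are not evidence of a second population, so a mode below
    ``min_density_frac`` of the tallest mode is removed together with the
    shallower of its adjacent antimodes (merging the two valleys).
    """
    if not modes:
        return modes, antimodes
    extrema = sorted(
        [(loc if not isinstance(loc, tuple) else loc[0], d, "M") for loc, d in modes]
        + [(loc if not isinstance(loc, tuple) else loc[0], d, "A") for loc, d in antimodes]
    )
    peak = max(d for _, d, k in extrema if k == "M")
    changed = True
    while changed:
        changed = False
        mode_idx = [i for i, e in enumerate(extrema) if e[2] == "M"]
        if len(mode_idx) <= 1:
            break
        for i in mode_idx:
            if extrema[i][1] < min_density_frac * peak:
                neighbours = [
                    j for j in (i - 1, i + 1) if 0 <= j < len(extrema)
                ]
                drop = max(neighbours, key=lambda j: extrema[j][1], default=None)
                for j in sorted({i, drop}, reverse=True):
                    extrema.pop(j)
                changed = True
                break
    keep_modes = {(loc, d) for loc, d, k in extrema if k == "M"}
    keep_antis = {(loc, d) for loc, d, k in extrema if k == "A"}
    return (
        [m for m in modes if ((m[0] if not isinstance(m[0], tuple) else m[0][0]), m[1]) in keep_modes],
        [a for a in antimodes if ((a[0] if not isinstance(a[0], tuple) else a[0][0]), a[1]) in keep_antis],
    )


def find_modes_antimodes(
    values: Sequence[float],
    kind: str = "integer",
    bandwidth: Optional[Union[str, float]] = None,
    grid_size: int = 1000,
    weights: Optional[Sequence[float]] = None,
    min_density_frac: float = 0.05,
) -> ModeProfile:
    """Locate the modes and antimodes of an index distribution.

    ``kind="integer"`` scans the exact integer histogram; plateau antimodes
    are reported as intervals.  ``kind="continuous"`` scans a Gaussian KDE
    (``bandwidth`` as in :func:`scipy.stats.gaussian_kde`; default
    Silverman) on ``grid_size`` points; KDE modes below
    ``min_density_frac`` of the tallest mode are discarded as tail noise.
    A unimodal input yields an empty antimode list and the caller must
    fall back to supplied thresholds.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")

    if kind == "integer":
        ints = values.astype(int)
        if not np.array_equal(ints, values):
            raise ValueError("integer kind requires integer values")
        lo, hi = ints.min(), ints.max()
        locs = np.arange(lo, hi + 1)
        counts = np.bincount(ints - lo, weights=weights, minlength=hi - lo + 1).astype(
            float
        )
        modes, antimodes = _extrema_from_runs(_runs(counts), locs)
        return ModeProfile(modes, antimodes, "integer")

    if kind != "continuous":
        raise ValueError(f"unknown kind {kind!r}")
    if np.ptp(values) == 0:
        return ModeProfile([(float(values[0]), math.inf)], [], "continuous")
    kde = gaussian_kde(values, bw_method=bandwidth or "silverman", weights=weights)
    bw = float(kde.factor * values.std(ddof=1))
    grid = np.linspace(values.min(), values.max(), grid_size)
    dens = kde(grid)
    modes, antimodes = _extrema_from_runs(_runs(dens), grid)
    modes, antimodes = _prune_minor_modes(modes, antimodes, min_density_frac)
    return ModeProfile(modes, antimodes, "continuous", bandwidth=bw)


@dataclass
class FalseNegativeCurve:
    """P(variable pair looks invariable | only N_L loci compared), per N_L."""

    probabilities: dict[int, float]
    n_pairs: int
    L_total: int
    n_enumerated: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nls = sorted(self.probabilities)
        probs = [self.probabilities[k] for k in nls]
        # keeping more loci can only expose more differences
        if any(b > a + 1e-12 for a, b in zip(probs, probs[1:])):
            raise AssertionError("false-negative curve is not non-increasing")

    def __getitem__(self, n_l: int) -> float:
        return self.probabilities[n_l]


def fn_probability_closed_form(d: int, n_l: int, L_total: int) -> float:
    """P(a pair differing at exactly d of L_total loci shows no difference
    when a uniformly random subset of n_l loci is compared).

    The kept subset must avoid all d differing loci:
    ``C(L_total - d, n_l) / C(L_total, n_l)``.
    """
    if not (0 <= n_l <= L_total):
        raise ValueError("n_l out of range")
    if n_l > L_total - d:
        return 0.0
    return math.comb(L_total - d, n_l) / math.comb(L_total, n_l)


def _differing_loci(mlg_a: MultilocusGenotype, mlg_b: MultilocusGenotype) -> list[int]:
    out = []
    for i, (ga, gb) in enumerate(zip(mlg_a.genotypes, mlg_b.genotypes)):
        if ga is None or gb is None:
            raise ValueError("false-negative input pairs must be complete")
        if sorted(ga) != sorted(gb):
            out.append(i)
    return out


def false_negative_curve(
    variable_pairs: Sequence[tuple[MultilocusGenotype, MultilocusGenotype]],
    L_total: Optional[int] = None,
    enumeration_limit: int = 10**6,
) -> FalseNegativeCurve:
    """Locus-removal false-negative probability for each N_L in 1..L_total.

    Every input pair must be complete at all ``L_total`` loci and variable.
    Removal combinations are enumerated exhaustively while
    ``C(L_total, L)`` stays within ``enumeration_limit``; beyond that the
    per-pair closed form is used (exact, because a pair stays detectable
    iff at least one of its differing loci survives).
    """
    if not variable_pairs:
        raise ValueError("no input pairs")
    if L_total is None:
        L_total = len(variable_pairs[0][0].panel)
    diff_sets = []
    for a, b in variable_pairs:
        if len(a.panel) != L_total:
            raise ValueError("pair panel size != L_total")
        d = _differing_loci(a, b)
        if not d:
            raise ValueError("input pair is not variable (no differing locus)")
        diff_sets.append(frozenset(d))

    probs: dict[int, float] = {}
    enumerated: dict[int, int] = {}
    for n_l in range(1, L_total + 1):
        n_combos = math.comb(L_total, n_l)
        if n_combos <= enumeration_limit:
            miss = 0
            for kept in combinations(range(L_total), n_l):
                kept_set = set(kept)
                miss += sum(1 for ds in diff_sets if not (ds & kept_set))
            probs[n_l] = miss / (n_combos * len(diff_sets))
            enumerated[n_l] = n_combos
        else:
            probs[n_l] = float(
                np.mean(
                    [
                        fn_probability_closed_form(len(ds), n_l, L_total)
                        for ds in diff_sets
                    ]
                )
            )
            enumerated[n_l] = 0
    return FalseNegativeCurve(probs, len(variable_pairs), L_total, enumerated)


def select_NL_threshold(
    curve: FalseNegativeCurve,
    NL_distribution: Optional[Sequence[int]] = None,
    max_fn: float = 0.20,
) -> tuple[int, Optional[ModeProfile]]:
    """Smallest ``N_L`` whose false-negative probability is <= ``max_fn``.

    If the N_L distribution over invariable-colony comparisons is supplied,
    its mode profile is returned alongside for diagnostic concordance with
    the curve-based choice (its first antimode should sit near the
    threshold).
    """
    if not (0.0 < max_fn < 1.0):
        raise ValueError("max_fn must be in (0, 1)")
    for n_l in sorted(curve.probabilities):
        if curve.probabilities[n_l] <= max_fn:
            profile = None
            if NL_distribution is not None:
                profile = find_modes_antimodes(NL_distribution, kind="integer")
            return n_l, profile
    raise ValueError(
        f"no N_L in 1..{curve.L_total} reaches a false-negative probability "
        f"<= {max_fn}; a larger locus panel is needed"
    )


def _antimode_floor(loc: Location) -> int:
    lo = loc[0] if isinstance(loc, tuple) else loc
    return int(math.floor(lo))


def select_chi_mos_thresholds(
    comparisons: Sequence[PairwiseComparison],
    bandwidth: Optional[Union[str, float]] = None,
    grid_size: int = 1000,
) -> tuple[int, float, ModeProfile, ModeProfile]:
    """Mosaic/chimera cutoffs from the first antimodes of N_A and D.

    Only evaluable intracolony/intracluster comparisons of complete MLGs
    should be supplied (intercluster and inter-SSH pairs sit far beyond the
    viable-chimera range and would bias the first antimode).  Returns
    ``(N_A_chi_mos, D_chi_mos, na_profile, d_profile)``; a chimeric call
    later requires strict exceedance of both.
    """
    usable = [
        c
        for c in comparisons
        if c.evaluable and c.stratum in (None, "intracolony", "intracluster")
    ]
    if len(usable) < 2:
        raise ValueError("need at least 2 evaluable intracluster comparisons")
    na_values = [c.N_A for c in usable]
    d_values = [c.D for c in usable]
    na_profile = find_modes_antimodes(na_values, kind="integer")
    d_profile = find_modes_antimodes(
        d_values, kind="continuous", bandwidth=bandwidth, grid_size=grid_size
    )
    if na_profile.first_antimode is None or d_profile.first_antimode is None:
        raise ValueError(
            "distribution is unimodal; supply N_A_chi_mos/D_chi_mos manually"
        )
    na_thresh = _antimode_floor(na_profile.first_antimode)
    d_loc = d_profile.first_antimode
    d_thresh = float(d_loc[0] if isinstance(d_loc, tuple) else d_loc)
    logger.info(
        "fitted thresholds: N_A_chi_mos=%d, D_chi_mos=%.4f (KDE bandwidth %.4g)",
        na_thresh,
        d_thresh,
        d_profile.bandwidth or float("nan"),
    )
    return na_thresh, d_thresh, na_profile, d_profile
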