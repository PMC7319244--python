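# Methods

## Model and assumptions

The unit of observation is a colony sampled at `n ≥ 2` nubbins, each
genotyped at a fixed panel of diploid microsatellite loci. The package
assumes:

- the cluster/species label of a colony is supplied as metadata (it is
  produced upstream by assignment software and is not re-estimated here);
- microsatellite alleles evolve either by arbitrary allele replacement
  (IAM, captured by `N_A`) or by single-repeat steps (SMM, captured by
  Bruvo's `D`); using both indices hedges against loci that violate the
  strict stepwise model;
- mosaic differences are small (one or two alleles, one or two repeat
  steps), chimeric differences resemble a draw of two independent genets
  from the same cluster — hence the pairwise distance distribution among
  complete same-cluster MLGs is bimodal and its first antimode separates
  the two processes;
- missing data arise per locus and make a comparison *less informative*
  rather than different: all indices are computed over comparable loci
  only.

## Distances

`N_A` uses the per-locus multiset intersection, so a shared homozygote
against a heterozygote contributes 1, not 0 or 2. `D` pairs the two
alleles of a locus by the cheaper of the two possible bijections
(the standard treatment for known diploid ploidy); an exhaustive
bijection minimiser (`bruvo_distance_bruteforce`) is kept as an
independent oracle and the equivalence is property-tested. `D` divides by
`2·N_L` (comparable loci), not by twice the panel size: restricting to
loci that amplified in both genotypes is what keeps missingness from
deflating the distance. A pair with `N_L = 0` carries an explicit
`evaluable = False` flag instead of NaN values.

Alleles are stored as integer repeat counts. bp-sized input is converted
at read time against a per-locus ladder (`size = offset + motif ×
repeat`): under the default `strict` policy an off-ladder size is an
error; under `tolerant` the modal residue class anchors the ladder and
off-ladder sizes round to the nearest rung, half away from zero (a 1.5
step becomes 2). Half-called genotypes (one readable allele) are coerced
to missing for the locus, mirroring the wholesale treatment of ambiguous
peak profiles and avoiding a single-allele distance convention.
Homozygotes are always written as two equal values.

## Thresholds

**`N_L_min`.** For every pair that is complete at the full panel and
variable, all ways of removing `L` loci down to `N_L = L_total − L` are
enumerated; a removal "misses" the pair when it deletes every differing
locus. The curve value at `N_L` is the miss fraction pooled over pairs.
Enumeration is exact while `C(L_total, N_L) ≤ 10^6`; beyond that the
per-pair closed form `C(L_total − d, N_L)/C(L_total, N_L)` (for a pair
differing at `d` loci) is used, which is identical because detectability
depends only on which differing loci survive. The curve is asserted
non-increasing in `N_L` on every construction. `N_L_min` is the smallest
`N_L` whose false-negative probability is ≤ `max_fn` (default 0.20,
configurable); the antimode of the `N_L` distribution over invariable
comparisons is reported alongside as a diagnostic.

**`N_A_chi_mos` and `D_chi_mos`.** Fitted on evaluable pairwise
comparisons of complete MLGs within a cluster (intracolonial and
intercolonial pooled); intercluster and inter-SSH pairs are excluded —
they sit at distances plausibly corresponding to unviable fusions and
would drag the first antimode upward. For the integer `N_A` the exact
histogram is scanned; plateau antimodes are reported as intervals and the
threshold takes the floor of the interval (an antimode "between 4 and 5"
yields 4, with chimerism requiring `N_A > 4`). For the continuous `D` a
Gaussian KDE (Silverman bandwidth by default, overridable, recorded in
the threshold report) is evaluated on a 1,000-point grid and scanned for
interior minima. KDE modes below 5% of the tallest mode's density are
pruned together with their shallower flanking antimode: a kernel bump
around a few stray tail observations is not evidence of a second
population, and without pruning it would masquerade as the first
antimode. A unimodal distribution raises an error instructing the user to
supply thresholds manually.

## Classification cascade

Given `(N_L_min, N_A_chi_mos, D_chi_mos)`:
variable ⇢ any evaluable pair with `N_A ≥ 1` and `D > 0`;
non-variable colonies split into `invariable` / `possibly_variable` on
the minimum `N_L`; variable colonies are `chimeric` only when a pair
exceeds both cutoffs **strictly** — equality at either cutoff, and the
discordant case where only one index exceeds, resolve to mosaic;
non-chimeric variable colonies split into `mosaic` / `possibly_chimeric`
on the same `N_L_min` (one threshold for both splits, for parsimony).
`D`-cutoff comparisons use an absolute tolerance of 1e-9; small-`x`
Bruvo values are ratios of dyadic rationals and exactly representable in
binary, so the tolerance is safety only. A chimeric colony is flagged
`also_mosaic` when some pair shows `0 < N_A ≤ N_A_chi_mos` or
`0 < D ≤ D_chi_mos`; this is a flag, not a sixth category, so the five
categories always partition the retained colonies. A variable colony
whose differences all lie on one locus gets `qc_single_locus_flag`
(re-amplification advice surfaced as a flag; the wet-lab step itself is
out of scope). Colonies with no evaluable pair are excluded and logged.
Distinct MLGs per colony are counted as union-find components under
`N_A = 0`, which keeps the count order-invariant when missing data make
genotype identity non-transitive.

## Synthetic data

The generator emulates the sampling design the analysis targets: 3 sites
× 32 threefold-sampled colonies, 12 loci (motif lengths cycling 2/3/4
bp), two clusters in 85/15 proportion whose per-locus allele frequencies
are discretized normals over repeat counts (SD 1.5 repeats) offset by 5
repeat units between clusters — two parameters that control intracluster
diversity and intercluster divergence and reproduce the multimodal
pooled distance distribution. Defaults: mosaic rate 0.40 and chimera
rate 0.10 per colony (chosen to produce roughly half variable colonies
with chimeras a small minority, the regime the method addresses); mosaic
mutations hit 1–2 alleles (0.7/0.3) on distinct loci with 1–2 repeat
steps (0.8/0.2), so planted mosaics can never exceed an `N_A` of 2 per
mutated nubbin; a second independently mutated nubbin occurs with
probability 0.15, exercising the three-distinct-MLG path; chimera
partners are drawn within the founder's cluster and redrawn until
`N_A > 4` and `D > 0.12` (both configurable), then assigned 2+1 (or
1+1+1) to the nubbins; dropout is independent per locus and nubbin with
per-locus rates drawn uniformly from 11.8%–41.7%; an optional dominant
clone replaces founders with one fixed MLG at a configured frequency.
Everything derives from one seeded generator, so a seed reproduces the
dataset byte-for-byte.

What the generator does **not** emulate: correlated dropout within a
sample (degraded DNA knocks out many loci at once, which is why real
datasets retain more fully-complete MLGs at the same per-locus rates),
realistic allele-frequency spectra (mutation–drift equilibria, allele
ladders shared between clusters), linkage, genotyping error other than
dropout, and larval settlement/fusion dynamics. Passing recovery tests
therefore show the decision machinery is faithful to its rules, not that
the rules are robust to every real-data pathology.

## Reporting and tests

Summaries count the five categories per stratum and collapse them to
invariable/mosaic/chimeric for the homogeneity tests. Fisher's exact
test for r×c tables enumerates all tables with the observed margins
(depth-first, up to 500,000 tables) and sums the probability of tables
no more probable than the observed one; larger problems fall back to a
seeded Monte-Carlo estimate (default 100,000 replicates, method recorded
in the output). scipy's 2×2 Fisher test and the hypergeometric closed
form serve as oracles in the test suite. Strata with fewer than 3
colonies are excluded from tests.

## Problem sizes

The test suite validates the enumeration/closed-form identity over the
full `d ≤ 12, N_L ≤ 12` grid, recovers planted parameters on seeded runs
of 90–500 colonies, and checks the single-mutation miss rate at
`N_L = 9` against the closed form 0.25 on 2,000 simulated pairs; these
sizes give binomial standard errors well below the effects asserted
while keeping the default run fast.

## Known limitations

- Antimode locations on real data shift slightly with KDE bandwidth; the
  bandwidth used is recorded in the threshold report, and fixed
  thresholds can always be supplied instead.
- Exact clone matching requires complete MLGs; with heavy dropout few
  genotypes qualify and shared-MLG reporting loses power.
- The false-negative machinery assumes differing loci are exchangeable
  with respect to removal; differential per-locus dropout is reported
  but not modelled in the curve.
- The r×c exact test enumerates naively rather than via the network
  algorithm; for the 3×3 tables of study-sized datasets this is
  comfortably fast, but very large margins will trip the Monte-Carlo
  fallback.
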