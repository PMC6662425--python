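# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user may want to audit.

## Genotype model and filters

Genotypes are biallelic diploid calls stored as alternate-allele dosages
(0/1/2) with an explicit missing code. VCF input uses only the GT field;
phased and unphased calls are equivalent, half-calls become missing, and
multiallelic records are dropped (with a logged count) because every
downstream statistic assumes two alleles.

Two matrix-level filters are applied, in a fixed order:

1. individuals with **strictly more than** 75% missing calls are removed;
2. loci genotyped in **at least** 10% of the remaining samples are kept.

The order matters (locus presence is evaluated over retained individuals
only) and is therefore fixed and tested. Both thresholds are configurable.
Accepted missing tokens on read are `NA`, `.` and `-9`; `NA` is written.

## Diversity and the mating system

Per locus, H<sub>o</sub> is the heterozygote fraction among non-missing
calls and H<sub>e</sub> = 2p(1−p) from the alternate-allele frequency
p = (Σ dosage)/(2 · calls). Group summaries are means over loci with
standard errors sd/√L. The multilocus inbreeding coefficient is

    Fis = 1 − mean(Ho) / mean(He),

clamped to [−1, 1] with a warning. No small-sample correction is applied to
H<sub>e</sub> by default and monomorphic loci are included in both means;
both behaviours are togglable (`unbiased`, `include_monomorphic`). This is
the simplest defensible estimator; users comparing against Weir–Cockerham
style estimators should expect small differences. Published per-cluster
tables in this literature are sometimes internally inconsistent under this
convention (a reported cluster-level Fis need not equal
1 − H̄o/H̄e of the same row, because per-site estimates may have been
aggregated in an unspecified way); the formula above is what this package
computes and tests.

Under equilibrium partial selfing, the selfing rate follows from
F<sub>IS</sub> as S = 2Fis/(1 + Fis), with outcrossing T = 1 − S and inverse
Fis = S/(2 − S). Negative Fis yields a negative S and a warning rather than
an error — heterozygote excess is informative, not merely invalid.

A private allele is an allele (ref or alt) observed in exactly one cluster's
non-missing calls. With a single cluster every observed allele is vacuously
private; the vectorized implementation is property-tested against an
exhaustive double loop.

## AMOVA

Distances are squared Euclidean on dosage vectors. Missing data are handled
by pairwise-complete loci with the distance rescaled by L/L<sub>complete</sub>
(no imputation); sample pairs sharing no called locus cause the offending
samples to be excluded with a warning. The classical sums-of-squares
decomposition for unequal group sizes gives variance components
σ<sub>c</sub> (within localities), σ<sub>b</sub> (between localities within
regions) and σ<sub>a</sub> (between regions). Negative components are
reported as-is and flagged, never truncated. The ɸ statistics are

    phi_st = (σa + σb) / σtotal    (reported on the "within localities" row)
    phi_sc = σb / (σb + σc)        ("between localities")
    phi_ct = σa / σtotal           ("between regions")

P-values are upper-tail permutation tests with
p = (#{ɸ\* ≥ ɸ} + 1)/(B + 1): individuals permuted among all localities for
ɸ<sub>ST</sub>, individuals permuted among localities within their region
for ɸ<sub>SC</sub>, and whole localities permuted among regions for
ɸ<sub>CT</sub>. Default B = 999; a seed is required. Null-calibration of
the p-values is covered by a Kolmogorov–Smirnov test in the suite.

## Index of association

Per-locus distance between individuals is |dosage difference|/2; r̄d
standardizes the excess variance of the summed distance over its
no-association expectation by 2Σ<sub>j<k</sub>√(v<sub>j</sub>v<sub>k</sub>),
so perfectly duplicated loci give exactly 1. The permutation test shuffles
each locus's calls independently, which preserves every per-locus distance
distribution (and hence V<sub>E</sub>) while destroying between-locus
association; the test is one-sided upper tail. Missing pairs are
pairwise-complete per locus with the summed distance rescaled to the full
locus count. The pair-distance computation is expressed as a handful of
matrix products (via |d| = d² − 2·[|d| = 2] for d ∈ {0, ±1, ±2}), so the
permutation test on 200 × 1,000 data takes seconds.

## Population structure

PCA operates on per-locus mean-imputed, centered dosages (optionally
scaled); a zero-variance matrix is flagged degenerate. The admixture model
minimizes ‖W ⊙ (X − QF)‖² where X is dosage/2, W masks observed entries
(missing calls are excluded from the objective, not imputed), rows of Q live
on the probability simplex and F ∈ [0, 1]. Optimization is block projected
gradient descent with fixed 1/L steps (L the block Lipschitz constant), so
the objective is provably non-increasing — asserted at every iteration.
Initialization is K-means on PCA scores; everything is deterministic given
the seed. This estimator is a deliberate, documented stand-in for spatial
Bayesian admixture samplers: the pipeline needs memberships and a cluster
count, not posterior samples, and no spatial prior is used.

**Choosing K.** A random 5% of observed calls is masked, the model is fit on
the rest, and squared prediction error on the masked entries is averaged
over repeats. In predominantly selfing data this error has *no minimum in
K*: beyond the true cluster number, extra components keep capturing real
family/lineage substructure (near-clonal selfing lines), so rules that look
for a minimum — including minimum-plus-one-standard-error — degenerate to
the largest K tried. K is therefore chosen by an explicit plateau rule,
mirroring how log-probability curves are read in practice: K grows while an
additional cluster still improves the mean masked-prediction error by at
least 10% of the baseline (K = 1) error, and stops at the plateau. The 10%
threshold is the one tunable of this rule (`min_relative_gain`); on
study-scale three-introduction simulations it selects K = 3 in ≥ 9/10 seeded
repetitions, K = 1 on panmictic data and K = 2 on two-population fixtures.

## Introduction inference

Rare variants are loci with 0 < MAF < 0.10 (strict; monomorphic loci are
never rare). A rare variant segregates at a site if at least one copy of its
(globally defined) minor allele is observed there. Site density is the
segregating count divided by the number of loci with any data at the site,
making sites with different missingness comparable; raw counts are also
reported.

The density surface is interpolated by ordinary kriging without a trend
surface: covariances come from an exponential variogram
γ(h) = nugget + psill·(1 − e^(−h/range)), fitted to the empirical
semivariogram by weighted least squares (weights √bin-count) unless
parameters are supplied. The kriging system with a Lagrange multiplier
enforces weights summing to one (asserted at every node); with zero nugget
the predictor interpolates the observations exactly. Duplicate site
coordinates make the system singular; the default policy jitters
coordinates by ~10⁻⁵ degrees (configurable to raise instead). Distances are
haversine great-circle kilometres (Earth radius 6,371 km) on WGS84 decimal
degrees; the default grid spans the site bounding box padded by 0.25° at
0.05° spacing.

Decay of density with distance from a putative origin is summarized by a
LOWESS fit (tricube-weighted local linear regression, span 0.75) plus a
Spearman rank correlation — a deliberately assumption-light monotonicity
summary.

**Iterative peeling.** Each round flags rare variants on the current matrix,
finds the peak-density site (ties break lexicographically), records the
majority cluster of that site as the most recent remaining introduction,
then removes that cluster's samples together with every locus whose minor
allele is private to it (default) or, behind a flag, every rare locus
segregating in it. The private-allele rule is the tighter operationalization
of "removing a cluster's rare variants": it deletes exactly the variation
that the focal introduction brought and nothing shared. Rounds are ordered
newest-introduction-first because recency preserves rare variation.
Termination is guaranteed: each round removes one cluster, and a round that
would remove no loci halts with a logged reason.

## Range expansion and the lag test

Occurrence records are binned into ~1 km² cells by rounding latitude and
longitude to the nearest hundredth of a degree; ties round half away from
zero, implemented with decimal arithmetic so results do not depend on the
platform's float rounding mode. A cell's first year is the minimum record
year. The accumulation curve counts cells first occupied by each calendar
year (zero-new years included).

The lag test regresses log₁₀ cumulative occupied cells on year over years
with non-zero occupancy (log of zero is undefined; the treatment of empty
years is a documented choice). Exponential, lag-free spread is exactly
log-linear, so slope b, R², F = (n−2)R²/(1−R²) with df (1, n−2) and p are
reported as diagnostics; the lag verdict itself is left to the caller. A
complementary hinge model a + b·max(0, year − τ) is fitted over all
candidate breakpoints and compared by AIC (ΔAIC > 2 favouring the lag
model).

## Synthetic data

The generator exists so that every stage has a ground-truthed input at the
scale the pipeline targets. Defaults: 744 individuals, 52 sites, 1,525 SNPs,
selfing rate 0.9, three introductions with origins at Malibu (1927, 36
sites, 60 private rare alleles), Palm Springs (1965, 10 sites, 150) and
Nipomo (2000, 6 sites, 300) — newest introduction carrying the most private
low-frequency variation, which is the signal peeling exploits.

Mechanics, per introduction:

* founder allele frequencies are drawn per locus from Beta(0.5, 0.5),
  independently across introductions (strong founder divergence);
* a founder population of 150 evolves 12 discrete generations under mixed
  mating (self with probability S, outcross otherwise), reaching the
  partial-selfing equilibrium Fis ≈ S/(2−S) = 0.818 (approach halves the
  distance each generation, so 12 generations suffice);
* the introduction's private rare alleles are then planted directly into
  the evolved pool at frequencies Uniform(0.02, 0.08), distributed across
  carriers at equilibrium homozygote/heterozygote proportions — they are
  standing variation the introduction arrived with, and planting after the
  burn-in means their survival is governed by the expansion process being
  studied, not by burn-in drift;
* sites spread by serial founder hops: each new site is seeded by 10
  founders drawn from a random established site, grows to 40 plants over 4
  generations, and sits at a Gaussian spatial offset (σ = 0.6°) from its
  source — so rare-variant density decays with hop count from the origin;
* individuals are sampled evenly across sites (~14 per site), then 15%
  of calls are dropped at random and a 2% stratum of individuals gets 85%
  dropout, emulating heavy, uneven missingness.

Occurrence records follow cumulative occupied cells = 10^(b·t) with
b = 0.0823/yr, anchored so the curve reaches `n_records` (default 2,900)
at the final year; each new cell contributes one dated record, with
coordinates diffusing outward from the origin. An exponential cannot span
both an arbitrary period and a fixed record count, so with no lag the first
occupied year falls log₁₀(n)/b ≈ 42 years before the end of the series;
with a lag the origin cell is planted at the start year and the curve stays
flat through the lag — the flat-then-exponential signature the breakpoint
test is designed to detect.

What the generator does **not** emulate: native-range demography, mutation
(the time scale is decades), realistic dispersal kernels, admixture between
introductions, collection-effort bias in occurrence records, and
genotyping-error structure beyond uniform dropout. Passing tests therefore
demonstrate correctness of the inference machinery under a favourable but
structurally faithful data-generating process, not robustness to every
artefact of real reduced-representation sequencing data.

## Numerical and reproducibility notes

* Every stochastic routine takes an explicit seed; identical seed + config
  gives bit-identical outputs, including serialized ground truth.
* Permutation p-values use the add-one convention (p ≥ 1/(B+1); never
  exactly zero).
* Pipeline JSON/TSV outputs are written at fixed float precision with no
  timestamps, so reruns are byte-identical.
* Simulation batteries in the test suite use 5–20 fixed seeds per property;
  the acceptance script uses 3–10 seeds per quantity. These sizes keep the
  full suite in a few minutes on one CPU while leaving comfortable margins
  on the seeded pass-rate assertions.

## Known limitations

* The Fis estimator is the ratio-of-means form without small-sample
  correction; site-level aggregation schemes from other software will not
  match it exactly.
* The admixture stand-in has no spatial prior and its K rule has one tuned
  threshold; very subtle clusters (pairwise Fst ≪ 0.05) may be folded into
  the plateau.
* Kriging assumes second-order stationarity and an exponential variogram by
  default; strongly anisotropic invasion fronts are not modelled.
* The peeling order is reliable when founder novelty is staggered (newer
  introductions genuinely richer in rare variants); simultaneous
  introductions of similar diversity give no recency signal to exploit.
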