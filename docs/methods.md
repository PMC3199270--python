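# Methods

This note records the statistical model behind each analysis stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model

A *population* is the set of strains of one species at one study site —
the unit of every test. Isolates are haploid, typed at a fixed marker
panel (12 microsatellite-like loci by default; 11-locus RFLP panels are
equally supported) and carry one mating-type idiomorph. Sites are sampled
on grid nets (74 points) or transects (11 points); `CUSTOM` geometries
cover anything else. Strains for which the mating-type assay amplified
both idiomorph fragments (`BOTH`) or failed (`UNKNOWN`) are retained in
the data model but excluded from ratio and spatial tests, with every
exclusion logged.

## Clone correction

Haplotypes are keyed by exact identity of the full allele vector; no
genetic-distance clustering is attempted. Two missing-data policies
exist because the analyses need different ones:

* `EXCLUDE_ISOLATE` — isolates with any missing allele are dropped before
  grouping. Used for the gametic-disequilibrium path, where a missing
  allele would corrupt the mismatch distribution.
* `EXACT_MATCH` — missing matches nothing; the isolate survives as its
  own haplotype. Used for the mating-type ratio path, where dropping a
  typed strain over one missing marker would discard information.

The representative of each haplotype is the lexicographically smallest
strain id: mating type is constant within a true clone, so the choice
cannot bias the ratio tests, but a deterministic rule is required for
reproducible output. Isolates with identical genotypes but different
mating types cannot be one clone; they are kept separate and a warning is
emitted rather than silently merged. Clone correction is idempotent and
invariant under row order.

## Mating-type ratio tests

The null is X ~ Binomial(n, ½) on the clone-corrected MAT1-1/MAT1-2
counts. One-sided p is the exact lower tail P(X ≤ min(n₁, n₂)); two-sided
doubles it, capped at 1 — at p = ½ this equals the minimum-likelihood
convention by symmetry. Two-sided is the default (the appropriate test of
a 1:1 null); the one-sided option exists because published per-population
significance flags in this literature are often only consistent with
one-sided testing (e.g. a 13:5 split flagged significant has two-sided
p ≈ 0.096, one-sided ≈ 0.048).

Populations with fewer than 10 haplotypes report counts without a test
(`min_mlh = 10`). Species below 3% of the whole collection are pooled
across sites into a single `Global` population before clone correction,
because their per-site samples are uninformative alone. The Bonferroni
family defaults to the number of populations actually tested in the run;
per-family alternatives can be built by calling `ratio_test_counts` with
an explicit `TestFamily`.

## Index of association

For all n(n−1)/2 isolate pairs, K = number of mismatched loci. V_O is the
population variance (divide by the number of pairs; the n−1 denominator
is available via a flag) of K. V_E = Σ_j h_j(1 − h_j) with the plug-in
gene diversity h_j = 1 − Σ_i p̂²_ij; the n/(n−1) unbiased correction is a
flag. I_A = V_O/V_E − 1. Isolates with missing data are dropped before
pair enumeration; at least 3 isolates and one polymorphic locus are
required (V_E = 0 raises rather than returning a meaningless value).

**Significance** is assessed by permutation rather than a parametric
variance approximation: each replicate independently shuffles the allele
column of every locus among isolates. This preserves every allele
frequency (hence V_E exactly) and destroys inter-locus association —
precisely the null of gametic equilibrium, with no distributional
assumption. p = (1 + #{I_A_perm ≥ I_A_obs}) / (n_perm + 1); ties count
against rejection. Default n_perm = 999; fewer than 99 triggers an
underpowered warning; n_perm = 0 returns the statistic alone. Since V_E
is permutation-invariant, replicates only need the permuted V_O, which is
computed by an exact decomposition into per-locus and locus-pair mismatch
probabilities (joint allele counts via vectorized bincounts) rather than
by materializing all pairwise comparisons; the two routes are asserted
equal to 1e−10 in the tests.

**Finite-sample bias.** Even under perfect equilibrium the statistic has
a small negative bias of order 1/n (sample pairs overlap, and plug-in
diversities are biased): at n = 50, 10 loci with 4 equifrequent alleles
the mean over 200 simulations is ≈ −0.04. This is a property of the
classic statistic, not of this implementation; the permutation test is
exactly calibrated regardless (measured type-I rate ≈ 0.05 at α = 0.05),
and the bias is negligible against clonal signals of order 1.

**Randomness.** One global seed; each population derives an independent
substream by hashing its (species, site) key with SHA-256, so results are
identical regardless of execution order or parallelism.

## Spatial association

Occupancy runs on the *raw* (not clone-corrected) collection: physical
co-occurrence concerns thalli in the ground, and one clone spanning two
grid points is genuine spatial structure. Every grid point of the site's
sampled universe is classified into exactly one of {only MAT1-1, only
MAT1-2, both, neither}; the "neither" cell uses the full grid (74 or 11
points). Q = (ad − bc)/(ad + bc) on that 2×2 table; Q = +1 iff the types
never occur apart, −1 iff they never co-occur; ad + bc = 0 is reported as
undefined rather than coerced. The chi-square test is the standard 1-df
Pearson statistic on the same table, Yates correction off by default
(flag available). Historical per-population Q and chi-square values in
this literature are generally not reconstructible from published summary
columns (the universe of points behind them is unstated), so correctness
here is guaranteed against closed forms and an independent
contingency-table oracle instead. Per site, only the `top_k = 2` most
abundant species are analyzed, ties kept.

## Selection LRTs

The package consumes site-model fit tables (gene, model, log-likelihood,
gene-wide ω, site-class mixtures, beta parameters); it does not fit codon
models — that is CODEML's job, and the fits for the three MAT genes ship
as packaged data. Sanctioned comparisons and degrees of freedom: M0–M3
(4), M1a–M2a (2), M7–M8 (2). 2Δλ = 2(lnL_alt − lnL_null), floored at zero
with a warning when fits converged inconsistently; p from the χ² upper
tail. When comparing against published 2Δλ values a tolerance of ±0.001
is appropriate, because printed log-likelihoods are rounded to 4 decimals.
Site-class proportion sums are validated (±1e−3) for the full mixtures
M1a/M2a/M3 only; published M8 rows conventionally print the beta-component
weight inconsistently, so M8's positive-class weight is taken as printed
and not sum-checked. Mixture-boundary caveats of these LRTs (the null on
the boundary of the alternative) are acknowledged but the conventional χ²
reference is used, as is standard practice.

## Synthetic-data generator

The generator produces the structure the analyses assume, not a
demographic model of the real fungi. Isolates are created sequentially:
with probability c (clonality) the new isolate copies a uniformly chosen
*earlier isolate* — inheriting its mating type and lineage, mutating each
locus to a brand-new allele with probability μ (infinite-alleles), and
landing within `patch_spread` grid points of its source — otherwise it is
an independent recombinant with each locus drawn from the founder allele
frequencies (exact linkage equilibrium), mating type Bernoulli(mat_skew),
uniform placement. Copying isolates rather than lineages makes abundant
clones more likely to be copied again, which reproduces the strongly
skewed strain-per-haplotype ratios seen in real collections. Missing
data, dual-amplification (`BOTH`) and typing-failure (`UNKNOWN`) outcomes
are injected at configurable rates (default 0).

Defaults — 50 isolates, 12 loci, 4 equifrequent alleles, c = 0,
mat_skew = 0.5, grid-net geometry, patch_spread = 1 — sit inside the
envelope of real surveyed populations (tens to ~200 strains collapsing to
3–87 haplotypes). Collections draw species abundances from a Zipf
distribution (exponent 1), matching the hyperbolic few-abundant /
many-rare shape of endophyte communities; about a dozen species are
needed before the rarest falls under the 3% pooling threshold.

What the generator does **not** emulate: population subdivision and
admixture, selection on markers, stepwise microsatellite mutation,
geographic differentiation between sites, and genotyping error beyond
random missingness. Tests passing on synthetic data therefore demonstrate
the correctness and calibration of the statistics, not robustness to
those real-world complications — admixture in particular is a known
alternative cause of gametic disequilibrium that this pipeline flags but
cannot explain.

## Study sizes used in the standing checks

Chosen once as the package's own verification design:

* Type-I error of the I_A permutation test: 1000 simulations at n = 50,
  10 loci, 4 alleles, with n_perm = 199 per simulation (p-value
  granularity 0.005; expected level exactly 10/200 = 0.05 under
  exchangeability). Acceptance band [0.03, 0.07].
* Clonality response: 200 replicates at each c ∈ {0, 0.3, 0.6, 0.9} with
  μ = 0.05; mean clone-corrected I_A must increase strictly in c. μ > 0
  is intrinsic here: with μ = 0, clone correction removes every trace of
  clonal structure and I_A has nothing to detect.
* Lineage recovery: with μ = 0 and no missing data, clone correction must
  recover the planted lineage count exactly (collision probability of two
  independent 12-locus genotypes ≈ 6×10⁻⁸ per pair).
* Oracle equivalence: I_A against a naive pair-enumeration implementation
  at n ≤ 6, tolerance 1e−12; chi-square against an independent
  contingency-table implementation, tolerance 1e−10; exact binomial
  against arbitrary-precision integer tail sums.

## Known limitations

* I_A is the classic multilocus index; the standardized r̄_d variant and
  per-locus-pair LD decompositions are out of scope.
* Only Bonferroni correction is provided (raw p-values are reported so
  users can apply anything else downstream).
* Mixed marker panels within one population are rejected, not harmonized.
* The exact binomial test is conservative for small discrete counts; its
  measured rejection rate under the null at n = 40 is ≈ 0.04, not 0.05.
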