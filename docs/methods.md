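# Methods

## Scientific setting

Zimbabwe (Z) females of *Drosophila melanogaster* largely refuse to mate
with cosmopolitan (C) males, while every other pairing of the two
population types succeeds — incipient, asymmetric sexual isolation driven
by female choice. The measurable trait is therefore a property of the C
male genotype: the proportion of Z females that copulate with males of
that genotype within a fixed observation window. The package implements
the three complementary mapping designs used on this trait — an inbred
line panel association study, a single-generation extreme-QTL (pool-seq)
contrast, and a multi-generation selection experiment — together with the
quantitative genetics that motivates them and a forward simulator of the
designs themselves.

## Phenotype model and heritability

Replicate-level data are vials of `n_females` (5) virgin Z females with
10 males of one genotype; the response is the proportion mated. Variance
is partitioned by the one-way random-effects model on the untransformed
proportion scale

    y_ij = mu + g_i + e_ij,   g_i ~ N(0, sg2),  e_ij ~ N(0, se2)

fit by REML, with broad-sense heritability `H2 = sg2 / (sg2 + se2)`. A
logit scale is available behind a flag but is not the default: the trait
is conventionally analysed as a rate. The REML objective is profiled
down to the single ratio `gamma = sg2/se2` (block-diagonal covariance
with one random effect admits closed-form profiling of both variances),
minimised by a coarse log-spaced grid plus bounded scalar refinement;
`gamma = 0` is evaluated explicitly so the boundary is exact. On
balanced designs the estimator coincides with the ANOVA closed form
`sg2 = (MSB - MSW)/r`, which the tests assert to machine tolerance.
Significance of `sg2 = 0` uses the REML likelihood-ratio statistic
against the 50:50 mixture of a point mass at zero and chi-square(1), the
standard null for a variance component on the boundary.

Line means are unweighted replicate averages. Trait correlations are
Pearson correlations of line means over the inner join of line ids, with
the two-sided t test `t = r sqrt((n-2)/(1-r^2))`. Inversion karyotype
effects are one-way fixed-effects fits of line means on the three-level
class factor, reporting per-class least-squares means with t-based 95%
confidence intervals and contrasts of each non-standard class against
ST/ST on the pooled residual variance.

## Mixed-model association

Line means are first adjusted by OLS for *Wolbachia* infection (2
levels) and the karyotypes of the five major polymorphic inversions
(3-level class factors, not additive dosages, matching how karyotype
effects present); the adjusted phenotype is residual + grand mean. A
companion mode omits the inversion terms so variants inside inversions
can be interrogated. The association model is the single-variance-
component LMM `y = Xb + Zu + e`, `u ~ N(0, su2 K)`. K is the
centred-and-scaled cross-product `W W' / L` with centring `2p` and scale
`sqrt(2p(1-p))`; missing dosages are mean-imputed for K only. Note the
expected diagonal of K is 2, not 1, for a fully inbred panel (realized
dosage variance `4pq` against the Hardy–Weinberg scale `2pq`); the
overall scale of K is absorbed by the variance ratio and does not affect
tests. The LMM is solved spectrally: one eigendecomposition of K, REML
estimation of `delta = se2/su2` under the no-variant model, then
per-variant generalized least squares in the rotated basis with
two-sided Wald t tests (exact per-variant REML behind a flag; lines
missing the tested dosage are dropped from that variant via a reduced
solve). With K = I the procedure reduces exactly to per-variant OLS,
which the tests assert.

MAF filtering is strict (`maf > threshold`, folded, non-missing lines).
Variants are assigned to every gene whose interval, widened by a
configurable 1000 bp window, contains the position (1-based inclusive
coordinates throughout); unassigned variants are `intergenic`. Both the
candidate threshold (p < 1e-5) and the Bonferroni threshold are
reported; no FDR.

## Pooled-sequencing divergence (extreme QTL)

The frequency estimate from a pool of `n` diploid flies sequenced to
depth `c` has sampling variance `v = p(1-p)(1/(2n) + 1/c)`: chromosomes
drawn out of the source population, then reads drawn off the pool. The
divergence statistic between replicated groups is

    Z = (pbar2 - pbar1) / sqrt(V2 + V1),    p = 2 * Phi(-|Z|)

with per-replicate plug-in variances and within-group depth weights
`w_r = c_r / sum(c)`. Two denominators are implemented because the
printed form of the statistic is ambiguous about how the weights enter:

* `literal` — `V = sum_r w_r v_r` with the unweighted replicate mean.
  This is the statistic as printed, but for R replicates it estimates
  the *average per-replicate* variance, which exceeds the variance of
  the mean by a factor ~R; the test is therefore conservative by ~sqrt(R)
  in Z. Under the package's 4-vs-4 no-selection null its empirical
  type-I error is ~0 at alpha = 0.05.
* `delta` (default for replicated scans) — depth-weighted mean with the
  matching delta-method variance `V = sum_r w_r^2 v_r`. Empirically
  calibrated: type-I error 0.048/0.0068 at alpha 0.05/0.01 over 2500
  null variants (within binomial 99% bounds).

The two modes coincide exactly for one replicate per group, which covers
every single-pair comparison including the worked example
(p1 = 0.2, p2 = 0.4, n = 50, c = 100 → Z = 2.236). Degenerate sites:
replicates with zero coverage are dropped from that variant (the variant
is skipped, with a logged reason, if a whole group is uncovered); a
zero-variance site with equal group means has Z = 0, with unequal means
Z is clamped at a configurable |Z|max = 37 (the largest value whose
normal tail probability is still representable).

The multi-generation selection contrast has unpaired pools, so every
selected × control pair is tested as a single-replicate comparison and a
variant passes only if its weakest pair (largest p) clears the
threshold — a stringent minimal-difference rule whose brute-force
equivalent the tests check.

## Selection-response analysis

Selected replicate lines are expressed as deviations from the mean of
the contemporaneous control lines; one control exists from the start and
a second is split from it at generation 5, so the control mean averages
over whichever controls have data at each generation. Response is the
unweighted OLS slope of deviation on generation number (generation 0
included), per replicate and for the replicate average; by OLS linearity
the average slope equals the mean of replicate slopes on a shared grid.

## The forward simulator

The simulator generates the designs, not just their summary statistics:

* **Founders** — fully inbred lines, dosage 2 with probability equal to
  the variant's generating frequency. An inversion is a recombination-
  suppressed block: each line draws two latent arrangement haplotypes
  (giving ST/ST, ST/INV, INV/INV at Hardy–Weinberg proportions of the
  inversion frequency), block variants have their alt probability
  shifted by +0.5 on inverted haplotypes, producing the island-of-
  divergence LD between block content and karyotype that the inversion
  adjustment exists to handle. The single haplotype a residually
  heterokaryotypic line transmits is fixed at panel creation.
* **Advanced intercross** — generation 1 is the round-robin of founders
  (line *i* females × line *i*+1 males; exactly n founders F1
  genotypes), generation 2 a round-robin of consecutive F1 pairs,
  generation 3 seeds 10 bottles with one female and one male from each
  generation-2 cross, and from generation 4 each bottle receives 4
  females + 4 males from every bottle of the previous generation —
  census 800. Haplotypes are tracked as founder-origin labels on the
  variant grid (origins partition each haplotype by construction;
  segment boundaries are label run-lengths). Meiosis places Poisson
  crossovers at 2e-8 Morgans/bp on four 23-Mb arms, only in females
  (Drosophila males are achiasmatic), and discards crossovers inside an
  inversion block when the mother is heterokaryotypic. Egg-laying limits
  and larval competition are not modelled; maintenance sampling is
  uniform among adults.
* **Mating assay** — liability = centred additive genetic value + N(0,
  env) deviate; per-minute mating probability is
  `expit(intercept + slope * liability)`. Each minute every unmated male
  attempts with that probability and as many attempts succeed as females
  remain (winners uniform among attempters); pairs are removed, latency
  is the minute index, same-minute ties carry a seeded uniform
  tie-break. The default intercept (−6.2) makes an outbred base
  population mate at ~1/3 of females per hour, the observed starting
  point of the selection design; the hazard model itself is a package
  choice — no generative latency model is established for this assay,
  so simulated latencies are a stand-in. A discrete-time Markov chain on
  the number of matings per vial provides the exact expectation the
  Monte-Carlo tests compare against.
* **Truncation selection** — `first-k` / `k-fastest` rank maters by
  latency (operationally identical on a common clock; both are provided
  because the designs describe them differently), `k-random` samples all
  assayed males; shortfalls raise errors naming the deficit.
* **Pool-seq** — per site, alt reads ~ Binomial(depth, pool frequency);
  depth fixed or Poisson.
* **Line phenotypes** — Gaussian line effects and residuals on the
  proportion scale with clamping to [0, 1]; defaults (grand mean 0.05 at
  2 h, total sd 0.02) keep clamping rare so REML recovery is clean. The
  continuous modelled value is stored (as proportion × n_females), so
  downstream proportions reproduce the generating model exactly rather
  than being re-discretised onto a 1/5 grid.

What the generator does **not** emulate: demographic divergence between
Z and C populations, larval-stage selection, X-chromosome dosage in
males (a pool-ploidy flag exists), overdispersed sequencing error, or
assay-day environmental structure. Passing tests therefore demonstrate
the estimators' behaviour under their own assumptions at realistic
design sizes, not robustness to those real-data complications.

## Benchmark problem sizes and design choices

The benchmark suite (`matescan.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) uses the designs'
true sample sizes — 205 lines × 10 replicates, 40 founders, census 800,
500 assayed / 50 fastest / 50 random / 4 replicate pools of 50 flies,
first 40 of 300 over 18 generations with the 1-then-2 control history —
with variant grids of 400–2500 sites, the package's chosen scale for
replicated benchmarking; variant count does not enter the phenotypic
models. The no-selection null uses an intercross at generation 20, by
which LD has decayed enough that per-variant calibration is the
dominant behaviour. The extreme-QTL power benchmark plants five
equal-magnitude causal variants at intermediate frequency (alt frequency
0.3–0.7) explaining 90% of liability variance, with an assay slope of 2
and coverage 200: a deliberately strong-signal regime that verifies the
scan ranks true targets highly when signal exists. The 18-generation
selection benchmark uses liability heritability 0.27 with 20 causal
variants and the default assay.

## Known limitations

* REML here covers the one-random-effect models the analyses need; it is
  not a general mixed-model engine.
* The literal Z mode reproduces the printed statistic and is the right
  choice for single-pair comparisons, but should not be used for
  replicated groups when calibrated p-values matter; use `delta`.
* The all-pairs minimal-difference rule is intentionally stringent: with
  4 pairs, per-variant power is roughly the fourth power of single-pair
  power, so moderate frequency shifts at moderate coverage will not pass
  stringent thresholds.
* Gene annotation uses a simple windowed interval overlap; no
  transcript-aware consequence annotation.
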