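# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `colocbench`.

## Summary-statistics model and harmonization

All inputs are per-variant marginal association statistics (beta, se, MAF,
n) for one trait in one *cis* region, with z = beta/se. Coordinates are
1-based inclusive; the 2 Mb *cis* window around a TSS is implemented as
[tss − 10⁶ + 1, tss + 10⁶] so its width is exactly 2,000,000 bp (the
convention fixes endpoint ambiguity; only the total width is standard).
The TSS is strand-aware (start on +, end on −). Trait pairs are joined on
(chromosome, position) with allele alignment: a swapped ref/alt pair flips
the sign of the second trait's beta; incompatible allele pairs are dropped
with a logged count; strand-ambiguous (A/T, C/G) variants are kept as-is
with a logged count, because the simulated data contain no strand flips. A
(gene, protein) pair is skipped when fewer than 10% of the outcome
region's variants fall inside the exposure gene's *cis* window.

## Fine-mapping

`susie_rss` fits the sum-of-single-effects model to z-scores and an LD
correlation matrix R by iterative Bayesian stepwise selection: each of L
effects (default L = 10) is refit as a Bayesian single-variant regression
on the residualized z-vector, with inclusion weights α ∝ exp(lABF) and
posterior-mean effects shrunk by W/(W + se²·σ²). Iteration stops when the
largest change in any fitted single-effect mean falls below `tol`
(default 1e-4) or after `max_iter` = 200 sweeps.

Numerical choices:

- **Prior effect variance.** W = 0.0225 (prior sd 0.15) on the beta scale,
  the usual convention for inverse-normal-transformed quantitative traits,
  translated per-variant to the z scale as W/se². By default each effect's
  prior variance is additionally optimized every sweep by maximizing the
  single-effect marginal likelihood, and the effect is zeroed when no
  positive value beats the null. This is essential, not cosmetic: in
  regions with runs of near-perfect proxies a fixed-W fit can converge to
  a degenerate solution in which one signal is split across all L effects,
  each too weak to form a credible set. With
  `estimate_prior_variance=False` the fit uses the fixed W everywhere, and
  with L = 1 its inclusion vector is then exactly the softmax of the
  marginal Wakefield lABFs — the bridge that makes per-signal BF
  colocalization reduce to ABF colocalization on single-signal loci.
- **Residual variance** is fixed at 1 (standardized traits); a config
  switch enables crude re-estimation from the residual z-vector.
- **Conditioning.** R must be symmetric with unit diagonal; if a Cholesky
  factorization fails, a 1e-6 ridge is added once, and a conditioning
  error is raised if that is not enough.
- **Credible sets.** Per effect, the smallest α-prefix reaching 95%
  coverage; sets with minimum pairwise |r| below 0.5 are discarded (100
  sampled pairs when sets are large); duplicate sets from split effects
  are removed; survivors are ranked 1..K by decreasing maximum per-signal
  log BF. The lead variant is the member with the largest |z|, ties broken
  by position then identifier.

`wakefield_labf` implements lABF = ½(log(1 − r) + r·z²), r = W/(W + se²).
Applied row-wise to all-but-one conditional betas and SEs it yields
per-signal lABF rows usable wherever fine-mapped LBF rows are expected —
the route for conditional meta-analysis summary statistics.

## Colocalization

The enumeration methods sum over single-causal-per-trait configurations.
With per-variant log Bayes factors lbf_a, lbf_b and L1 = logsumexp(lbf_a),
L2 = logsumexp(lbf_b), L12 = logsumexp(lbf_a + lbf_b), the unnormalized
log-weights are S0 = 0, S1 = log p1 + L1, S2 = log p2 + L2,
S3 = log(p1·p2) + log(e^{L1+L2} − e^{L12}), S4 = log p12 + L12, and
PP0..PP4 is their softmax. `coloc_abf` feeds marginal Wakefield lABFs;
`coloc_bf_bf` substitutes one fine-mapped per-signal row per trait and is
evaluated for every signal pair, with identical priors (p1 = p2 = 1e-4,
p12 = 5e-6, no per-signal rescaling). A brute-force oracle that loops over
all M×M configurations in plain probability space verifies the
enumeration to 1e-10 in the tests. PP4 > 0.8 declares significance.

CLPP multiplies the two traits' per-variant inclusion probabilities and
sums over the exposure trait's credible set; variants absent from either
trait contribute zero; CLPP > 0.1 declares significance. The default uses
per-signal α rows (the credible-set decomposition); passing overall PIPs
instead is exposed as a config switch (`clpp_use_overall_pip`) because the
region-level variant is also in circulation and the two differ on
multi-signal loci.

Analysis universe: only protein-coding exposure genes are tested, and
outcome traits flagged as protein complexes are excluded, both as
annotation-driven filters.

## Mendelian randomization

Instruments come from significant per-signal colocalizations: a
(gene, protein, dataset) triplet is retained when ≥ 2 significant signal
pairs with mutually distinct exposure indices and distinct outcome indices
exist (selected greedily by decreasing PP4; distinctness prevents reusing
one signal twice, which would violate instrument independence). Each
pair's instrument variant is the shared variant maximizing the product of
the two α rows, and its marginal betas supply (bx, by).

- **IVW.** Ratios θ_j = by_j/bx_j with first-order weights
  v_j = se_by²/bx² or delta weights v_j = se_by²/bx² + by²·se_bx²/bx⁴;
  α̂ = Σθ_j/v_j / Σ1/v_j. The multiplicative random-effects model inflates
  the fixed SE by max(1, √(Q/(k−1))), Q = Σ(θ_j − α̂)²/v_j. All intervals
  use the 80% normal quantile 1.281552.
- **Robust adjusted profile score.** Standardized residuals
  t_j = (by_j − α·bx_j)/√(se_by² + α²se_bx² + τ²) enter a Tukey-biweight
  score (c = 4.685); α solves the weighted score equation and τ² a moment
  equation calibrated so Σψ(t)·t matches its null expectation
  E[ψ(Z)Z]. Two numerical points: the redescending score makes the τ²
  equation non-monotone (at τ² = 0 all residuals can exceed the cutoff and
  the score collapses), so the root is located by a log-grid scan for the
  rightmost sign change before Brent refinement; and the Tukey loss in α
  is flat away from the data, so α is profiled by a grid scan centred on
  the delta-weight IVW estimate before polishing. SEs are M-estimation
  sandwich variances (one-dimensional at the τ² = 0 boundary).
- **Hierarchical slope model (allelic spread).** α_j ~ N(α, τ²),
  by_j ~ N(α_j·bx_j, se_by²) with bx fixed, so marginally
  by_j ~ N(α·bx_j, se_by² + τ²bx_j²). The posterior is evaluated on an
  adaptive (α, τ) grid with trapezoidal marginalization — fully
  deterministic, no sampler. Priors are weakly informative and scaled to
  the data: α ~ N(0, (10s)²) with s the ratio magnitude scale, and
  τ ~ half-N(0, (2s_τ)²) with s_τ the ratio dispersion scale (spread of
  the per-instrument ratios plus their median SE). Fixed wide priors
  (e.g. τ ~ half-N(0, 5²)) were rejected: with the typical k = 2
  instruments the flat τ tail dominates the posterior and no concordant
  locus is ever significant, contradicting the intended behavior (tight
  intervals for concordant instruments with small SEs, wide intervals
  with large spread under discordance). Reported: posterior median of α,
  central 80% credible interval, posterior median of τ as the allelic
  spread.

## The synthetic-data generator

The generator emulates the statistical structure of a two-sample *cis*-QTL
benchmark: a small expression cohort and a large protein cohort drawn from
one population.

**Genotypes.** Haplotypes follow a first-order copy process: within a
block of `block_size` adjacent variants, each variant copies the previous
variant's allele on the same haplotype with probability ρ, else draws
fresh from its own frequency (uniform in `maf_range`); blocks are
independent. Diploid dosages are sums of two haplotypes; both cohorts come
from one pool, and the LD matrix is the empirical dosage correlation of
the pooled cohorts. The copy process yields valid discrete genotypes,
block structure, and an exact empirical LD matrix — unlike a Gaussian
threshold model.

**Phenotypes.** Additive effects with N(0,1) noise; each causal's beta is
scaled so it explains its configured fraction of total phenotypic
variance given its realized dosage variance (power comparable across
allele frequencies). The outcome phenotype is passed through a rank-based
inverse normal transform (Blom offset), emulating standard pQTL
processing.

**The benchmark catalog** (`simulate_benchmark_catalog`) builds one locus
per protein: a coding gene whose body contains every causal variant, plus
protein-coding neighbors at distinct TSS offsets (±60/±110/±160 kb).
Default study conditions, chosen to mirror the data regime the benchmark
describes and then frozen:

| parameter | default | rationale |
|---|---|---|
| variants per locus m | 150 at 1 kb spacing | a dense *cis* core region |
| ρ / block size | 0.99 / 15 | *cis* regions carry runs of near-perfect proxies; this is what disperses posterior mass across variants and separates CLPP from the BF methods |
| n_exp / n_out | 300 / 3,000 | expression cohorts of a few hundred vs. a plasma-proteome cohort of thousands |
| shared-signal exposure ve | log-uniform 0.09–0.25 | weak-but-fine-mappable to strong primary *cis*-eQTLs at n ≈ 300; the truth universe mirrors loci where fine-mapping yields purity-filtered sets |
| outcome ve | 0.3 × exposure ve | pQTL effects attenuated relative to eQTLs |
| secondary signal ve | 0.5 × primary | secondary signals are weaker, which is what limits multi-signal recall |
| pleiotropy rate | 0.5 | a neighbor gene shares the primary causal (co-regulation) |
| multi-signal rate | 0.6 | a second conditionally distinct shared causal |
| gene-specific eQTL rate | 0.3 | buffered eQTLs with no protein consequence, drawn stronger than the shared signal so they dominate the gene's marginal statistics |
| protein-specific pQTL rate | 0.2 | protein-altering variants with no expression effect, stronger than the shared signal |
| full co-regulation rate | 0.25 (conditional) | a co-regulated neighbor of a multi-signal locus shares *all* causal variants, each with its own effect size and direction — the confound that can mislead even multi-signal MR |

The trait-specific and fully co-regulated components are what give the
methods room to disagree: buffered eQTLs defeat the marginal ABF
enumeration (the gene's strongest signal is not the protein's), protein-
specific signals consume the first pQTL credible set, near-perfect proxies
dilute CLPP's inclusion-probability products, and fully co-regulated
neighbors with discordant per-signal effects are exactly the false
positives that fixed-weight IVW keeps and the overdispersion-robust
estimators reject.

**What the generator does not emulate:** realistic human LD maps and
recombination hotspots, allele-frequency spectra, imputation error and
panel mismatch between cohorts, trans effects, multiple aptamers per
protein, and tissue heterogeneity of eQTLs. Passing benchmarks here
therefore demonstrates correctness of the statistical machinery and the
direction of the method contrasts, not the numerical precision/recall
levels to expect on real cohorts — on real data every method is further
degraded by LD mismatch and measurement artifacts.

## Scoring

A predicted (protein, gene) pair is a true positive iff the gene codes
for the protein; a tested protein (≥ 1 purity-filtered outcome credible
set) with no true-positive prediction is a false negative. Precision is
computed over unique pairs pooled across datasets; recall's denominator
is all tested proteins for every method row, which makes the multi-signal
MR recalls structurally small; slope direction is assessed per
(gene, protein, dataset) triplet. The closest-gene baseline takes each
outcome credible set's lead variant and returns all protein-coding genes
tied at minimal gene-body (or TSS) distance, distance zero inside the
body, boundaries inclusive. The three-method colocalization comparison
restricts to the first outcome signal; the multi-signal and MR rows use
all signal pairs. Percentages are reported to one decimal, half-up.

## Problem sizes

The test suite and the acceptance script use deliberately scaled problem
sizes — 200 loci of 100 variants for credible-set coverage, 500 loci for
MR null calibration, a 40–60-protein catalog for the end-to-end ordering —
chosen so the full suite completes in minutes on one CPU while leaving the
Monte-Carlo margins comfortably wide of the thresholds they check.

## Known limitations

- The fine-mapping fitter targets the common summary-statistics regime
  (in-sample LD, one causal per effect); it does not implement
  out-of-sample LD corrections.
- The MR estimators assume uncorrelated instruments, which the
  distinct-signal-index rule approximates but does not guarantee under
  residual LD between credible sets.
- The hierarchical slope model fixes bx at its observed values; exposure
  sampling error is absorbed into the spread parameter rather than
  modeled as measurement error.
- CLPP's outcome-side inclusion vector uses the same per-signal
  decomposition as the exposure; the literature is split between
  per-signal and region-level PIPs, hence the config switch.
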