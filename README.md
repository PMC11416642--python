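# colocbench

Benchmarking colocalization and *cis*-Mendelian-randomization methods for
target-gene prioritization, on simulated QTL loci with known ground truth.

## The problem

A *cis*-pQTL — a variant associated with a plasma protein's abundance —
almost certainly acts through the gene coding for that protein, which makes
protein QTLs a rare source of ground truth for the question every GWAS
follow-up faces: *given an association signal, which nearby gene is causal?*
The standard strategies are (i) assign the variant to the closest
protein-coding gene, (ii) test for colocalization with a *cis*-eQTL, and
(iii) require multiple conditionally distinct shared signals with
proportional effects (Mendelian randomization). Horizontal pleiotropy — one
regulatory variant driving several genes' expression in the same locus —
confounds all eQTL-based strategies.

`colocbench` implements the full benchmarking pipeline as a tested library:

- **Fine-mapping** (`colocbench.finemap`) — a sum-of-single-effects fitter on
  z-scores and LD (per-signal inclusion vectors α, per-signal log Bayes
  factors, PIPs, purity-filtered credible sets), plus Wakefield log
  approximate Bayes factors, lABF = ½·(log(1−r) + r·z²) with
  r = W/(W + se²), for marginal or all-but-one conditional statistics.
- **Colocalization** (`colocbench.coloc`) — three methods:
  enumeration over single-causal configurations from marginal statistics
  (PP0–PP4, significant when PP4 > 0.8), the same enumeration over
  per-signal Bayes-factor rows for every signal pair, and CLPP — the sum of
  per-variant inclusion-probability products over the exposure credible set
  (significant when CLPP > 0.1). Priors p1 = p2 = 1e-4, p12 = 5e-6.
- **Mendelian randomization** (`colocbench.mr`) — five estimators of the
  causal slope of expression on protein abundance from the instruments
  supplied by colocalizing signal pairs: IVW with first-order or delta
  weights, multiplicative random-effects IVW, a robust adjusted profile
  score with Tukey loss and overdispersion, and a hierarchical
  per-instrument-slope model with an allelic-spread parameter. Significance
  at the 80% confidence/credible level.
- **Benchmarking** (`colocbench.benchmark`, `colocbench.pipeline`) —
  closest-gene baselines (gene-body and TSS distance, ties kept),
  TP/FP/FN accounting over unique (protein, gene) pairs, recall over
  proteins with at least one purity-filtered credible set, slope-sign
  concordance per triplet.
- **Synthetic data** (`colocbench.simulate`) — paired exposure/outcome
  cohorts drawn from one haplotype pool with block LD, 1–5 causal variants
  per trait with configurable sharing, co-regulated neighbor genes, and
  rank-inverse-normal outcome phenotypes, with every sharing recorded as a
  truth label.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
30-protein catalog (three genes per locus, pleiotropy rate 0.5,
multi-signal rate 0.6):

```bash
python analysis/01_simulate_catalog.py
python analysis/05_benchmark_report.py
```

prints

```
tested proteins: 30
method             precision  recall  TP+slope  FP+slope
closest_gene          100.0%  100.0%         -         -
closest_gene_tss       96.7%   96.7%         -         -
abf                    41.5%   56.7%         -         -
bf_bf                  50.0%   80.0%         -         -
clpp                   47.2%   56.7%         -         -
multi_signal           81.8%   60.0%         -         -
ivw                    81.8%   60.0%     18/18       2/4
ivw_delta              81.8%   60.0%     18/18       2/4
ivw_delta_random       85.7%   60.0%     18/18       2/4
raps                   85.7%   60.0%     18/18       2/4
locus_spread           85.7%   60.0%     18/18       2/4
```

Reading the table: the closest-gene baseline dominates every colocalization
method on precision because primary pQTLs sit inside their coding gene's
body; per-signal colocalization (`bf_bf`) has the highest recall of the
three colocalization methods while CLPP pays for its variant-level
stringency; requiring two conditionally distinct colocalizing signals
(`multi_signal`) trades recall for precision; and the overdispersion-robust
MR estimators discard the discordant false positives that fixed-weight IVW
keeps. `TP+slope` / `FP+slope` count triplets with a positive fitted slope
among true/false positives — true causal pairs are concordant, co-regulated
neighbors only about half the time.

`analysis/04_mr_comparison.py` additionally shows why the random-effects
model matters: under a heterogeneous null its 80%-interval false-positive
rate is ~38% versus ~94% for fixed-weight IVW.

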