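"""Ground-truth scoring: closest-gene baseline, precision/recall, slopes.

A predicted (protein, gene) pair is a true positive iff the gene codes
for the protein; a tested protein (one with at least one purity-filtered
credible set) with no true-positive prediction is a false negative.
Precision is computed over unique (protein, gene) pairs pooled across
datasets; MR slope direction is assessed per (gene, protein, dataset)
triplet.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .datatypes import ColocbenchError, GeneAnnotation, Variant

logger = logging.getLogger(__name__)


@dataclass
class TruthMap:
    coding_gene: dict[str, str]  # protein_id -> coding gene_id
    tested_proteins: set[str]

    def __post_init__(self) -> None:
        extra = set(self.coding_gene) - self.tested_proteins
        if extra:
            raise ValueError(f"labeled proteins missing from tested set: {sorted(extra)[:3]}")


@dataclass(frozen=True)
class Prediction:
    protein_id: str
    gene_id: str
    dataset_id: str = "dataset"
    cs_index: int | None = None  # outcome (pQTL) credible-set rank


@dataclass
class BenchmarkReport:
    method: str
    tp: int
    fp: int
    fn: int
    tp_positive_slope: tuple[int, int] | None = None  # (positive, total)
    fp_positive_slope: tuple[int, int] | None = None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def round_pct(x: float | None, digits: int = 1) -> float | None:
    """Percentage with half-up rounding to ``digits`` decimals."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(100 * x)).quantize(q, rounding=ROUND_HALF_UP))


def distance_to_gene(variant: Variant, gene: GeneAnnotation) -> float:
    """Base-pair distance to the gene body; 0 inside, +inf across chromosomes."""
    if variant.chrom != gene.chrom:
        return math.inf
    if gene.start <= variant.pos <= gene.end:
        return 0
    return min(abs(variant.pos - gene.start), abs(variant.pos - gene.end))


def closest_genes(
    lead: Variant, annotations: list[GeneAnnotation], mode: str = "gene_body"
) -> set[str]:
    """Protein-coding genes minimizing distance to the lead variant.

    ``gene_body`` mode uses distance to the gene body (0 inside);
    ``tss`` mode uses |pos - TSS|. All tied genes are returned.
    """
    if mode not in ("gene_body", "tss"):
        raise ValueError(f"unknown mode {mode!r}")
    coding = [g for g in annotations if g.protein_coding]
    if not coding:
        raise ColocbenchError("empty annotation list")
    if mode == "gene_body":
        dist = {g.gene_id: distance_to_gene(lead, g) for g in coding}
    else:
        dist = {
            g.gene_id: (abs(lead.pos - g.tss) if g.chrom == lead.chrom else math.inf)
            for g in coding
        }
    best = min(dist.values())
    if math.isinf(best):
        return set()
    return {gid for gid, d in dist.items() if d == best}


def score_method(
    predictions: list[Prediction],
    truth: TruthMap,
    restriction: str = "all",
    method: str = "method",
) -> BenchmarkReport | dict[int, BenchmarkReport]:
    """Precision/recall over unique (protein, gene) pairs.

    ``restriction``: ``all`` pools every prediction; ``first_signal_only``
    keeps predictions from the first outcome signal; ``by_cs_index``
    returns one report per outcome credible-set rank.
    """
    for p in predictions:
        if p.protein_id not in truth.tested_proteins:
            raise ColocbenchError(f"prediction for untested protein {p.protein_id}")
    if restriction == "first_signal_only":
        predictions = [p for p in predictions if p.cs_index == 1]
    elif restriction == "by_cs_index":
        strata = sorted({p.cs_index for p in predictions if p.cs_index is not None})
        return {
            s: score_method([p for p in predictions if p.cs_index == s], truth,
                            "all", f"{method}[cs{s}]")
            for s in strata
        }
    elif restriction != "all":
        raise ValueError(f"unknown restriction {restriction!r}")

    pairs = {(p.protein_id, p.gene_id) for p in predictions}
    tp_proteins = {prot for prot, gene in pairs if truth.coding_gene.get(prot) == gene}
    tp = len(tp_proteins)
    fp = len(pairs) - tp
    fn = len(truth.tested_proteins) - tp
    return BenchmarkReport(method=method, tp=tp, fp=fp, fn=fn)


def report_from_counts(method: str, tp: int, n_pairs: int, n_tested: int) -> BenchmarkReport:
    """Build a report directly from printed counts (tp / pairs / tested)."""
    return BenchmarkReport(method=method, tp=tp, fp=n_pairs - tp, fn=n_tested - tp)


def sign_concordance(labeled_estimates) -> dict[str, tuple[int, int]]:
    """Fractions of TP / FP triplets with a positive fitted MR slope.

    ``labeled_estimates`` is an iterable of (estimate, is_tp) pairs, one
    per (gene, protein, dataset) triplet. A slope of exactly zero counts
    as non-positive.
    """
    pos = {"tp": 0, "fp": 0}
    tot = {"tp": 0, "fp": 0}
    for est, is_tp in labeled_estimates:
        key = "tp" if is_tp else "fp"
        tot[key] += 1
        if est.alpha_hat > 0:
            pos[key] += 1
        elif est.alpha_hat == 0:
            logger.info("MR slope exactly zero counted as non-positive")
    return {k: (pos[k], tot[k]) for k in ("tp", "fp")}
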