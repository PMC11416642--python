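"""Allele harmonization of trait pairs and cis-window extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CisWindow,
    EmptyJoinError,
    EmptyRegionError,
    GeneAnnotation,
    RegionSummaryStats,
)

logger = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class HarmonizedPair:
    """Shared variants of two traits with effect alleles aligned to trait a.

    ``beta_b`` is sign-flipped wherever b's ref/alt were swapped relative
    to a. Row order follows trait a.
    """

    variant_ids: list[str]
    pos: np.ndarray
    beta_a: np.ndarray
    se_a: np.ndarray
    maf_a: np.ndarray
    beta_b: np.ndarray
    se_b: np.ndarray
    maf_b: np.ndarray
    n_a: int
    n_b: int
    idx_a: np.ndarray  # positional indices into the original inputs
    idx_b: np.ndarray
    n_flipped: int
    n_ambiguous: int
    n_incompatible: int

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def z_a(self) -> np.ndarray:
        return self.beta_a / self.se_a

    @property
    def z_b(self) -> np.ndarray:
        return self.beta_b / self.se_b


def harmonize_pair(a: RegionSummaryStats, b: RegionSummaryStats) -> HarmonizedPair:
    """Inner-join two traits on (chrom, pos) with effect-allele alignment.

    A variant matches if the allele pairs are identical (kept as-is) or
    swapped (b's beta negated). Incompatible allele pairs are dropped with
    a logged count; strand-ambiguous (A/T, C/G) pairs are kept as-is.
    """
    lookup: dict[tuple[str, int], list[int]] = {}
    for j, v in enumerate(b.variants):
        lookup.setdefault(v.key, []).append(j)

    ia, ib, flips = [], [], []
    n_ambiguous = n_incompatible = 0
    for i, va in enumerate(a.variants):
        for j in lookup.get(va.key, ()):
            vb = b.variants[j]
            if (va.ref, va.alt) == (vb.ref, vb.alt):
                flip = False
            elif (va.ref, va.alt) == (vb.alt, vb.ref):
                flip = True
            else:
                n_incompatible += 1
                continue
            if frozenset((va.ref, va.alt)) in _AMBIGUOUS:
                n_ambiguous += 1
            ia.append(i)
            ib.append(j)
            flips.append(flip)
            break
    if not ia:
        raise EmptyJoinError(
            f"no shared variants between {a.trait_id} and {b.trait_id}"
        )
    if n_ambiguous:
        logger.info("kept %d strand-ambiguous variants as-is", n_ambiguous)
    if n_incompatible:
        logger.warning("dropped %d variants with incompatible allele pairs", n_incompatible)

    ia_arr = np.asarray(ia, dtype=int)
    ib_arr = np.asarray(ib, dtype=int)
    sign = np.where(np.asarray(flips), -1.0, 1.0)
    return HarmonizedPair(
        variant_ids=[a.variants[i].id for i in ia],
        pos=np.asarray([a.variants[i].pos for i in ia], dtype=int),
        beta_a=a.beta[ia_arr],
        se_a=a.se[ia_arr],
        maf_a=a.maf[ia_arr],
        beta_b=b.beta[ib_arr] * sign,
        se_b=b.se[ib_arr],
        maf_b=b.maf[ib_arr],
        n_a=a.n,
        n_b=b.n,
        idx_a=ia_arr,
        idx_b=ib_arr,
        n_flipped=int(np.sum(flips)),
        n_ambiguous=n_ambiguous,
        n_incompatible=n_incompatible,
    )


def cis_window(gene: GeneAnnotation, stats: RegionSummaryStats) -> RegionSummaryStats:
    """Restrict summary statistics to the 2 Mb window centred on the TSS."""
    win = CisWindow.around(gene.tss)
    pos = np.asarray([v.pos for v in stats.variants])
    keep = np.flatnonzero((pos >= win.lo) & (pos <= win.hi))
    if keep.size == 0:
        raise EmptyRegionError(
            f"no variants of {stats.trait_id} inside the cis-window of {gene.gene_id}"
        )
    return stats.subset(keep)


def window_overlap_fraction(gene: GeneAnnotation, stats: RegionSummaryStats) -> float:
    """Fraction of a trait's variants that fall inside the gene's cis-window.

    Used for the pair skip rule: a pair is skipped when more than 90% of
    the outcome region's variants fall outside the exposure cis-window.
    """
    win = CisWindow.around(gene.tss)
    pos = np.asarray([v.pos for v in stats.variants])
    return float(np.mean((pos >= win.lo) & (pos <= win.hi)))
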