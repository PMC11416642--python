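"""Core domain types shared across the pipeline.

Conventions: genomic coordinates are 1-based and inclusive (GTF style);
effect sizes (``beta``) are per alt-allele-dosage unit; ``maf`` is always
folded to the minor allele (``0 < maf <= 0.5``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ColocbenchError(Exception):
    """Base class for package errors."""


class FormatError(ColocbenchError):
    """A file did not match the expected tabular dialect."""


class EmptyJoinError(ColocbenchError):
    """Two summary-statistic sets share no variants."""


class EmptyRegionError(ColocbenchError):
    """No variants remain after restricting to a cis-window."""


class EstimationError(ColocbenchError):
    """An estimator failed to produce a usable fit."""


@dataclass(frozen=True)
class Variant:
    """A biallelic variant keyed by position and allele pair."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical for {self.id}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class RegionSummaryStats:
    """Marginal association summary statistics for one trait in one region.

    Arrays are aligned with ``variants``; ``z`` is derived as ``beta / se``.
    """

    trait_id: str
    dataset_id: str
    variants: list[Variant]
    beta: np.ndarray
    se: np.ndarray
    maf: np.ndarray
    n: int
    z: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        m = len(self.variants)
        for name in ("beta", "se", "maf"):
            arr = getattr(self, name)
            if arr.shape != (m,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({m},)")
        if np.any(self.se <= 0):
            raise ValueError("all standard errors must be positive")
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.z is None:
            self.z = self.beta / self.se
        else:
            self.z = np.asarray(self.z, dtype=float)
            if not np.allclose(self.z, self.beta / self.se, atol=1e-12, rtol=0):
                raise ValueError("z inconsistent with beta / se")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != m:
            raise ValueError("variant ids must be unique within a region")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset(self, idx: np.ndarray) -> "RegionSummaryStats":
        """Return a new object restricted to positional indices ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return RegionSummaryStats(
            trait_id=self.trait_id,
            dataset_id=self.dataset_id,
            variants=[self.variants[i] for i in idx],
            beta=self.beta[idx],
            se=self.se[idx],
            maf=self.maf[idx],
            n=self.n,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates plus the strand-aware transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    protein_coding: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP colocalization priors and the ABF prior effect variance W.

    Defaults follow the standard quantitative-trait convention:
    p1 = p2 = 1e-4, p12 = 5e-6, prior effect s.d. 0.15 (W = 0.0225).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-6
    W: float = 0.0225

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.W <= 0:
            raise ValueError("W must be positive")


@dataclass(frozen=True)
class CisWindow:
    """A 2 Mb window centred on a TSS: [tss - 1e6 + 1, tss + 1e6].

    The lower bound is clipped at 1 near the chromosome start, in which
    case the width is less than the nominal 2,000,000 bp.
    """

    center: int
    lo: int
    hi: int

    HALF_WIDTH: int = 1_000_000

    @classmethod
    def around(cls, tss: int, half_width: int = 1_000_000) -> "CisWindow":
        lo = max(1, tss - half_width + 1)
        return cls(center=tss, lo=lo, hi=tss + half_width)

    def contains(self, pos: int) -> bool:
        return self.lo <= pos <= self.hi
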