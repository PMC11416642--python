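"""Bayesian colocalization: ABF enumeration, per-signal BF, and CLPP.

All three methods test whether two traits share a causal variant in a
region. The enumeration methods return posterior probabilities over the
five sharing hypotheses: H0 no association, H1/H2 one trait only, H3 two
distinct causal variants, H4 one shared causal variant. CLPP scores a
pair of fine-mapped signals by the summed product of their per-variant
inclusion probabilities over the exposure credible set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .datatypes import ColocbenchError, ColocPriors, RegionSummaryStats
from .finemap import CredibleSet, wakefield_labf
from .harmonize import HarmonizedPair, harmonize_pair

PP4_THRESHOLD = 0.8
CLPP_THRESHOLD = 0.1


@dataclass
class ColocResult:
    trait_pair: tuple[str, str]
    method: str  # abf | bf_bf | clpp
    signal_pair: tuple[int | None, int | None]
    pp: np.ndarray | None  # PP0..PP4
    clpp_value: float | None
    significant: bool

    @property
    def pp4(self) -> float | None:
        return None if self.pp is None else float(self.pp[4])


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b (returns -inf on numerical ties)."""
    if b >= a:
        if b - a > 1e-9:
            raise ColocbenchError("internal consistency error: L1+L2 < L12")
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def colocalization_pp(
    lbf_a: np.ndarray, lbf_b: np.ndarray, priors: ColocPriors
) -> np.ndarray:
    """Posterior probabilities PP0..PP4 from two aligned per-variant log-BF rows.

    Sums over the single-causal-per-trait configuration space: with
    L1 = logsumexp(lbf_a), L2 = logsumexp(lbf_b), L12 = logsumexp(lbf_a + lbf_b),
    the unnormalized log weights are S0 = 0, S1 = log p1 + L1,
    S2 = log p2 + L2, S3 = log(p1 p2) + log(exp(L1 + L2) - exp(L12)),
    S4 = log p12 + L12; PPk = softmax(S0..S4).
    """
    lbf_a = np.asarray(lbf_a, dtype=float)
    lbf_b = np.asarray(lbf_b, dtype=float)
    if lbf_a.shape != lbf_b.shape:
        raise ValueError(f"row length mismatch: {lbf_a.shape} vs {lbf_b.shape}")
    if lbf_a.size < 2:
        raise ColocbenchError("need at least 2 shared variants")
    L1 = float(logsumexp(lbf_a))
    L2 = float(logsumexp(lbf_b))
    L12 = float(logsumexp(lbf_a + lbf_b))
    s = np.array(
        [
            0.0,
            np.log(priors.p1) + L1,
            np.log(priors.p2) + L2,
            np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(L1 + L2, L12),
            np.log(priors.p12) + L12,
        ]
    )
    return np.exp(s - logsumexp(s))


def coloc_abf(
    a: RegionSummaryStats | HarmonizedPair,
    b: RegionSummaryStats | None = None,
    priors: ColocPriors | None = None,
    pp4_threshold: float = PP4_THRESHOLD,
) -> ColocResult:
    """Enumeration colocalization from marginal summary statistics.

    Accepts either two traits (harmonized internally) or a pre-built
    :class:`HarmonizedPair`. Significant iff PP4 > 0.8.
    """
    priors = priors or ColocPriors()
    if isinstance(a, HarmonizedPair):
        pair = a
        trait_pair = ("a", "b")
    else:
        pair = harmonize_pair(a, b)
        trait_pair = (a.trait_id, b.trait_id)
    if len(pair) < 2:
        raise ColocbenchError("insufficient overlap: need >= 2 shared variants")
    lbf_a = wakefield_labf(pair.beta_a, pair.se_a, priors.W)
    lbf_b = wakefield_labf(pair.beta_b, pair.se_b, priors.W)
    pp = colocalization_pp(lbf_a, lbf_b, priors)
    return ColocResult(
        trait_pair=trait_pair,
        method="abf",
        signal_pair=(None, None),
        pp=pp,
        clpp_value=None,
        significant=bool(pp[4] > pp4_threshold),
    )


def coloc_bf_bf(
    lbf_a_row: np.ndarray,
    lbf_b_row: np.ndarray,
    priors: ColocPriors | None = None,
    trait_pair: tuple[str, str] = ("a", "b"),
    signal_pair: tuple[int, int] = (1, 1),
    pp4_threshold: float = PP4_THRESHOLD,
) -> ColocResult:
    """Per-signal-pair colocalization from fine-mapped log Bayes factors.

    Identical enumeration to :func:`coloc_abf` with the per-signal rows
    substituted for the marginal lABFs, using the same priors.
    """
    priors = priors or ColocPriors()
    pp = colocalization_pp(lbf_a_row, lbf_b_row, priors)
    return ColocResult(
        trait_pair=trait_pair,
        method="bf_bf",
        signal_pair=signal_pair,
        pp=pp,
        clpp_value=None,
        significant=bool(pp[4] > pp4_threshold),
    )


def clpp(
    alpha_a_row: np.ndarray,
    alpha_b_row: np.ndarray,
    cs_a: CredibleSet,
    variant_ids: Sequence[str],
    trait_pair: tuple[str, str] = ("a", "b"),
    signal_pair: tuple[int, int] = (1, 1),
    threshold: float = CLPP_THRESHOLD,
) -> ColocResult:
    """Credible-set colocalization posterior probability.

    CLPP = sum over exposure-credible-set variants of the product of the
    two traits' per-signal inclusion probabilities; variants absent from
    either trait contribute 0. Significant iff CLPP > 0.1. Overall PIP
    vectors may be passed in place of the per-signal alpha rows to score
    region-level rather than per-signal inclusion.
    """
    alpha_a_row = np.asarray(alpha_a_row, dtype=float)
    alpha_b_row = np.asarray(alpha_b_row, dtype=float)
    if alpha_a_row.shape != alpha_b_row.shape or len(alpha_a_row) != len(variant_ids):
        raise ValueError("alpha rows must be aligned to the harmonized variant set")
    in_cs = np.fromiter(
        (vid in cs_a.variant_ids for vid in variant_ids), dtype=bool, count=len(variant_ids)
    )
    value = float(np.sum(alpha_a_row[in_cs] * alpha_b_row[in_cs]))
    return ColocResult(
        trait_pair=trait_pair,
        method="clpp",
        signal_pair=signal_pair,
        pp=None,
        clpp_value=value,
        significant=bool(value > threshold),
    )


def coloc_abf_bruteforce(
    lbf_a: np.ndarray, lbf_b: np.ndarray, priors: ColocPriors
) -> np.ndarray:
    """Direct double-loop enumeration over all M x M causal configurations.

    Independent oracle for :func:`colocalization_pp`: works in plain
    probability space without log-sum-exp shortcuts. Intended for small M.
    """
    bf_a = np.exp(np.asarray(lbf_a, dtype=float))
    bf_b = np.exp(np.asarray(lbf_b, dtype=float))
    M = len(bf_a)
    w0 = 1.0
    w1 = priors.p1 * sum(bf_a)
    w2 = priors.p2 * sum(bf_b)
    w3 = 0.0
    w4 = 0.0
    for i in range(M):
        for j in range(M):
            if i == j:
                w4 += priors.p12 * bf_a[i] * bf_b[j]
            else:
                w3 += priors.p1 * priors.p2 * bf_a[i] * bf_b[j]
    w = np.array([w0, w1, w2, w3, w4])
    return w / w.sum()
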