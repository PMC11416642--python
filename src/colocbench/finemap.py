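"""Sum-of-single-effects fine-mapping from summary statistics.

The fitter runs iterative Bayesian stepwise selection on z-scores and an
LD correlation matrix: each of L single effects is fit as a Bayesian
single-variant regression on residualized z-scores, with per-variant
posterior inclusion weights proportional to exp(log Bayes factor). It
yields per-signal inclusion vectors (alpha rows), per-signal log Bayes
factors, overall PIPs, and purity-filtered credible sets.

Wakefield log approximate Bayes factors are exposed separately: applied
row-wise to all-but-one conditional betas/SEs they produce per-signal
LABF rows usable wherever fine-mapped LBF rows are expected (the
conditional-meta-analysis route to per-signal colocalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .datatypes import ColocbenchError, RegionSummaryStats


class ConditioningError(ColocbenchError):
    """LD matrix is too far from positive semi-definite even after ridge."""


@dataclass(frozen=True)
class FineMapConfig:
    """Settings for the sum-of-single-effects fit.

    ``W`` is the prior effect variance on the beta scale (prior sd 0.15,
    the quantitative-trait convention shared with the colocalization
    priors). With ``estimate_prior_variance`` (the default, matching the
    reference implementation of the method) each effect's prior variance
    is optimized every iteration and the effect is zeroed when the data
    do not support it; this prevents a single signal from being split
    across several effects when the region contains near-duplicate
    proxies. Disable it to fix every effect's prior variance at ``W``.
    """

    L: int = 10
    coverage: float = 0.95
    purity_min: float = 0.5
    max_iter: int = 200
    tol: float = 1e-4
    W: float = 0.0225
    estimate_prior_variance: bool = True
    estimate_residual_variance: bool = False
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must lie in (0, 1)")
        if not (0 <= self.purity_min <= 1):
            raise ValueError("purity_min must lie in [0, 1]")


@dataclass
class CredibleSet:
    cs_index: int  # 1-based signal rank after purity filtering
    variant_ids: frozenset[str]
    member_indices: np.ndarray  # positional indices into the region
    alpha_mass: float
    purity: float
    lead_variant: str
    lead_index: int
    effect_row: int  # row of alpha/lbf this set came from


@dataclass
class FineMapResult:
    variant_ids: list[str]
    alpha: np.ndarray  # (L, M), rows sum to 1
    lbf: np.ndarray  # (L, M) per-signal, per-variant natural-log BFs
    pip: np.ndarray  # (M,)
    credible_sets: list[CredibleSet] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    def alpha_row(self, cs: CredibleSet) -> np.ndarray:
        return self.alpha[cs.effect_row]

    def lbf_row(self, cs: CredibleSet) -> np.ndarray:
        return self.lbf[cs.effect_row]


def wakefield_labf(beta, se, W: float):
    """Wakefield log approximate Bayes factor.

    With V = se^2, z = beta/se and r = W/(W+V):
    lABF = 0.5 * (log(1 - r) + r * z^2). Strictly increasing in z^2 for
    fixed se and W; tends to 0 as W -> 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("beta and se must be finite")
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if W < 0:
        raise ValueError("W must be non-negative")
    V = se**2
    r = W / (W + V)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def _check_ld(R: np.ndarray, ridge: float) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have unit diagonal")
    try:
        np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
        return R
    except np.linalg.LinAlgError:
        pass
    R2 = R + ridge * np.eye(len(R))
    try:
        np.linalg.cholesky(R2)
    except np.linalg.LinAlgError:
        raise ConditioningError(
            "LD matrix is not positive semi-definite even after ridge "
            f"regularization ({ridge}); check its construction"
        ) from None
    return R2


def _single_effect_loglik(V: float, resid: np.ndarray, se2: np.ndarray, sigma2: float) -> float:
    """Log marginal likelihood ratio (vs null) of one single-effect fit.

    Uniform prior over which variant carries the effect; prior effect
    variance V on the beta scale.
    """
    if V <= 0:
        return 0.0
    shrink = (V / se2) / (V / se2 + sigma2)
    lbf = 0.5 * (np.log1p(-shrink) + shrink * resid**2 / sigma2)
    return float(logsumexp(lbf) - np.log(len(resid)))


def _optimize_prior_variance(
    resid: np.ndarray, se2: np.ndarray, sigma2: float, W: float
) -> float:
    """Per-effect prior variance maximizing the single-effect likelihood.

    Returns 0 when no positive prior variance beats the null, which
    zeroes the effect and prevents one signal from being split across
    several effects in regions of near-duplicate proxies.
    """
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda lnv: -_single_effect_loglik(np.exp(lnv), resid, se2, sigma2),
        bounds=(np.log(1e-8), np.log(4.0)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    v_opt = float(np.exp(res.x))
    best = -float(res.fun)
    if _single_effect_loglik(W, resid, se2, sigma2) > best:
        v_opt, best = W, _single_effect_loglik(W, resid, se2, sigma2)
    return v_opt if best > 0.0 else 0.0


def susie_rss(
    stats: RegionSummaryStats, R: np.ndarray, config: FineMapConfig | None = None
) -> FineMapResult:
    """Fit the sum-of-single-effects model to z-scores and LD.

    The per-variant prior effect variance is ``config.W`` on the beta
    scale, translated per-variant to the z scale as W / se^2 so that a
    single-effect fit reproduces the Wakefield lABFs of the marginal
    statistics (the bridge that makes per-signal BF colocalization reduce
    to ABF colocalization on single-signal loci).
    """
    if config is None:
        config = FineMapConfig()
    M = len(stats)
    if R.shape != (M, M):
        raise ValueError(f"R has shape {R.shape}, expected ({M}, {M})")
    R = _check_ld(R, config.ridge)
    z = stats.z.copy()
    L = config.L

    b = np.zeros((L, M))  # fitted per-signal means (z scale)
    alpha = np.full((L, M), 1.0 / M)
    lbf = np.zeros((L, M))
    se2 = stats.se**2
    sigma2 = 1.0
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        b_old = b.copy()
        b_sum = b.sum(axis=0)
        for l in range(L):
            b_sum -= b[l]
            resid = z - R @ b_sum
            if config.estimate_prior_variance:
                V = _optimize_prior_variance(resid, se2, sigma2, config.W)
            else:
                V = config.W
            if V == 0.0:
                # effect unsupported by the residual: zero it out
                lbf[l] = 0.0
                alpha[l] = 1.0 / M
                b[l] = 0.0
                continue
            shrink = (V / se2) / (V / se2 + sigma2)
            lbf[l] = 0.5 * (np.log1p(-shrink) + shrink * resid**2 / sigma2)
            a = np.exp(lbf[l] - logsumexp(lbf[l]))
            alpha[l] = a
            b[l] = a * shrink * resid
            b_sum += b[l]
        if config.estimate_residual_variance:
            r_all = z - R @ b.sum(axis=0)
            sigma2 = max(float(np.mean(r_all**2)), 1e-4)
        if np.max(np.abs(b - b_old)) < config.tol:
            converged = True
            break

    pip = 1.0 - np.prod(1.0 - alpha, axis=0)
    result = FineMapResult(
        variant_ids=stats.variant_ids,
        alpha=alpha,
        lbf=lbf,
        pip=pip,
        converged=converged,
        n_iter=it,
    )
    result.credible_sets = _build_credible_sets(result, stats, R, config)
    return result


def _purity(members: np.ndarray, R: np.ndarray) -> float:
    """Minimum |r| over pairs in the set; 100 sampled pairs when large."""
    k = len(members)
    if k == 1:
        return 1.0
    n_pairs = k * (k - 1) // 2
    if n_pairs <= 100:
        sub = np.abs(R[np.ix_(members, members)])
        iu = np.triu_indices(k, 1)
        return float(sub[iu].min())
    rng = np.random.default_rng(0)
    i = rng.integers(0, k, size=100)
    j = rng.integers(0, k - 1, size=100)
    j = np.where(j >= i, j + 1, j)
    return float(np.min(np.abs(R[members[i], members[j]])))


def _lead_variant(stats: RegionSummaryStats, members: np.ndarray) -> int:
    """Member with max |z|; ties broken by lowest position, then id."""
    absz = np.abs(stats.z[members])
    best = None
    for k, j in enumerate(members):
        key = (-absz[k], stats.variants[j].pos, stats.variants[j].id)
        if best is None or key < best[0]:
            best = (key, j)
    return best[1]


def _build_credible_sets(
    result: FineMapResult, stats: RegionSummaryStats, R: np.ndarray, config: FineMapConfig
) -> list[CredibleSet]:
    candidates = []
    for l in range(config.L):
        order = np.argsort(-result.alpha[l], kind="stable")
        cum = np.cumsum(result.alpha[l][order])
        size = int(np.searchsorted(cum, config.coverage) + 1)
        size = min(size, len(order))
        members = np.sort(order[:size])
        purity = _purity(members, R)
        if purity < config.purity_min:
            continue
        candidates.append((l, members, float(cum[size - 1]), purity))
    # rank surviving sets by decreasing max single-effect log BF; two
    # effects can split one signal and emit identical sets - deduplicate
    candidates.sort(key=lambda c: -float(result.lbf[c[0]].max()))
    seen: set[tuple] = set()
    sets = []
    rank = 0
    for l, members, mass, purity in candidates:
        key = tuple(members)
        if key in seen:
            continue
        seen.add(key)
        rank += 1
        lead = _lead_variant(stats, members)
        sets.append(
            CredibleSet(
                cs_index=rank,
                variant_ids=frozenset(stats.variants[j].id for j in members),
                member_indices=members,
                alpha_mass=mass,
                purity=purity,
                lead_variant=stats.variants[lead].id,
                lead_index=lead,
                effect_row=l,
            )
        )
    return sets


def extract_credible_sets(result: FineMapResult, first_only: bool = False) -> list[CredibleSet]:
    """All purity-filtered credible sets, or only the first signal."""
    if first_only:
        return [cs for cs in result.credible_sets if cs.cs_index == 1]
    return list(result.credible_sets)
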