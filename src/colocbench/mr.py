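"""Cis-Mendelian-randomization estimators over colocalizing signal pairs.

Five estimators of the causal slope of exposure (gene expression) on
outcome (protein abundance): inverse-variance-weighted MR with
first-order or delta weights under a fixed or multiplicative-random
effects model; a robust adjusted profile score estimator with Tukey
biweight loss and overdispersion; and a hierarchical per-instrument-slope
model summarizing the dispersion of instrument effects as an allelic
spread parameter. Significance is declared when the 80% confidence (or
credible) interval excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from .datatypes import EstimationError

logger = logging.getLogger(__name__)

#: standard normal quantile for central 80% intervals
Z80 = 1.281552

TUKEY_C = 4.685


@dataclass
class MRInput:
    """Instrument effects, one per colocalizing signal pair."""

    bx: np.ndarray
    se_bx: np.ndarray
    by: np.ndarray
    se_by: np.ndarray
    pair_ids: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bx = np.atleast_1d(np.asarray(self.bx, dtype=float))
        self.se_bx = np.atleast_1d(np.asarray(self.se_bx, dtype=float))
        self.by = np.atleast_1d(np.asarray(self.by, dtype=float))
        self.se_by = np.atleast_1d(np.asarray(self.se_by, dtype=float))
        if not (len(self.bx) == len(self.se_bx) == len(self.by) == len(self.se_by)):
            raise ValueError("instrument arrays must have equal length")
        if np.any(self.se_bx <= 0) or np.any(self.se_by <= 0):
            raise ValueError("standard errors must be positive")
        if self.pair_ids:
            es = [e for e, _ in self.pair_ids]
            os_ = [o for _, o in self.pair_ids]
            if len(set(es)) != len(es) or len(set(os_)) != len(os_):
                raise ValueError("pair_ids must be distinct on both coordinates")

    @property
    def k(self) -> int:
        return len(self.bx)


@dataclass
class MREstimate:
    method: str
    alpha_hat: float
    interval: tuple[float, float]
    dispersion: float | None  # tau^2 (raps/ivw-random Q scale) or tau (spread)
    significant: bool
    se: float | None = None
    k: int = 0

    @classmethod
    def from_normal(cls, method: str, alpha: float, se: float, dispersion=None, k=0):
        lo, hi = alpha - Z80 * se, alpha + Z80 * se
        return cls(method, float(alpha), (float(lo), float(hi)),
                   dispersion, not (lo <= 0 <= hi), float(se), k)


def mr_ivw(
    input: MRInput, weighting: str = "first_order", model: str = "fixed"
) -> MREstimate:
    """Inverse-variance-weighted MR over per-instrument ratio estimates.

    Ratio theta_j = by_j / bx_j; first-order weights use v_j =
    se_by_j^2 / bx_j^2, delta weights add the exposure's sampling error:
    v_j = se_by_j^2 / bx_j^2 + by_j^2 se_bx_j^2 / bx_j^4. The
    multiplicative random-effects model inflates the fixed-effect SE by
    max(1, sqrt(Q / (k - 1))) to absorb overdispersion heterogeneity
    between instruments.
    """
    if weighting not in ("first_order", "delta"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    keep = input.bx != 0
    if not np.all(keep):
        logger.warning("rejected %d instruments with bx = 0", int((~keep).sum()))
    bx, se_bx = input.bx[keep], input.se_bx[keep]
    by, se_by = input.by[keep], input.se_by[keep]
    k = len(bx)
    if k == 0:
        raise EstimationError("no usable instruments (all bx = 0)")
    name = "ivw" if weighting == "first_order" else (
        "ivw_delta" if model == "fixed" else "ivw_delta_random")
    theta = by / bx
    v = se_by**2 / bx**2
    if weighting == "delta":
        v = v + by**2 * se_bx**2 / bx**4
    if k == 1:
        if model == "random":
            raise EstimationError("random-effects model needs k >= 2")
        return MREstimate.from_normal(name, theta[0], np.sqrt(v[0]), None, 1)
    w = 1.0 / v
    alpha = float(np.sum(theta * w) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    Q = float(np.sum((theta - alpha) ** 2 * w))
    if model == "random":
        se = se_fixed * max(1.0, np.sqrt(Q / (k - 1)))
        return MREstimate.from_normal(name, alpha, se, Q / (k - 1), k)
    return MREstimate.from_normal(name, alpha, se_fixed, None, k)


# ---------------------------------------------------------------------------
# robust adjusted profile score with Tukey biweight and overdispersion


def _tukey_psi(t: np.ndarray) -> np.ndarray:
    u = t / TUKEY_C
    return np.where(np.abs(u) < 1, t * (1 - u**2) ** 2, 0.0)


def _tukey_rho(t: np.ndarray) -> np.ndarray:
    u = np.clip((t / TUKEY_C) ** 2, 0, 1)
    return TUKEY_C**2 / 6 * (1 - (1 - u) ** 3)


@lru_cache(maxsize=1)
def _delta_null() -> float:
    """E[psi(Z) Z] for standard normal Z (the null calibration constant)."""
    val, _ = integrate.quad(lambda t: _tukey_psi(np.array([t]))[0] * t * norm.pdf(t), -8, 8)
    return val


def _raps_t(alpha, tau2, inp: MRInput):
    s2 = inp.se_by**2 + alpha**2 * inp.se_bx**2 + tau2
    return (inp.by - alpha * inp.bx) / np.sqrt(s2), s2


def _raps_score_alpha(alpha, tau2, inp: MRInput) -> float:
    t, s2 = _raps_t(alpha, tau2, inp)
    s = np.sqrt(s2)
    dt = -(inp.bx / s) - t * alpha * inp.se_bx**2 / s2
    return float(np.sum(_tukey_psi(t) * dt))

def _raps_score_tau(alpha, tau2, inp: MRInput) -> float:
    t, _ = _raps_t(alpha, tau2, inp)
    return float(np.sum(_tukey_psi(t) * t - _delta_null()))


def _raps_alpha_given_tau(tau2: float, inp: MRInput, init: float, width: float) -> float:
    """Profile alpha: grid-scan the Tukey loss, then polish the score root.

    The redescending loss is flat far from the data, so a blind scalar
    minimizer can miss the (narrow) basin; a grid centred on the IVW
    initializer locates it reliably.
    """

    def loss_vec(a_grid):
        a = np.asarray(a_grid)[:, None]
        s2 = inp.se_by[None, :] ** 2 + a**2 * inp.se_bx[None, :] ** 2 + tau2
        t = (inp.by[None, :] - a * inp.bx[None, :]) / np.sqrt(s2)
        return _tukey_rho(t).sum(axis=1)

    a = init
    for _ in range(6):
        grid = np.linspace(a - width, a + width, 201)
        losses = loss_vec(grid)
        i = int(np.argmin(losses))
        a = float(grid[i])
        if 0 < i < len(grid) - 1:
            break
        width *= 4  # minimum sits at the grid edge: widen and rescan
    # local refine inside the bracketing cell, then polish the score root
    res = optimize.minimize_scalar(
        lambda x: float(loss_vec([x])[0]),
        bounds=(a - 2 * width / 200, a + 2 * width / 200), method="bounded",
        options={"xatol": 1e-12},
    )
    a = float(res.x)
    try:
        sol = optimize.root_scalar(
            lambda x: _raps_score_alpha(x, tau2, inp),
            x0=a, x1=a + 1e-4 * max(abs(a), 1.0), method="secant", maxiter=50,
        )
        if sol.converged and abs(sol.root - a) < 4 * width / 200 + 1e-8:
            a = float(sol.root)
    except (RuntimeError, ValueError):
        pass
    return a


def mr_raps(input: MRInput) -> MREstimate:
    """Robust adjusted profile score MR with overdispersion.

    Solves the Tukey-weighted score equation for the slope jointly with a
    moment equation for the overdispersion variance tau^2 (calibrated so
    the weighted squared residuals match their null expectation), with a
    sandwich standard error. Instruments with gross residuals receive
    zero weight under the redescending Tukey score.
    """
    if input.k < 2:
        raise EstimationError("mr_raps needs k >= 2 instruments")
    inp = input
    init_est = mr_ivw(inp, weighting="delta", model="random")
    init = init_est.alpha_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(inp.bx != 0, inp.by / inp.bx, np.nan)
    width = max(10 * init_est.se, 4 * float(np.nanstd(theta)), 0.1)

    theta_spread = float(np.var(inp.by / np.where(inp.bx == 0, np.nan, inp.bx))) if np.all(inp.bx != 0) else 1.0
    tau_hi = max(10.0 * np.max(inp.se_by**2), 10.0 * theta_spread * np.max(inp.bx**2), 1.0)

    def tau_eq(tau2):
        a = _raps_alpha_given_tau(tau2, inp, init, width)
        return _raps_score_tau(a, tau2, inp)

    # the moment equation is not monotone: with a redescending score, all
    # residuals can exceed the Tukey cutoff at tau^2 = 0 (score collapses
    # to -k*delta) while the consistent root lies at larger tau^2. Scan a
    # log grid for the rightmost +/- sign change and bracket there.
    grid = np.concatenate([[0.0], np.geomspace(1e-6 * tau_hi, tau_hi, 20)])
    fvals = np.array([tau_eq(t) for t in grid])
    while fvals[-1] > 0 and tau_hi < 1e8:
        tau_hi *= 16
        grid = np.append(grid, tau_hi)
        fvals = np.append(fvals, tau_eq(tau_hi))
    crossings = np.flatnonzero((fvals[:-1] > 0) & (fvals[1:] <= 0))
    if crossings.size == 0:
        tau2 = 0.0  # residuals never more dispersed than their null expectation
    else:
        i = int(crossings[-1])
        try:
            tau2 = float(optimize.brentq(tau_eq, grid[i], grid[i + 1],
                                         xtol=1e-12, maxiter=200))
        except (RuntimeError, ValueError) as exc:
            raise EstimationError(f"mr_raps failed to converge: {exc}") from exc
    alpha = _raps_alpha_given_tau(tau2, inp, init, width)
    se = _raps_sandwich_se(alpha, tau2, inp)
    return MREstimate.from_normal("raps", alpha, se, tau2, inp.k)


def _raps_sandwich_se(alpha: float, tau2: float, inp: MRInput) -> float:
    """M-estimation sandwich variance with a numerical Jacobian."""
    def scores(theta):
        a, t2 = theta
        t2 = max(t2, 0.0)
        t, s2 = _raps_t(a, t2, inp)
        s = np.sqrt(s2)
        dt = -(inp.bx / s) - t * a * inp.se_bx**2 / s2
        g1 = _tukey_psi(t) * dt
        g2 = _tukey_psi(t) * t - _delta_null()
        return np.stack([g1, g2], axis=1)  # (k, 2)

    theta = np.array([alpha, tau2])
    eps = np.array([1e-5 * max(abs(alpha), 1.0), 1e-5 * max(tau2, 1.0)])
    if tau2 == 0.0:
        # boundary: one-dimensional sandwich in alpha alone
        g = scores(theta)[:, 0]
        d = (scores(theta + [eps[0], 0])[:, 0].sum() - scores(theta - [eps[0], 0])[:, 0].sum()) / (2 * eps[0])
        if d == 0:
            return float("inf")
        return float(np.sqrt(np.sum(g**2)) / abs(d))
    A = np.zeros((2, 2))
    for j in range(2):
        dp = theta.copy(); dp[j] += eps[j]
        dm = theta.copy(); dm[j] -= eps[j]
        A[:, j] = (scores(dp).sum(axis=0) - scores(dm).sum(axis=0)) / (2 * eps[j])
    g = scores(theta)
    B = g.T @ g
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return float("inf")
    V = Ainv @ B @ Ainv.T
    return float(np.sqrt(max(V[0, 0], 0.0)))


# ---------------------------------------------------------------------------
# hierarchical per-instrument-slope model (allelic spread)


def mr_locus_spread(
    input: MRInput,
    prior_alpha_sd: float | None = None,
    prior_tau_sd: float | None = None,
    n_alpha: int = 401,
    n_tau: int = 161,
) -> MREstimate:
    """Hierarchical slope model with an allelic-spread parameter.

    Per-instrument slopes alpha_j ~ Normal(alpha, tau^2) and
    by_j ~ Normal(alpha_j * bx_j, se_by_j^2) with bx_j fixed, so
    marginally by_j ~ Normal(alpha * bx_j, se_by_j^2 + tau^2 bx_j^2).
    Priors are weakly informative and scaled to the observed ratio scale
    (alpha ~ Normal(0, (10 s)^2), tau ~ half-Normal(0, (2 s_tau)^2) with s
    the ratio magnitude scale and s_tau the ratio dispersion scale), so
    that neither a slope of typical magnitude nor a dispersion comparable
    to the ratio spread is penalized, while the tau tail cannot drown a
    concordant signal at small k. The posterior is evaluated on an
    adaptive (alpha, tau) grid and tau is marginalized by trapezoidal
    integration, making the estimate fully deterministic. Reported:
    posterior median of alpha and the central 80% credible interval;
    dispersion is the posterior median of tau (the allelic spread).
    """
    if input.k < 2:
        raise EstimationError("mr_locus_spread needs k >= 2 instruments")
    bx, by, se_by = input.bx, input.by, input.se_by
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bx != 0, by / bx, 0.0)
        ratio_se = np.sqrt(se_by**2 / np.maximum(bx**2, 1e-12)
                           + by**2 * input.se_bx**2 / np.maximum(bx**4, 1e-24))
    center = float(np.median(ratios))
    spread0 = float(np.std(ratios)) if input.k > 1 else 1.0
    if prior_alpha_sd is None:
        prior_alpha_sd = 10.0 * max(abs(center), spread0, float(np.median(ratio_se)), 0.1)
    if prior_tau_sd is None:
        prior_tau_sd = 2.0 * max(spread0 + float(np.median(ratio_se)), 1e-3)
    half = max(8 * np.sqrt(np.sum(se_by**2 / np.maximum(bx**2, 1e-12)) / input.k**2),
               4 * spread0, 2 * abs(center), 1.0)
    tau_hi = max(4 * spread0, 2.0)

    for _ in range(6):
        a_grid = np.linspace(center - half, center + half, n_alpha)
        t_grid = np.linspace(0.0, tau_hi, n_tau)
        var = se_by[None, None, :] ** 2 + (t_grid[:, None, None] ** 2) * bx[None, None, :] ** 2
        resid = by[None, None, :] - a_grid[None, :, None] * bx[None, None, :]
        loglik = -0.5 * np.sum(np.log(2 * np.pi * var) + resid**2 / var, axis=2)
        logpost = (
            loglik
            + norm.logpdf(a_grid, 0.0, prior_alpha_sd)[None, :]
            + norm.logpdf(t_grid, 0.0, prior_tau_sd)[:, None]
        )
        logpost -= logpost.max()
        post = np.exp(logpost)
        dens_a = np.trapezoid(post, t_grid, axis=0)
        dens_t = np.trapezoid(post, a_grid, axis=1)
        edge = max(dens_a[0], dens_a[-1]) / max(dens_a.max(), 1e-300)
        tau_edge = dens_t[-1] / max(dens_t.max(), 1e-300)
        if edge < 1e-6 and tau_edge < 1e-4:
            break
        if edge >= 1e-6:
            center = float(a_grid[np.argmax(dens_a)])
            half *= 2
        if tau_edge >= 1e-4:
            tau_hi *= 2
    total = np.trapezoid(dens_a, a_grid)
    if not np.isfinite(total) or total <= 0:
        raise EstimationError("posterior grid evaluation failed")
    cdf = integrate.cumulative_trapezoid(dens_a, a_grid, initial=0.0) / total
    med, lo, hi = np.interp([0.5, 0.1, 0.9], cdf, a_grid)
    cdf_t = integrate.cumulative_trapezoid(dens_t, t_grid, initial=0.0)
    cdf_t /= cdf_t[-1]
    tau_med = float(np.interp(0.5, cdf_t, t_grid))
    return MREstimate(
        method="locus_spread",
        alpha_hat=float(med),
        interval=(float(lo), float(hi)),
        dispersion=tau_med,
        significant=not (lo <= 0 <= hi),
        se=None,
        k=input.k,
    )


METHODS = {
    "ivw": lambda inp: mr_ivw(inp, "first_order", "fixed"),
    "ivw_delta": lambda inp: mr_ivw(inp, "delta", "fixed"),
    "ivw_delta_random": lambda inp: mr_ivw(inp, "delta", "random"),
    "raps": mr_raps,
    "locus_spread": mr_locus_spread,
}


def build_mr_input(
    bf_results,
    finemap_exp,
    finemap_out,
    pair,
) -> MRInput | None:
    """Assemble instruments from significant per-signal colocalizations.

    ``bf_results`` are the per-signal-pair ``bf_bf`` results for one
    (gene, protein, dataset) triplet; ``finemap_exp`` / ``finemap_out``
    the two traits' fine-mapping results; ``pair`` the harmonized
    statistics. Retains the triplet only if >= 2 significant pairs with
    mutually distinct exposure and outcome signal indices exist (selected
    greedily by decreasing PP4). The instrument variant for a pair is the
    shared variant maximizing the product of the two alpha rows; its
    marginal effects supply (bx, by).
    """
    sig = [r for r in bf_results if r.significant and r.method == "bf_bf"]
    sig.sort(key=lambda r: -r.pp4)
    used_e: set[int] = set()
    used_o: set[int] = set()
    chosen = []
    for r in sig:
        e, o = r.signal_pair
        if e in used_e or o in used_o:
            continue
        used_e.add(e)
        used_o.add(o)
        chosen.append(r)
    if len(chosen) < 2:
        return None

    cs_e = {cs.cs_index: cs for cs in finemap_exp.credible_sets}
    cs_o = {cs.cs_index: cs for cs in finemap_out.credible_sets}
    pos_e = {vid: i for i, vid in enumerate(finemap_exp.variant_ids)}
    pos_o = {vid: i for i, vid in enumerate(finemap_out.variant_ids)}
    bx, se_bx, by, se_by, pair_ids = [], [], [], [], []
    for r in chosen:
        e, o = r.signal_pair
        a_e = finemap_exp.alpha[cs_e[e].effect_row]
        a_o = finemap_out.alpha[cs_o[o].effect_row]
        prod = np.array(
            [
                a_e[pos_e[vid]] * a_o[pos_o[vid]]
                if vid in pos_e and vid in pos_o
                else 0.0
                for vid in pair.variant_ids
            ]
        )
        if prod.max() <= 0:
            raise EstimationError(
                "significant signal pair with disjoint variant support"
            )
        j = int(np.argmax(prod))
        bx.append(pair.beta_a[j])
        se_bx.append(pair.se_a[j])
        by.append(pair.beta_b[j])
        se_by.append(pair.se_b[j])
        pair_ids.append((e, o))
    return MRInput(np.array(bx), np.array(se_bx), np.array(by), np.array(se_by), pair_ids)
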