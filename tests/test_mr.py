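"""Mendelian randomization estimators and instrument assembly."""

import numpy as np
import pytest

from colocbench import MRInput, build_mr_input, mr_ivw, mr_locus_spread, mr_raps
from colocbench.datatypes import EstimationError
from colocbench.finemap import CredibleSet, FineMapResult
from colocbench.harmonize import HarmonizedPair
from colocbench.mr import METHODS, Z80


def make_input(bx, by, se_bx=0.01, se_by=0.1, pair_ids=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    return MRInput(bx, np.full_like(bx, se_bx), by, np.full_like(by, se_by),
                   pair_ids or [])


class TestIvw:
    def test_equal_ratios_recover_slope_exactly(self):
        est = mr_ivw(make_input([0.5, 0.25], [1.0, 0.5]), "first_order", "fixed")
        assert est.alpha_hat == pytest.approx(2.0)

    def test_hand_computed_q_and_random_inflation(self):
        # theta = (0, 2, 4), v = 1 each: alpha = 2, SE_fixed = 3^-0.5,
        # Q = 8, SE_random = sqrt(8/2) * SE_fixed = 2 * SE_fixed
        inp = make_input([1, 1, 1], [0, 2, 4], se_by=1.0)
        fixed = mr_ivw(inp, "first_order", "fixed")
        random = mr_ivw(inp, "first_order", "random")
        assert fixed.alpha_hat == pytest.approx(2.0)
        assert fixed.se == pytest.approx(3**-0.5)
        assert random.se == pytest.approx(2 * 3**-0.5)
        assert random.interval == pytest.approx(
            (2 - Z80 * 2 * 3**-0.5, 2 + Z80 * 2 * 3**-0.5))

    def test_single_instrument_ratio(self):
        est = mr_ivw(make_input([0.5], [1.0], se_by=0.1), "first_order", "fixed")
        assert est.alpha_hat == pytest.approx(2.0)
        assert est.se == pytest.approx(0.1 / 0.5)

    def test_delta_weights_add_exposure_error(self):
        inp = make_input([0.5, 0.25], [1.0, 0.5], se_bx=0.1, se_by=0.1)
        fo = mr_ivw(inp, "first_order", "fixed")
        de = mr_ivw(inp, "delta", "fixed")
        assert de.se > fo.se

    def test_zero_bx_instrument_rejected(self):
        est = mr_ivw(make_input([0.0, 0.5, 0.25], [9.9, 1.0, 0.5]))
        assert est.alpha_hat == pytest.approx(2.0)
        with pytest.raises(EstimationError):
            mr_ivw(make_input([0.0], [1.0]))

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 12))
            inp = make_input(rng.uniform(0.2, 1, k), rng.normal(0, 0.5, k))
            f = mr_ivw(inp, "delta", "fixed")
            r = mr_ivw(inp, "delta", "random")
            assert r.se >= f.se - 1e-15


class TestRaps:
    def test_agrees_with_ivw_without_violations(self, rng):
        diffs = []
        for _ in range(60):
            bx = rng.normal(0.6, 0.1, 10)
            by = 0.5 * bx + rng.normal(0, 0.03, 10)
            inp = MRInput(bx, np.full(10, 0.05), by, np.full(10, 0.03))
            diffs.append(mr_raps(inp).alpha_hat - mr_ivw(inp, "delta", "fixed").alpha_hat)
        assert abs(np.mean(diffs)) < 0.05

    def test_downweights_gross_outlier(self, rng):
        wins = 0
        for _ in range(40):
            bx = np.ones(11)
            by = np.concatenate([rng.normal(0, 0.05, 10), [10.0]])
            inp = MRInput(bx, np.full(11, 0.01), by, np.full(11, 0.05))
            wins += abs(mr_raps(inp).alpha_hat) < abs(mr_ivw(inp).alpha_hat)
        assert wins >= 0.90 * 40

    def test_overdispersion_recovery(self, rng):
        # injected tau^2 = 0.2 on the outcome scale at k = 50
        taus = []
        for _ in range(30):
            bx = rng.uniform(0.5, 1.5, 50)
            by = 0.3 * bx + rng.normal(0, np.sqrt(0.05**2 + 0.2), 50)
            inp = MRInput(bx, np.full(50, 0.01), by, np.full(50, 0.05))
            taus.append(mr_raps(inp).dispersion)
        med = np.median(taus)
        assert abs(med - 0.2) < 0.5 * 0.2

    def test_no_overdispersion_under_exact_null(self, rng):
        bx = rng.uniform(0.5, 1.5, 20)
        by = 0.4 * bx + rng.normal(0, 0.01, 20) * 0.1
        inp = MRInput(bx, np.full(20, 1e-4), by, np.full(20, 0.05))
        assert mr_raps(inp).dispersion == pytest.approx(0.0, abs=1e-6)


class TestLocusSpread:
    def test_concordant_instruments_concentrate_on_ratio(self):
        inp = make_input([0.5, 0.25], [1.0, 0.5], se_bx=0.01, se_by=0.02)
        est = mr_locus_spread(inp)
        lo, hi = est.interval
        assert lo <= 2.0 <= hi and est.significant

    def test_discordant_instruments_widen_interval(self):
        inp = make_input([0.5, 0.5], [1.0, -1.0], se_bx=0.02, se_by=0.05)
        est = mr_locus_spread(inp)
        lo, hi = est.interval
        assert lo <= 0.0 <= hi and not est.significant
        assert est.dispersion > 1.0  # wide allelic spread

    def test_null_interval_symmetric_about_zero(self):
        inp = make_input([0.5, 0.4, 0.6], [0.0, 0.0, 0.0], se_by=0.05)
        est = mr_locus_spread(inp)
        assert est.alpha_hat == pytest.approx(0.0, abs=1e-6)
        assert est.interval[0] == pytest.approx(-est.interval[1], rel=1e-3)


class TestProperties:
    @pytest.mark.parametrize("method", list(METHODS))
    def test_scale_equivariance_in_outcome_units(self, method, rng):
        bx = rng.uniform(0.4, 1.0, 6)
        by = 0.7 * bx + rng.normal(0, 0.05, 6)
        inp = MRInput(bx, np.full(6, 0.03), by, np.full(6, 0.05))
        c = 3.7
        scaled = MRInput(bx, np.full(6, 0.03), c * by, np.full(6, c * 0.05))
        e1, e2 = METHODS[method](inp), METHODS[method](scaled)
        tol = 1e-8 if method.startswith("ivw") else 2e-2
        assert e2.alpha_hat == pytest.approx(c * e1.alpha_hat, rel=tol, abs=tol)
        assert e2.interval[0] == pytest.approx(c * e1.interval[0], rel=tol, abs=tol)
        assert e2.interval[1] == pytest.approx(c * e1.interval[1], rel=tol, abs=tol)

    def test_fixed_model_overrejects_under_heterogeneous_null(self, rng):
        # per-locus slopes spread around a zero mean: the fixed model's 80%
        # interval excludes 0 far more often than the multiplicative
        # random-effects model
        fp_fixed = fp_random = 0
        n_loci = 500
        for _ in range(n_loci):
            k = int(rng.integers(2, 5))
            bx = rng.uniform(0.3, 1.0, k)
            slopes = rng.normal(0.0, 0.5, k)  # heterogeneous, mean zero
            by = slopes * bx + rng.normal(0, 0.02, k)
            inp = MRInput(bx, np.full(k, 0.01), by, np.full(k, 0.02))
            fp_fixed += mr_ivw(inp, "delta", "fixed").significant
            fp_random += mr_ivw(inp, "delta", "random").significant
        assert fp_fixed > fp_random

    def test_homogeneous_null_calibration(self, rng):
        # with exact SEs and a true zero slope, fixed IVW rejects ~20%
        hits = 0
        n_loci = 2000
        for _ in range(n_loci):
            bx = rng.uniform(0.5, 1.0, 4)
            by = rng.normal(0, 0.05, 4)
            inp = MRInput(bx, np.full(4, 1e-6), by, np.full(4, 0.05))
            hits += mr_ivw(inp, "first_order", "fixed").significant
        assert 0.17 <= hits / n_loci <= 0.23

    @pytest.mark.parametrize("method", list(METHODS))
    def test_recovery_under_no_violation_model(self, method, rng):
        ests = []
        for _ in range(40):
            bx = rng.uniform(0.5, 1.5, 12)
            by = 0.5 * bx + rng.normal(0, 0.02, 12)
            inp = MRInput(bx, np.full(12, 0.01), by, np.full(12, 0.02))
            ests.append(METHODS[method](inp).alpha_hat)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.02)


def _fake_finemap(ids, rows):
    alpha = np.asarray(rows, dtype=float)
    sets = []
    for i in range(alpha.shape[0]):
        members = np.argsort(-alpha[i])[:2]
        sets.append(CredibleSet(
            cs_index=i + 1, variant_ids=frozenset(ids[j] for j in members),
            member_indices=np.sort(members), alpha_mass=float(alpha[i][members].sum()),
            purity=1.0, lead_variant=ids[members[0]], lead_index=int(members[0]),
            effect_row=i))
    return FineMapResult(variant_ids=list(ids), alpha=alpha,
                         lbf=np.log(alpha + 1e-9), pip=1 - np.prod(1 - alpha, 0),
                         credible_sets=sets)


class _FakeBf:
    method = "bf_bf"

    def __init__(self, signal_pair, pp4, significant=True):
        self.signal_pair = signal_pair
        self.pp4 = pp4
        self.significant = significant


def _pair(ids):
    m = len(ids)
    return HarmonizedPair(
        variant_ids=list(ids), pos=np.arange(m),
        beta_a=np.linspace(0.5, 0.6, m), se_a=np.full(m, 0.05),
        maf_a=np.full(m, 0.3), beta_b=np.linspace(0.2, 0.3, m),
        se_b=np.full(m, 0.02), maf_b=np.full(m, 0.3), n_a=300, n_b=3000,
        idx_a=np.arange(m), idx_b=np.arange(m),
        n_flipped=0, n_ambiguous=0, n_incompatible=0)


class TestBuildMrInput:
    ids = [f"v{i}" for i in range(6)]

    def setup_method(self):
        exp_rows = [[0.9, 0.05, 0.05, 0, 0, 0], [0, 0, 0, 0.8, 0.1, 0.1]]
        out_rows = [[0, 0.1, 0, 0.8, 0.1, 0], [0.7, 0.2, 0.1, 0, 0, 0],
                    [0, 0, 0, 0, 0.5, 0.5], [0, 0, 0.9, 0.1, 0, 0],
                    [0, 0, 0, 0.1, 0.2, 0.7]]
        self.fm_exp = _fake_finemap(self.ids, exp_rows)
        self.fm_out = _fake_finemap(self.ids, out_rows)
        self.pair = _pair(self.ids)

    def test_two_distinct_pairs_build_k2_input(self):
        bf = [_FakeBf((1, 2), 0.95), _FakeBf((2, 5), 0.9)]
        inp = build_mr_input(bf, self.fm_exp, self.fm_out, self.pair)
        assert inp is not None and inp.k == 2
        assert inp.pair_ids == [(1, 2), (2, 5)]
        # instrument = argmax of the alpha-row product per pair
        assert inp.bx[0] == pytest.approx(self.pair.beta_a[0])
        assert inp.bx[1] == pytest.approx(self.pair.beta_a[3])

    def test_single_pair_is_insufficient(self):
        assert build_mr_input([_FakeBf((1, 1), 0.95)],
                              self.fm_exp, self.fm_out, self.pair) is None

    def test_shared_exposure_signal_violates_distinctness(self):
        bf = [_FakeBf((1, 2), 0.95), _FakeBf((1, 5), 0.9)]
        assert build_mr_input(bf, self.fm_exp, self.fm_out, self.pair) is None
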