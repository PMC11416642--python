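"""Synthetic locus generator: LD, traits, association testing, catalogs."""

import numpy as np
import pytest
from scipy import stats as sps

from colocbench import (
    CausalArchitecture,
    LocusConfig,
    marginal_sumstats,
    simulate_benchmark_catalog,
    simulate_locus,
    simulate_traits,
)
from colocbench.simulate import Locus, Variant, inverse_normal_transform


def small_config(**kw):
    defaults = dict(m=40, n_exp=200, n_out=1800, rho=0.9, block_size=8,
                    maf_range=(0.05, 0.5))
    defaults.update(kw)
    return LocusConfig(**defaults)


class TestSimulateLocus:
    def test_independent_variants_have_near_zero_ld(self):
        loc = simulate_locus(LocusConfig(m=50, n_exp=1000, n_out=1000, rho=0.0, seed=3))
        off = loc.R[~np.eye(loc.m, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.05

    def test_high_copy_rate_gives_strong_adjacent_ld(self):
        cfg = LocusConfig(m=60, n_exp=1000, n_out=1000, rho=0.95, block_size=10, seed=4)
        loc = simulate_locus(cfg)
        adj = [loc.R[j, j + 1] ** 2 for j in range(loc.m - 1)
               if (j + 1) % cfg.block_size != 0]
        assert np.median(adj) > 0.5

    def test_same_seed_is_bit_identical(self):
        cfg = small_config(seed=9)
        a, b = simulate_locus(cfg), simulate_locus(cfg)
        assert np.array_equal(a.dosages_exp, b.dosages_exp)
        assert np.array_equal(a.dosages_out, b.dosages_out)
        assert np.array_equal(a.R, b.R)

    def test_realized_maf_within_range(self):
        # conservation: frequencies stay inside the configured band up to
        # binomial sampling noise for essentially all variants
        cfg = LocusConfig(m=200, n_exp=1000, n_out=1000, rho=0.8, seed=5,
                          maf_range=(0.05, 0.5))
        loc = simulate_locus(cfg)
        pooled = np.vstack([loc.dosages_exp, loc.dosages_out])
        f = pooled.mean(axis=0) / 2
        maf = np.minimum(f, 1 - f)
        n_hap = 2 * pooled.shape[0]
        slack = 3 * np.sqrt(0.05 * 0.95 / n_hap)
        assert np.mean(maf >= 0.05 - slack) >= 0.99


class TestSimulateTraits:
    def test_null_phenotype_z_scores_are_standard_normal(self):
        # LD-free loci so the pooled z-scores are approximately independent
        zs = []
        for seed in range(20):
            loc = simulate_locus(small_config(seed=seed, rho=0.0))
            arch = CausalArchitecture([], [], [], "H0")
            y, _, _, _ = simulate_traits(loc, arch, np.random.default_rng(seed))
            zs.append(marginal_sumstats(loc.dosages_exp, y, loc.variants, "g").z)
        pooled = np.concatenate(zs)
        assert sps.kstest(pooled, "norm").pvalue > 0.01

    def test_variance_explained_calibration(self):
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            loc = simulate_locus(LocusConfig(m=10, n_exp=2000, n_out=2, rho=0.0, seed=seed))
            arch = CausalArchitecture([(4, 0.10, 1)], [], [], "H1")
            y, _, _, _ = simulate_traits(loc, arch, np.random.default_rng(seed + 1))
            r2 = np.corrcoef(loc.dosages_exp[:, 4], y)[0, 1] ** 2
            hits += 0.06 <= r2 <= 0.14
        assert hits >= 0.90 * n_rep

    def test_inverse_normal_output_has_no_skew(self, rng):
        y = rng.exponential(size=3000)  # heavily skewed input
        t = inverse_normal_transform(y)
        assert abs(sps.skew(t)) < 0.1

    def test_shared_causal_concordance_bookkeeping(self):
        arch = CausalArchitecture([(1, 0.1, 1)], [(1, 0.05, -1)], [(1, 1)])
        assert arch.concordance == [-1]
        with pytest.raises(ValueError, match="shared pairs"):
            CausalArchitecture([(1, 0.1, 1)], [], [(2, 2)])

    def test_total_variance_must_stay_below_one(self):
        with pytest.raises(ValueError):
            CausalArchitecture([(0, 0.5, 1), (1, 0.5, 1)], [], [])


class TestMarginalSumstats:
    def test_hand_computed_ols_toy(self):
        # dosages 0,1,1,2 / phenotype 0,1,2,3: Sxy = 3, Sxx = 2 -> beta 1.5
        variants = [Variant("v1", "chr1", 100, "A", "G")]
        d = np.array([[0.0], [1.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        s = marginal_sumstats(d, y, variants, "g")
        assert s.beta[0] == pytest.approx(1.5)
        # residuals: y_hat = 1.5 + 1.5*(x-1); rss = 0.5; se = sqrt(0.25/2)
        assert s.se[0] == pytest.approx(np.sqrt(0.25 / 2))
        assert s.maf[0] == pytest.approx(0.5)

    def test_estimates_cover_truth(self):
        # OLS consistency: estimate within 3 SEs of the true slope nearly always
        hits = n_rep = 0
        for seed in range(60):
            loc = simulate_locus(LocusConfig(m=5, n_exp=2, n_out=3000, rho=0.0, seed=seed))
            rng = np.random.default_rng(seed + 7)
            y, truth = _outcome_only(loc, 2, 0.05, rng)
            s = marginal_sumstats(loc.dosages_out, y, loc.variants, "p")
            hits += abs(s.beta[2] - truth) <= 3 * s.se[2]
            n_rep += 1
        assert hits / n_rep >= 0.95

    def test_permuted_phenotype_type_one_error(self, rng):
        loc = simulate_locus(LocusConfig(m=30, n_exp=800, n_out=2, rho=0.0, seed=42))
        count = total = 0
        for _ in range(50):
            y = rng.standard_normal(loc.dosages_exp.shape[0])
            s = marginal_sumstats(loc.dosages_exp, y, loc.variants, "g")
            count += int(np.sum(np.abs(s.z) > 1.96))
            total += len(s)
        assert 0.03 <= count / total <= 0.07


def _outcome_only(loc, idx, ve, rng):
    d = loc.dosages_out[:, idx]
    beta = np.sqrt(ve / (1 - ve) / d.var())
    y = beta * d + rng.standard_normal(len(d))
    return y, beta


@pytest.fixture(scope="module")
def tiny_locus_config():
    return LocusConfig(m=30, n_exp=150, n_out=600, rho=0.9, block_size=6)


class TestBenchmarkCatalog:

    def test_zero_pleiotropy_truth_has_no_neighbor_sharing(self, tiny_locus_config):
        cat = simulate_benchmark_catalog(6, pleiotropy_rate=0.0, multi_signal_rate=0.5,
                                         config=tiny_locus_config, seed=1)
        coding = set(cat.coding_gene_map.values())
        assert all(t.gene_id in coding for t in cat.truth)

    def test_full_pleiotropy_every_neighbor_shares(self, tiny_locus_config):
        cat = simulate_benchmark_catalog(6, genes_per_locus=3, pleiotropy_rate=1.0,
                                         multi_signal_rate=0.0, config=tiny_locus_config, seed=2)
        for pl in cat.loci:
            shared_genes = {t.gene_id for t in cat.truth if t.protein_id == pl.protein_id}
            assert shared_genes == {g.gene_id for g in pl.genes}

    def test_full_multi_signal_rate_gives_two_shared_signals(self, tiny_locus_config):
        cat = simulate_benchmark_catalog(6, pleiotropy_rate=0.0, multi_signal_rate=1.0,
                                         config=tiny_locus_config, seed=3)
        for pl in cat.loci:
            n_signals = {t.signal for t in cat.truth
                         if t.protein_id == pl.protein_id and t.gene_id == pl.coding_gene_id}
            assert n_signals == {1, 2}

    def test_causal_variants_inside_coding_gene_body(self, tiny_locus_config):
        cat = simulate_benchmark_catalog(8, config=tiny_locus_config, seed=4)
        for pl in cat.loci:
            body = next(g for g in pl.genes if g.gene_id == pl.coding_gene_id)
            for idx in pl.causal_indices:
                assert body.start <= pl.locus.variants[idx].pos <= body.end

    def test_coding_gene_truth_slopes_are_concordant_by_default(self, tiny_locus_config):
        cat = simulate_benchmark_catalog(8, config=tiny_locus_config, seed=5)
        coding = set(cat.coding_gene_map.values())
        assert all(t.true_bx * t.true_by > 0 for t in cat.truth if t.gene_id in coding)

    def test_catalog_is_reproducible(self, tiny_locus_config):
        a = simulate_benchmark_catalog(3, config=tiny_locus_config, seed=6)
        b = simulate_benchmark_catalog(3, config=tiny_locus_config, seed=6)
        assert np.array_equal(a.loci[2].protein_stats.beta, b.loci[2].protein_stats.beta)
        assert [(t.protein_id, t.gene_id, t.signal) for t in a.truth] == [
            (t.protein_id, t.gene_id, t.signal) for t in b.truth
        ]
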