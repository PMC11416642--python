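"""Synthetic paired eQTL/pQTL loci with known LD and causal architecture.

The generator emulates the statistical structure of a two-sample cis-QTL
design: a small expression cohort and a large protein cohort drawn from
one population, genotyped on a shared haplotype pool with block LD, with
1-5 causal variants per trait and configurable sharing between the protein
and the genes in its locus. Neighbor genes can be co-regulated by the
protein's causal variant (horizontal pleiotropy), which is the confound
the benchmark is designed to expose.

Effect sizes are parameterized by variance explained so that power is
comparable across allele frequencies. Protein phenotypes are passed
through a rank-based inverse normal transform, mirroring standard pQTL
processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datatypes import ColocbenchError, GeneAnnotation, RegionSummaryStats, Variant

_ALLELES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class LocusConfig:
    """Parameters of one simulated cis-locus.

    LD is produced by a first-order haplotype copy process: within a block
    of ``block_size`` adjacent variants, each variant copies the previous
    variant's allele on the same haplotype with probability ``rho``, else
    draws fresh from its own allele frequency. Blocks are independent.
    """

    m: int = 150
    n_exp: int = 300
    n_out: int = 3000
    rho: float = 0.9
    block_size: int = 15
    maf_range: tuple[float, float] = (0.05, 0.5)
    spacing: int = 1000
    start_pos: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= lo < hi <= 0.5")


@dataclass(frozen=True)
class CausalArchitecture:
    """Causal variants per trait with configurable sharing.

    ``exp_causals`` / ``out_causals`` are lists of (variant index, variance
    explained, effect sign). ``shared`` lists (exposure index, outcome
    index) pairs declared identical across traits — for shared causals
    both entries use the same variant index.
    """

    exp_causals: list[tuple[int, float, int]] = field(default_factory=list)
    out_causals: list[tuple[int, float, int]] = field(default_factory=list)
    shared: list[tuple[int, int]] = field(default_factory=list)
    scenario_label: str = "H4"

    def __post_init__(self) -> None:
        for causals in (self.exp_causals, self.out_causals):
            for _, ve, sign in causals:
                if not (0 < ve <= 0.5):
                    raise ValueError("variance explained per causal must be in (0, 0.5]")
                if sign not in (-1, 1):
                    raise ValueError("effect sign must be -1 or +1")
            if sum(ve for _, ve, _ in causals) >= 1:
                raise ValueError("total variance explained per trait must be < 1")
        exp_idx = {i for i, _, _ in self.exp_causals}
        out_idx = {i for i, _, _ in self.out_causals}
        for ie, io in self.shared:
            if ie not in exp_idx or io not in out_idx:
                raise ValueError("shared pairs must reference declared causals")

    @property
    def concordance(self) -> list[int]:
        """Sign of true exposure x outcome effect per shared causal."""
        es = {i: s for i, _, s in self.exp_causals}
        os_ = {i: s for i, _, s in self.out_causals}
        return [es[ie] * os_[io] for ie, io in self.shared]


@dataclass
class Locus:
    """Realized genotypes for one simulated region."""

    variants: list[Variant]
    dosages_exp: np.ndarray  # (n_exp, m) diploid dosage
    dosages_out: np.ndarray
    R: np.ndarray  # pooled empirical dosage correlation, unit diagonal
    freq: np.ndarray  # target allele frequencies

    @property
    def m(self) -> int:
        return len(self.variants)


def _haplotypes(config: LocusConfig, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    f = rng.uniform(lo, hi, size=config.m)
    H = np.empty((n_hap, config.m), dtype=np.int8)
    fresh = rng.random((n_hap, config.m)) < f
    copy = rng.random((n_hap, config.m)) < config.rho
    for j in range(config.m):
        if j % config.block_size == 0:
            H[:, j] = fresh[:, j]
        else:
            H[:, j] = np.where(copy[:, j], H[:, j - 1], fresh[:, j])
    return H


def simulate_locus(
    config: LocusConfig, rng: np.random.Generator | None = None, chrom: str = "chr1"
) -> Locus:
    """Draw both cohorts' dosages from one haplotype pool and return the
    realized LD correlation matrix of the pooled cohorts."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_total = config.n_exp + config.n_out
    H = _haplotypes(config, 2 * n_total, rng)
    dosage = (H[0::2] + H[1::2]).astype(np.float64)

    # a monomorphic variant carries no information: redraw once, then fail
    mono = np.flatnonzero(dosage.std(axis=0) == 0)
    if mono.size:
        lo, hi = config.maf_range
        for j in mono:
            f_j = rng.uniform(lo, hi)
            dosage[:, j] = rng.binomial(2, f_j, size=n_total)
            if dosage[:, j].std() == 0:
                raise ColocbenchError(f"variant {j} monomorphic after resampling")

    R = np.corrcoef(dosage, rowvar=False)
    np.fill_diagonal(R, 1.0)
    alle = rng.integers(0, 4, size=(config.m, 2))
    variants = []
    for j in range(config.m):
        ref = _ALLELES[alle[j, 0]]
        alt = _ALLELES[(alle[j, 0] + 1 + alle[j, 1] % 3) % 4]
        pos = config.start_pos + j * config.spacing
        variants.append(Variant(id=f"{chrom}_{pos}_{ref}_{alt}", chrom=chrom, pos=pos, ref=ref, alt=alt))
    freq = H.mean(axis=0)
    return Locus(
        variants=variants,
        dosages_exp=dosage[: config.n_exp],
        dosages_out=dosage[config.n_exp :],
        R=R,
        freq=freq,
    )


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset c = 3/8)."""
    n = len(y)
    ranks = sps.rankdata(y, method="average")
    return sps.norm.ppf((ranks - 0.375) / (n + 0.25))


def _phenotype(
    dosage: np.ndarray,
    causals: list[tuple[int, float, int]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[int, float]]:
    """Additive phenotype with per-causal variance fractions and N(0,1) noise.

    beta_c is scaled so variant c explains its configured fraction of the
    total phenotypic variance given its realized dosage variance.
    """
    n = dosage.shape[0]
    total_ve = sum(ve for _, ve, _ in causals)
    if total_ve >= 1:
        raise ValueError("total variance explained must be < 1")
    y = rng.standard_normal(n)
    betas: dict[int, float] = {}
    for idx, ve, sign in causals:
        v = dosage[:, idx].var()
        if v == 0:
            raise ColocbenchError(f"causal variant {idx} has zero dosage variance")
        beta = sign * np.sqrt(ve / (1 - total_ve) / v)
        y = y + beta * dosage[:, idx]
        betas[idx] = beta
    return y, betas


def simulate_traits(
    locus: Locus, arch: CausalArchitecture, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[int, float], dict[int, float]]:
    """Exposure and outcome phenotypes; the outcome is rank-INT transformed.

    Returns (y_exp, y_out, true_betas_exp, true_betas_out) with true betas
    on the pre-transform scale.
    """
    y_exp, b_exp = _phenotype(locus.dosages_exp, arch.exp_causals, rng)
    y_out, b_out = _phenotype(locus.dosages_out, arch.out_causals, rng)
    y_out = inverse_normal_transform(y_out)
    return y_exp, y_out, b_exp, b_out


def marginal_sumstats(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    variants: list[Variant],
    trait_id: str,
    dataset_id: str = "simulated",
) -> RegionSummaryStats:
    """Per-variant simple linear regression of phenotype on dosage.

    beta = cov/var, se from OLS residual variance with n-2 df; maf is the
    folded sample allele frequency. Zero-variance dosage columns are
    dropped (they carry no association information).
    """
    n, m = dosages.shape
    if len(phenotype) != n:
        raise ValueError("phenotype length must equal cohort size")
    x = dosages - dosages.mean(axis=0)
    y = phenotype - phenotype.mean()
    sxx = np.einsum("ij,ij->j", x, x)
    keep = np.flatnonzero(sxx > 0)
    x = x[:, keep]
    sxx = sxx[keep]
    sxy = y @ x
    syy = float(y @ y)
    beta = sxy / sxx
    rss = syy - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    f = dosages[:, keep].mean(axis=0) / 2
    maf = np.minimum(f, 1 - f)
    return RegionSummaryStats(
        trait_id=trait_id,
        dataset_id=dataset_id,
        variants=[variants[j] for j in keep],
        beta=beta,
        se=se,
        maf=maf,
        n=n,
    )


@dataclass
class TruthRecord:
    """One truth-shared (protein, gene, signal) label."""

    protein_id: str
    gene_id: str
    signal: int  # 1-based causal signal index within the locus
    variant_index: int
    true_bx: float
    true_by: float


@dataclass
class ProteinLocus:
    """All per-locus artifacts for one protein and its neighborhood."""

    protein_id: str
    coding_gene_id: str
    locus: Locus
    genes: list[GeneAnnotation]
    gene_stats: dict[str, RegionSummaryStats]
    protein_stats: RegionSummaryStats
    causal_indices: list[int]  # outcome causal variant indices, primary first


@dataclass
class SyntheticCatalog:
    """A benchmark catalog of protein loci with ground-truth labels."""

    loci: list[ProteinLocus]
    truth: list[TruthRecord]
    complex_proteins: set[str] = field(default_factory=set)

    @property
    def genes(self) -> list[GeneAnnotation]:
        return [g for pl in self.loci for g in pl.genes]

    @property
    def coding_gene_map(self) -> dict[str, str]:
        return {pl.protein_id: pl.coding_gene_id for pl in self.loci}


#: study-condition defaults. Shared (gene <-> protein) signals draw their
#: exposure-side variance explained log-uniformly from this range, spanning
#: weak-but-fine-mappable to strong primary cis-eQTLs at n ~ 300 (the truth
#: universe mirrors loci where fine-mapping yields purity-filtered sets).
VE_EXP_RANGE = (0.09, 0.25)
#: adjacent-variant copy probability of the benchmark catalog: cis regions
#: carry runs of near-perfect proxies, which disperses posterior inclusion
#: mass across variants the way real fine-mapping does
CATALOG_RHO = 0.99
#: outcome-side variance explained of a shared signal relative to the
#: exposure side (plasma pQTL effects are attenuated relative to eQTLs).
OUT_TO_EXP_VE = 0.3
#: secondary shared signals are weaker than primary ones by this factor
SECONDARY_VE_FACTOR = 0.5
#: rate of gene-specific eQTLs that do not propagate to the protein
#: (post-transcriptional buffering); drawn stronger than the shared signal
#: so they dominate the gene's marginal statistics
GENE_SPECIFIC_RATE = 0.3
#: rate of protein-specific pQTLs with no expression effect (e.g. variants
#: altering protein stability or epitope), stronger than the shared signal
PROTEIN_SPECIFIC_RATE = 0.2
#: conditional probability that a co-regulated neighbor shares ALL of the
#: protein's causal variants (strong local co-regulation), with its own
#: effect size and direction per signal - the scenario in which even
#: multi-signal MR can be misled
FULL_COREGULATION_RATE = 0.25


def _distinct_block_index(
    idx_taken: list[int], m: int, block_size: int, rng: np.random.Generator, span: int = 25
) -> int:
    """A variant index near ``idx_taken[0]`` in an LD block not yet used."""
    anchor = idx_taken[0]
    taken_blocks = {i // block_size for i in idx_taken}
    candidates = [
        j
        for j in range(max(0, anchor - span), min(m, anchor + span + 1))
        if j // block_size not in taken_blocks
    ]
    return int(rng.choice(candidates))


def simulate_benchmark_catalog(
    n_proteins: int,
    genes_per_locus: int = 3,
    pleiotropy_rate: float = 0.5,
    multi_signal_rate: float = 0.5,
    config: LocusConfig | None = None,
    seed: int = 0,
    concordant: bool = True,
    gene_specific_rate: float = GENE_SPECIFIC_RATE,
    protein_specific_rate: float = PROTEIN_SPECIFIC_RATE,
    full_coregulation_rate: float = FULL_COREGULATION_RATE,
    ve_exp_range: tuple[float, float] = VE_EXP_RANGE,
) -> SyntheticCatalog:
    """Simulate a catalog of protein loci with co-regulated neighbor genes.

    Each protein locus has one coding gene whose body contains the causal
    variant(s), plus ``genes_per_locus - 1`` protein-coding neighbors at
    distinct TSS offsets. With probability ``pleiotropy_rate`` a neighbor
    gene shares the protein's primary causal variant (co-regulation); with
    probability ``multi_signal_rate`` a second, conditionally distinct
    shared causal is added. Trait-specific signals (gene-only eQTLs from
    buffering, protein-only pQTLs from protein-altering variants) occur at
    their configured rates and are never shared. A co-regulated neighbor
    of a multi-signal locus shares every causal variant with probability
    ``full_coregulation_rate``, each with an independent effect size and
    direction - the strong-co-regulation confound that can mislead even
    multi-signal MR.
    """
    for rate in (pleiotropy_rate, multi_signal_rate, gene_specific_rate, protein_specific_rate):
        if not (0 <= rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
    if config is None:
        config = LocusConfig(rho=CATALOG_RHO)
    rng = np.random.default_rng(seed)

    loci: list[ProteinLocus] = []
    truth: list[TruthRecord] = []
    for p in range(n_proteins):
        chrom = f"chr{p + 1}"
        locus = simulate_locus(config, rng=rng, chrom=chrom)
        m = locus.m
        pos = np.asarray([v.pos for v in locus.variants])

        # primary shared causal in the middle third; further causals land
        # in different LD blocks but stay inside the coding gene body
        idx1 = int(rng.integers(m // 3, 2 * m // 3))
        causal_idx = [idx1]
        idx2 = None
        if rng.random() < multi_signal_rate:
            idx2 = _distinct_block_index(causal_idx, m, config.block_size, rng)
            causal_idx.append(idx2)
        idx_gene_spec = None
        if rng.random() < gene_specific_rate:
            idx_gene_spec = _distinct_block_index(causal_idx, m, config.block_size, rng)
            causal_idx.append(idx_gene_spec)
        idx_prot_spec = None
        if rng.random() < protein_specific_rate:
            idx_prot_spec = _distinct_block_index(causal_idx, m, config.block_size, rng)
            causal_idx.append(idx_prot_spec)

        lohi = pos[causal_idx]
        body_lo = int(lohi.min()) - 5000
        body_hi = int(lohi.max()) + 5000
        coding_id = f"GENE{p + 1}_0"
        protein_id = f"PROT{p + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes = [GeneAnnotation(coding_id, chrom, body_lo, body_hi, strand, True)]
        offsets = [60_000, -60_000, 110_000, -110_000, 160_000, -160_000]
        for g in range(genes_per_locus - 1):
            off = offsets[g % len(offsets)] * (1 + g // len(offsets))
            lo = body_lo + off
            genes.append(
                GeneAnnotation(f"GENE{p + 1}_{g + 1}", chrom, max(1, lo), max(1, lo) + 20_000,
                               "+" if rng.random() < 0.5 else "-", True)
            )

        lo_ve, hi_ve = ve_exp_range
        ve1 = float(np.exp(rng.uniform(np.log(lo_ve), np.log(hi_ve))))
        sign = 1 if concordant else int(rng.choice([-1, 1]))
        out_causals = [(idx1, OUT_TO_EXP_VE * ve1, sign)]
        coding_causals = [(idx1, ve1, 1)]
        shared_coding = [(idx1, idx1)]
        if idx2 is not None:
            ve2 = SECONDARY_VE_FACTOR * ve1
            out_causals.append((idx2, OUT_TO_EXP_VE * ve2, sign))
            coding_causals.append((idx2, ve2, 1))
            shared_coding.append((idx2, idx2))
        if idx_gene_spec is not None:
            coding_causals.append((idx_gene_spec, min(1.6 * ve1, 0.4), 1))
        if idx_prot_spec is not None:
            out_causals.append((idx_prot_spec, min(2.5 * OUT_TO_EXP_VE * ve1, 0.3), sign))

        arch = CausalArchitecture(coding_causals, out_causals, shared_coding, "H4")
        y_exp, y_out, bx_true, by_true = simulate_traits(locus, arch, rng)
        protein_stats = marginal_sumstats(locus.dosages_out, y_out, locus.variants, protein_id)
        gene_stats = {
            coding_id: marginal_sumstats(locus.dosages_exp, y_exp, locus.variants, coding_id)
        }
        for s, (ie, io) in enumerate(shared_coding, start=1):
            truth.append(
                TruthRecord(protein_id, coding_id, s, ie, bx_true[ie], by_true[io])
            )

        # neighbor genes: co-regulated by the primary causal with the
        # configured pleiotropy rate, otherwise null traits. A co-regulated
        # neighbor occasionally shares every causal variant with its own
        # effect size and direction per signal (strong local co-regulation)
        for gene in genes[1:]:
            if rng.random() < pleiotropy_rate:
                full = idx2 is not None and rng.random() < full_coregulation_rate
                shared_idx = [idx1, idx2] if full else [idx1]
                n_causals = []
                for s, ci in enumerate(shared_idx, start=1):
                    ve_g = float(np.exp(rng.uniform(np.log(lo_ve), np.log(hi_ve))))
                    sign_g = int(rng.choice([-1, 1])) if full else 1
                    n_causals.append((ci, ve_g, sign_g))
                y_g, bg = _phenotype(locus.dosages_exp, n_causals, rng)
                for s, ci in enumerate(shared_idx, start=1):
                    truth.append(
                        TruthRecord(protein_id, gene.gene_id, s, ci, bg[ci], by_true[ci])
                    )
            else:
                y_g = rng.standard_normal(config.n_exp)
            gene_stats[gene.gene_id] = marginal_sumstats(
                locus.dosages_exp, y_g, locus.variants, gene.gene_id
            )

        loci.append(
            ProteinLocus(
                protein_id=protein_id,
                coding_gene_id=coding_id,
                locus=locus,
                genes=genes,
                gene_stats=gene_stats,
                protein_stats=protein_stats,
                causal_indices=[idx1] + ([idx2] if idx2 is not None else []),
            )
        )
    return SyntheticCatalog(loci=loci, truth=truth)
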