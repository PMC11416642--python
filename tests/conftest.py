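import numpy as np
import pytest

from colocbench import RegionSummaryStats, Variant


def make_stats(
    beta,
    se=None,
    trait_id="trait",
    chrom="chr1",
    start=1000,
    spacing=1000,
    maf=None,
    n=500,
    ids=None,
    alleles=None,
):
    """Build a RegionSummaryStats from plain lists for unit tests."""
    beta = np.asarray(beta, dtype=float)
    m = len(beta)
    se = np.full(m, 0.1) if se is None else np.asarray(se, dtype=float)
    maf = np.full(m, 0.3) if maf is None else np.asarray(maf, dtype=float)
    variants = []
    for j in range(m):
        ref, alt = alleles[j] if alleles else ("A", "G")
        pos = start + j * spacing
        vid = ids[j] if ids else f"{chrom}_{pos}"
        variants.append(Variant(id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt))
    return RegionSummaryStats(
        trait_id=trait_id, dataset_id="test", variants=variants,
        beta=beta, se=se, maf=maf, n=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
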