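"""Shared settings for the numbered analysis drivers."""

from pathlib import Path

from colocbench import simulate_benchmark_catalog

RESULTS = Path(__file__).resolve().parent.parent / "results"
CATALOG_SEED = 29
N_PROTEINS = 30


def build_catalog():
    """The study catalog used by every driver (deterministic in the seed)."""
    return simulate_benchmark_catalog(
        N_PROTEINS, genes_per_locus=3, pleiotropy_rate=0.5,
        multi_signal_rate=0.6, seed=CATALOG_SEED,
    )
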