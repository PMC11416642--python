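"""End-to-end benchmark: simulate -> fine-map -> colocalize -> MR -> score.

Runs every stage on a synthetic catalog and emits one report per method
(closest-gene baseline in gene-body and TSS modes, the three
colocalization methods under the first-outcome-signal restriction, the
multi-signal filter without MR, and the five MR estimators), mirroring a
benchmark table of precision, recall, and slope-sign concordance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .benchmark import (
    BenchmarkReport,
    Prediction,
    TruthMap,
    closest_genes,
    round_pct,
    score_method,
    sign_concordance,
)
from .coloc import clpp, coloc_abf, coloc_bf_bf
from .datatypes import ColocbenchError, ColocPriors
from .finemap import FineMapConfig, susie_rss
from .harmonize import harmonize_pair, window_overlap_fraction
from .mr import METHODS, MREstimate, build_mr_input
from .simulate import LocusConfig, SyntheticCatalog, simulate_benchmark_catalog

logger = logging.getLogger(__name__)

MR_METHODS = ("ivw", "ivw_delta", "ivw_delta_random", "raps", "locus_spread")


@dataclass
class RunConfig:
    """Structured configuration for a full benchmark run."""

    locus: LocusConfig = field(default_factory=LocusConfig)
    finemap: FineMapConfig = field(default_factory=FineMapConfig)
    priors: ColocPriors = field(default_factory=ColocPriors)
    n_proteins: int = 50
    genes_per_locus: int = 3
    pleiotropy_rate: float = 0.5
    multi_signal_rate: float = 0.5
    min_window_overlap: float = 0.1
    pp4_threshold: float = 0.8
    clpp_threshold: float = 0.1
    clpp_use_overall_pip: bool = False
    seed: int = 0
    output_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "locus" in raw:
            kwargs["locus"] = LocusConfig(**{**raw["locus"],
                "maf_range": tuple(raw["locus"].get("maf_range", (0.05, 0.5)))})
        if "finemap" in raw:
            kwargs["finemap"] = FineMapConfig(**raw["finemap"])
        if "priors" in raw:
            kwargs["priors"] = ColocPriors(**raw["priors"])
        for key in ("n_proteins", "genes_per_locus", "pleiotropy_rate",
                    "multi_signal_rate", "min_window_overlap", "pp4_threshold",
                    "clpp_threshold", "clpp_use_overall_pip", "seed", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def stage_seed(seed: int, stage: int) -> np.random.SeedSequence:
    """Counter-based fan-out of the global seed to per-stage streams."""
    return np.random.SeedSequence(entropy=seed, spawn_key=(stage,))


@dataclass
class EndToEndResult:
    reports: dict[str, BenchmarkReport]
    truth_map: TruthMap
    coloc_rows: list[dict]
    mr_rows: list[dict]

    def table(self) -> list[dict]:
        rows = []
        for name, rep in self.reports.items():
            rows.append(
                {
                    "method": name,
                    "tp": rep.tp,
                    "fp": rep.fp,
                    "fn": rep.fn,
                    "precision_pct": round_pct(rep.precision),
                    "recall_pct": round_pct(rep.recall),
                    "tp_positive_slope": rep.tp_positive_slope,
                    "fp_positive_slope": rep.fp_positive_slope,
                }
            )
        return rows


def run_end_to_end(catalog: SyntheticCatalog, config: RunConfig | None = None) -> EndToEndResult:
    """Execute fine-mapping, the three colocalization methods, the
    multi-signal filter, and all five MR estimators on a catalog, then
    score every method against the ground truth."""
    if config is None:
        config = RunConfig()
    priors = config.priors
    fmc = config.finemap

    tested: set[str] = set()
    preds: dict[str, list[Prediction]] = {
        "closest_gene": [], "closest_gene_tss": [],
        "abf": [], "bf_bf": [], "clpp": [], "multi_signal": [],
        **{m: [] for m in MR_METHODS},
    }
    mr_labeled: dict[str, list[tuple[MREstimate, bool]]] = {m: [] for m in MR_METHODS}
    coloc_rows: list[dict] = []
    mr_rows: list[dict] = []

    for pl in catalog.loci:
        if pl.protein_id in catalog.complex_proteins:
            continue  # protein complexes are excluded from the universe
        try:
            fm_out = susie_rss(pl.protein_stats, pl.locus.R, fmc)
        except ColocbenchError as exc:
            logger.warning("fine-mapping failed for %s: %s", pl.protein_id, exc)
            continue
        if not fm_out.credible_sets:
            continue
        tested.add(pl.protein_id)

        # closest-gene baseline from each pQTL credible set's lead variant
        lead_by_cs = {
            cs.cs_index: pl.protein_stats.variants[cs.lead_index]
            for cs in fm_out.credible_sets
        }
        for cs_idx, lead in lead_by_cs.items():
            for mode, key in (("gene_body", "closest_gene"), ("tss", "closest_gene_tss")):
                for gid in closest_genes(lead, pl.genes, mode=mode):
                    preds[key].append(Prediction(pl.protein_id, gid, "simulated", cs_idx))

        for gene in pl.genes:
            if not gene.protein_coding:
                continue
            if window_overlap_fraction(gene, pl.protein_stats) < config.min_window_overlap:
                continue
            gstats = pl.gene_stats[gene.gene_id]
            try:
                fm_exp = susie_rss(gstats, pl.locus.R, fmc)
                pair = harmonize_pair(gstats, pl.protein_stats)
                res_abf = coloc_abf(pair, priors=priors, pp4_threshold=config.pp4_threshold)
            except ColocbenchError as exc:
                logger.warning("pair (%s, %s) quarantined: %s", gene.gene_id, pl.protein_id, exc)
                continue
            trait_pair = (gene.gene_id, pl.protein_id)
            coloc_rows.append(
                {"gene": gene.gene_id, "protein": pl.protein_id, "method": "abf",
                 "signal_pair": None, "pp4": res_abf.pp4, "clpp": None,
                 "significant": res_abf.significant}
            )
            if res_abf.significant:
                preds["abf"].append(Prediction(pl.protein_id, gene.gene_id, "simulated", 1))

            bf_results = []
            for cs_e in fm_exp.credible_sets:
                lbf_e = fm_exp.lbf[cs_e.effect_row][pair.idx_a]
                if config.clpp_use_overall_pip:
                    alpha_e = fm_exp.pip[pair.idx_a]
                else:
                    alpha_e = fm_exp.alpha[cs_e.effect_row][pair.idx_a]
                for cs_o in fm_out.credible_sets:
                    lbf_o = fm_out.lbf[cs_o.effect_row][pair.idx_b]
                    if config.clpp_use_overall_pip:
                        alpha_o = fm_out.pip[pair.idx_b]
                    else:
                        alpha_o = fm_out.alpha[cs_o.effect_row][pair.idx_b]
                    sp = (cs_e.cs_index, cs_o.cs_index)
                    res_bf = coloc_bf_bf(lbf_e, lbf_o, priors, trait_pair, sp,
                                         pp4_threshold=config.pp4_threshold)
                    bf_results.append(res_bf)
                    res_clpp = clpp(alpha_e, alpha_o, cs_e, pair.variant_ids, trait_pair, sp,
                                    threshold=config.clpp_threshold)
                    coloc_rows.append(
                        {"gene": gene.gene_id, "protein": pl.protein_id, "method": "bf_bf",
                         "signal_pair": sp, "pp4": res_bf.pp4, "clpp": None,
                         "significant": res_bf.significant}
                    )
                    coloc_rows.append(
                        {"gene": gene.gene_id, "protein": pl.protein_id, "method": "clpp",
                         "signal_pair": sp, "pp4": None, "clpp": res_clpp.clpp_value,
                         "significant": res_clpp.significant}
                    )
                    if res_bf.significant:
                        preds["bf_bf"].append(
                            Prediction(pl.protein_id, gene.gene_id, "simulated", cs_o.cs_index)
                        )
                    if res_clpp.significant:
                        preds["clpp"].append(
                            Prediction(pl.protein_id, gene.gene_id, "simulated", cs_o.cs_index)
                        )

            mr_input = build_mr_input(bf_results, fm_exp, fm_out, pair)
            if mr_input is None:
                continue
            preds["multi_signal"].append(Prediction(pl.protein_id, gene.gene_id, "simulated"))
            is_tp = pl.coding_gene_id == gene.gene_id
            for mname in MR_METHODS:
                try:
                    est = METHODS[mname](mr_input)
                except ColocbenchError as exc:
                    logger.warning("MR %s failed for (%s, %s): %s",
                                   mname, gene.gene_id, pl.protein_id, exc)
                    continue
                mr_labeled[mname].append((est, is_tp))
                mr_rows.append(
                    {"gene": gene.gene_id, "protein": pl.protein_id, "method": mname,
                     "k": mr_input.k, "alpha_hat": est.alpha_hat, "lo": est.interval[0],
                     "hi": est.interval[1], "dispersion": est.dispersion,
                     "significant": est.significant, "is_tp": is_tp}
                )
                if est.significant:
                    preds[mname].append(Prediction(pl.protein_id, gene.gene_id, "simulated"))

    truth_map = TruthMap(
        coding_gene={p: g for p, g in catalog.coding_gene_map.items() if p in tested},
        tested_proteins=tested,
    )
    reports: dict[str, BenchmarkReport] = {}
    for key in ("closest_gene", "closest_gene_tss", "abf", "bf_bf", "clpp"):
        reports[key] = score_method(preds[key], truth_map, "first_signal_only", key)
    reports["multi_signal"] = score_method(preds["multi_signal"], truth_map, "all", "multi_signal")
    for mname in MR_METHODS:
        rep = score_method(preds[mname], truth_map, "all", mname)
        conc = sign_concordance(mr_labeled[mname])
        rep.tp_positive_slope = conc["tp"]
        rep.fp_positive_slope = conc["fp"]
        reports[mname] = rep
    return EndToEndResult(reports=reports, truth_map=truth_map,
                          coloc_rows=coloc_rows, mr_rows=mr_rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Simulate a catalog, run the full benchmark, and write artifacts.

    Writes per-trait summary statistics, LD matrices, annotations, truth
    labels, the per-pair colocalization table, the per-triplet MR table,
    and the benchmark report, plus a manifest with content hashes.
    Rerunning with the same config reproduces all outputs bit-identically.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = simulate_benchmark_catalog(
        n_proteins=config.n_proteins,
        genes_per_locus=config.genes_per_locus,
        pleiotropy_rate=config.pleiotropy_rate,
        multi_signal_rate=config.multi_signal_rate,
        config=config.locus,
        seed=int(stage_seed(config.seed, 0).generate_state(1)[0] % 2**31),
    )
    write_catalog(catalog, out / "catalog")
    result = run_end_to_end(catalog, config)

    import pandas as pd

    pd.DataFrame(result.coloc_rows).to_csv(out / "coloc.tsv", sep="\t", index=False)
    pd.DataFrame(result.mr_rows).to_csv(out / "mr.tsv", sep="\t", index=False)
    table = result.table()
    pd.DataFrame(table).to_csv(out / "report.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(table, fh, indent=2)

    manifest = {
        "seed": config.seed,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"reports": table, "manifest": manifest}


def write_catalog(catalog: SyntheticCatalog, outdir) -> None:
    """Write a catalog's summary statistics, LD, annotations, and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_genes = []
    truth = [
        {"protein": t.protein_id, "gene": t.gene_id, "signal": t.signal,
         "variant_index": t.variant_index, "true_bx": t.true_bx, "true_by": t.true_by}
        for t in catalog.truth
    ]
    for pl in catalog.loci:
        ldir = outdir / pl.protein_id
        ldir.mkdir(exist_ok=True)
        cio.write_sumstats(pl.protein_stats, ldir / "protein.tsv")
        cio.write_sumstats(list(pl.gene_stats.values()), ldir / "genes.tsv")
        cio.write_ld_matrix(pl.locus.R, [v.id for v in pl.locus.variants], ldir / "ld.tsv")
        all_genes.extend(pl.genes)
    cio.write_gene_annotations(all_genes, outdir / "annotations.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {"coding_gene": catalog.coding_gene_map, "sharing": truth,
             "complex_proteins": sorted(catalog.complex_proteins)},
            fh, indent=2,
        )
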