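"""Readers and writers for summary statistics, annotations, and matrices.

All tabular formats are plain TSV (gzip-transparent through pandas). The
default summary-statistics dialect matches eQTL Catalogue-style exports:
``variant chromosome position ref alt beta se maf an`` with ``an`` the
allele number (2n) and an optional ``molecular_trait_id`` column.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import FormatError, GeneAnnotation, RegionSummaryStats, Variant

logger = logging.getLogger(__name__)

#: canonical field -> default column name
DEFAULT_DIALECT: dict[str, str] = {
    "variant": "variant",
    "chrom": "chromosome",
    "pos": "position",
    "ref": "ref",
    "alt": "alt",
    "beta": "beta",
    "se": "se",
    "maf": "maf",
    "an": "an",
    "trait": "molecular_trait_id",
    "dataset": "dataset_id",
}

_REQUIRED = ("variant", "chrom", "pos", "ref", "alt", "beta", "se", "maf", "an")


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str = "trait",
    dataset_id: str = "dataset",
) -> dict[str, RegionSummaryStats]:
    """Read per-variant summary statistics, one object per distinct trait.

    Rows with missing beta/se or non-positive se are dropped and counted in
    a warning. Allele frequencies above 0.5 are folded to the minor allele.
    ``trait_id``/``dataset_id`` are fallbacks used when the file has no
    trait or dataset column.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype={colmap["chrom"]: str})
    for field in _REQUIRED:
        if colmap[field] not in df.columns:
            raise FormatError(f"missing required column {colmap[field]!r} in {path}")

    trait_col = colmap["trait"] if colmap["trait"] in df.columns else None
    dataset_col = colmap["dataset"] if colmap["dataset"] in df.columns else None

    beta = pd.to_numeric(df[colmap["beta"]], errors="coerce")
    se = pd.to_numeric(df[colmap["se"]], errors="coerce")
    bad = beta.isna() | se.isna() | (se <= 0)
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning("dropped %d rows with missing beta/se or non-positive se", n_rejected)
        df = df.loc[~bad.values]

    out: dict[str, RegionSummaryStats] = {}
    groups = df.groupby(trait_col, sort=False) if trait_col else [(trait_id, df)]
    for tid, sub in groups:
        maf = np.minimum(sub[colmap["maf"]].to_numpy(float), 1 - sub[colmap["maf"]].to_numpy(float))
        variants = [
            Variant(id=str(v), chrom=str(c), pos=int(p), ref=str(r), alt=str(a))
            for v, c, p, r, a in zip(
                sub[colmap["variant"]], sub[colmap["chrom"]], sub[colmap["pos"]],
                sub[colmap["ref"]], sub[colmap["alt"]],
            )
        ]
        n = int(round(sub[colmap["an"]].astype(float).mean() / 2))
        ds = str(sub[dataset_col].iloc[0]) if dataset_col else dataset_id
        out[str(tid)] = RegionSummaryStats(
            trait_id=str(tid),
            dataset_id=ds,
            variants=variants,
            beta=sub[colmap["beta"]].to_numpy(float),
            se=sub[colmap["se"]].to_numpy(float),
            maf=maf,
            n=n,
        )
    return out


def write_sumstats(stats: RegionSummaryStats | list[RegionSummaryStats], path) -> None:
    """Write one or more traits' summary statistics as a TSV."""
    if isinstance(stats, RegionSummaryStats):
        stats = [stats]
    frames = []
    for s in stats:
        frames.append(
            pd.DataFrame(
                {
                    "molecular_trait_id": s.trait_id,
                    "dataset_id": s.dataset_id,
                    "variant": s.variant_ids,
                    "chromosome": [v.chrom for v in s.variants],
                    "position": [v.pos for v in s.variants],
                    "ref": [v.ref for v in s.variants],
                    "alt": [v.alt for v in s.variants],
                    "beta": s.beta,
                    "se": s.se,
                    "maf": s.maf,
                    "an": 2 * s.n,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Read a gene annotation table (TSV) or a genes-only GFF3 file."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff-version") or first.count("\t") == 8:
        return _read_gff3_genes(path)
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    genes = []
    for row in df.itertuples(index=False):
        gene_type = getattr(row, "gene_type", "protein_coding")
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                protein_coding=(str(gene_type) == "protein_coding"),
            )
        )
    return genes


def _read_gff3_genes(path) -> list[GeneAnnotation]:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols, dtype={"seqid": str})
    df = df[df["type"] == "gene"]
    genes = []
    for row in df.itertuples(index=False):
        attrs = dict(
            item.split("=", 1) for item in str(row.attributes).split(";") if "=" in item
        )
        gene_id = attrs.get("gene_id") or attrs.get("ID", "").removeprefix("gene:")
        if not gene_id:
            raise FormatError("GFF3 gene record without gene_id/ID attribute")
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=str(row.seqid),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                protein_coding=(attrs.get("biotype", attrs.get("gene_biotype", "protein_coding")) == "protein_coding"),
            )
        )
    return genes


def write_gene_annotations(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chromosome": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "gene_type": ["protein_coding" if g.protein_coding else "other" for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_lbf_matrix(path) -> pd.DataFrame:
    """Read a per-signal log-Bayes-factor matrix (rows = signals)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_lbf_matrix(lbf: np.ndarray, variant_ids: list[str], path, row_prefix: str = "signal") -> None:
    pd.DataFrame(
        lbf, index=[f"{row_prefix}{i + 1}" for i in range(lbf.shape[0])], columns=variant_ids
    ).to_csv(path, sep="\t", float_format="%.17g")


def read_ld_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]


def write_ld_matrix(R: np.ndarray, variant_ids: list[str], path) -> None:
    pd.DataFrame(R, index=variant_ids, columns=variant_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )
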