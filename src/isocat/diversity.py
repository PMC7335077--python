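"""Isoform diversity statistics: Shannon index, Lorenz curves, treemap shares.

A gene's expression is distributed across its isoform portfolio; these
statistics quantify how evenly. The Shannon index H' = -sum p_i ln(p_i)
(natural log, nats) with p_i = n_i / N, where n_i is the full-length read
count of isoform i and N the gene's total reads, rises with both the number
of isoforms and the parity of their expression. The Lorenz ("jellyfish")
curve is the cumulative fraction of gene reads covered by isoforms ranked
from most to least abundant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GeneCatalog

__all__ = [
    "shannon_index",
    "lorenz_curve",
    "treemap_shares",
    "summary_stats",
    "diversity_report",
    "LorenzCurve",
    "TreemapShares",
]


def shannon_index(counts: Sequence[int]) -> float:
    """Shannon diversity H' = -sum p_i ln p_i (nats) of isoform read counts.

    Zero-count isoforms contribute nothing; an all-zero vector has undefined
    proportions and raises ValueError.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or np.any(arr < 0):
        raise ValueError("counts must be a non-empty vector of non-negative numbers")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero counts: proportions undefined")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class LorenzCurve:
    """Descending-abundance cumulative curve for one gene."""

    gene_id: str
    isoform_ids: list[str]
    percent_abundance: list[float]
    cumulative: list[float]


@dataclass
class TreemapShares:
    """Read-mass shares of genes within the dataset and isoforms nested within genes."""

    gene_shares: dict[str, float]
    isoform_shares: dict[str, dict[str, float]]


def lorenz_curve(catalog: GeneCatalog, gene_id: str) -> LorenzCurve:
    """Rank a gene's isoforms by percent abundance (descending, ties by id)
    and accumulate partial sums."""
    isoforms = catalog.genes.get(gene_id)
    if not isoforms:
        raise KeyError(f"unknown gene {gene_id!r}")
    total = sum(iso.total_reads for iso in isoforms)
    if total == 0:
        raise ValueError(f"gene {gene_id!r} has zero reads")
    ranked = sorted(isoforms, key=lambda i: (-i.total_reads, i.id))
    shares = [iso.total_reads / total for iso in ranked]
    return LorenzCurve(
        gene_id=gene_id,
        isoform_ids=[iso.id for iso in ranked],
        percent_abundance=shares,
        cumulative=list(np.cumsum(shares)),
    )


def treemap_shares(catalog: GeneCatalog) -> TreemapShares:
    """Gene and isoform shares of total dataset reads (rectangle areas)."""
    dataset_total = catalog.total_reads
    if dataset_total == 0:
        raise ValueError("dataset has zero reads")
    gene_shares: dict[str, float] = {}
    isoform_shares: dict[str, dict[str, float]] = {}
    for gene_id, isoforms in catalog.genes.items():
        gene_total = sum(iso.total_reads for iso in isoforms)
        gene_shares[gene_id] = gene_total / dataset_total
        isoform_shares[gene_id] = {
            iso.id: iso.total_reads / dataset_total for iso in isoforms
        }
    return TreemapShares(gene_shares=gene_shares, isoform_shares=isoform_shares)


def diversity_report(catalog: GeneCatalog) -> pd.DataFrame:
    """Per-gene table: isoform count, total reads N, Shannon H (nats).

    Genes with zero total reads get H = NaN rather than an error, so a
    whole-catalog report never fails on a silent gene.
    """
    rows = []
    for gene_id, isoforms in catalog.genes.items():
        counts = [iso.total_reads for iso in isoforms]
        n_total = int(sum(counts))
        h = shannon_index(counts) if n_total > 0 else float("nan")
        rows.append(
            {"gene_id": gene_id, "n_isoforms": len(isoforms), "N": n_total, "H": h}
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_isoforms", "N", "H"])


def summary_stats(catalog: GeneCatalog) -> pd.DataFrame:
    """Per-gene summary: isoform count, spliced-length quartiles, exon counts.

    Lengths are spliced cDNA lengths (sum of exon lengths); quartiles use
    linear interpolation between order statistics. ``exon_count_hist`` maps
    segment count -> number of isoforms.
    """
    from .curation import exon_count

    rows = []
    for gene_id, isoforms in catalog.genes.items():
        lengths = np.array([iso.spliced_length for iso in isoforms], dtype=float)
        ecounts = [exon_count(iso) for iso in isoforms]
        hist: dict[int, int] = {}
        for c in ecounts:
            hist[c] = hist.get(c, 0) + 1
        q = (
            np.percentile(lengths, [0, 25, 50, 75, 100], method="linear")
            if len(lengths)
            else [float("nan")] * 5
        )
        rows.append(
            {
                "gene_id": gene_id,
                "n_isoforms": len(isoforms),
                "length_min": q[0],
                "length_q1": q[1],
                "length_median": q[2],
                "length_q3": q[3],
                "length_max": q[4],
                "exon_count_hist": dict(sorted(hist.items())),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_isoforms",
            "length_min",
            "length_q1",
            "length_median",
            "length_q3",
            "length_max",
            "exon_count_hist",
        ],
    )
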