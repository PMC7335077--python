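"""Shared fixtures: toy genomes/catalogs and a random-structure generator.

``random_gene`` draws exon chains from a small shared boundary grid so that
boundary-subsequence relationships (and hence truncation-rule firings) are
common, which is what the brute-force oracle comparisons need to be
informative.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from isocat.model import GeneCatalog, Genome, GenomicInterval, Isoform

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_isoform(
    iso_id: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    gene_id: str = "geneA",
    reads: int = 10,
    chrom: str = "chr1",
) -> Isoform:
    return Isoform(
        id=iso_id,
        gene_id=gene_id,
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        read_counts={"s1": reads},
    )


def make_catalog(isoforms: list[Isoform]) -> GeneCatalog:
    catalog = GeneCatalog(genes={}, samples=["s1"])
    for iso in isoforms:
        catalog.genes.setdefault(iso.gene_id, []).append(iso)
    return catalog


def random_gene(
    rng: np.random.Generator,
    gene_id: str = "geneA",
    max_isoforms: int = 20,
    chrom: str = "chr1",
) -> list[Isoform]:
    """Random isoforms over a shared boundary grid (distinct splice chains)."""
    strand = "+" if rng.random() < 0.5 else "-"
    # grid of candidate boundaries, spaced >= 10 apart
    n_points = int(rng.integers(8, 16))
    grid = np.cumsum(rng.integers(10, 60, size=n_points))
    n_iso = int(rng.integers(1, max_isoforms + 1))
    isoforms: list[Isoform] = []
    seen: set[tuple[int, ...]] = set()
    attempts = 0
    while len(isoforms) < n_iso and attempts < 200:
        attempts += 1
        n_exons = int(rng.integers(1, max(2, n_points // 2)))
        picks = sorted(rng.choice(n_points, size=min(2 * n_exons, n_points), replace=False))
        if len(picks) % 2:
            picks = picks[:-1]
        if not picks:
            continue
        exons = [(int(grid[picks[i]]), int(grid[picks[i + 1]])) for i in range(0, len(picks), 2)]
        if any(s >= e for s, e in exons):
            continue
        key = tuple(b for se in exons for b in se)[1:-1]
        if key in seen:
            continue
        seen.add(key)
        isoforms.append(
            make_isoform(
                f"{gene_id}.i{len(isoforms) + 1}",
                exons,
                strand=strand,
                gene_id=gene_id,
                reads=int(rng.integers(1, 50)),
                chrom=chrom,
            )
        )
    return isoforms


@pytest.fixture
def toy_genome() -> Genome:
    return Genome(sequences={"chr1": "ACGTTTGCA"})


@pytest.fixture
def sim_study():
    from isocat.simdata import SimConfig, simulate_study

    return simulate_study(SimConfig(seed=7))
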