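"""Sequence-level isoform comparison.

k-mer vectorization of spliced cDNA (counts of all overlapping 6-mers,
normalized to sum to 1 so transcript length does not dominate), Euclidean
distances between vectors, complete-linkage agglomerative clustering, PCA /
t-SNE ordination, binary exon-call matrices with read-count weights,
weighted Pearson exon co-occurrence correlation, and per-gene splice
junction frequency tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import GeneCatalog, Genome, Isoform, extract_cdna, reverse_complement

__all__ = [
    "kmer_vector",
    "kmer_matrix",
    "kmer_distance_matrix",
    "hierarchical_cluster",
    "cut_tree",
    "reduce_dimensions",
    "exon_call_matrix",
    "weighted_pearson",
    "junction_frequencies",
    "KmerMatrix",
    "ClusterTree",
    "ExonCallMatrix",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_words(k: int) -> list[str]:
    """All 4^k words over {A,C,G,T} in lexicographic order."""
    return ["".join(w) for w in itertools.product("ACGT", repeat=k)]


def kmer_vector(sequence: str, k: int = 6) -> np.ndarray:
    """Normalized k-mer frequency vector (4^k entries, lexicographic order).

    All overlapping windows of the 5'->3' sequence are counted; windows
    containing letters outside {A,C,G,T} (e.g. N) are skipped. The count
    vector is divided by its sum.
    """
    seq = sequence.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    counts = np.zeros(4**k, dtype=float)
    modulus = 4**k
    index = 0
    run = 0  # length of the current run of unambiguous bases
    for ch in seq:
        code = _BASE_INDEX.get(ch)
        if code is None:
            run = 0
            index = 0
            continue
        index = (index * 4 + code) % modulus  # rolling code of the last k bases
        run += 1
        if run >= k:
            counts[index] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid k-mer windows (all skipped)")
    return counts / total


@dataclass
class KmerMatrix:
    """Per-isoform normalized k-mer frequency vectors."""

    k: int
    ids: list[str]
    values: np.ndarray  # shape (n_isoforms, 4**k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=kmer_words(self.k))


def kmer_matrix(
    isoforms: list[Isoform] | GeneCatalog, genome: Genome, k: int = 6
) -> KmerMatrix:
    """k-mer vectorize the spliced cDNA of every isoform."""
    iso_list = list(isoforms)
    rows = []
    for iso in iso_list:
        try:
            rows.append(kmer_vector(extract_cdna(iso, genome), k=k))
        except ValueError as exc:
            raise ValueError(f"isoform {iso.id}: {exc}") from exc
    return KmerMatrix(k=k, ids=[iso.id for iso in iso_list], values=np.vstack(rows))


def kmer_distance_matrix(
    isoforms: list[Isoform] | GeneCatalog, genome: Genome, k: int = 6
) -> pd.DataFrame:
    """Pairwise Euclidean distances between normalized k-mer vectors."""
    km = kmer_matrix(isoforms, genome, k=k)
    diff = km.values[:, None, :] - km.values[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(dist, index=km.ids, columns=km.ids)


@dataclass
class ClusterTree:
    """Agglomerative clustering result over isoform ids."""

    ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (n-1, 4)
    method: str


def hierarchical_cluster(distances: pd.DataFrame, method: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a symmetric distance matrix.

    Complete linkage merges at the maximum pairwise distance between
    clusters; ties resolve deterministically (scipy merges the
    lowest-index pair first).
    """
    values = np.asarray(distances, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(values < 0):
        raise ValueError("negative distances")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    ids = list(distances.index) if isinstance(distances, pd.DataFrame) else [
        str(i) for i in range(values.shape[0])
    ]
    condensed = squareform(values, checks=False)
    z = linkage(condensed, method=method)
    return ClusterTree(ids=ids, linkage=z, method=method)


def cut_tree(tree: ClusterTree, n_clusters: int) -> dict[str, int]:
    """Flat cluster labels (1..n_clusters) from a ClusterTree."""
    labels = fcluster(tree.linkage, t=n_clusters, criterion="maxclust")
    return dict(zip(tree.ids, (int(x) for x in labels)))


def reduce_dimensions(
    matrix: KmerMatrix,
    method: str = "pca",
    n_components: int = 3,
    perplexity: float = 35.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Ordination coordinates of the k-mer matrix.

    PCA is exact (deterministic up to sign); t-SNE runs the exact (theta=0)
    algorithm with an explicit seed and requires perplexity < n rows.
    """
    n = matrix.values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    n_components = min(n_components, matrix.values.shape[1])
    if n_components > n:
        raise ValueError(f"cannot extract {n_components} components from {n} rows")
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=n_components, svd_solver="full").fit_transform(matrix.values)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        if perplexity >= n:
            raise ValueError(f"perplexity {perplexity} must be < n rows ({n})")
        coords = TSNE(
            n_components=n_components,
            perplexity=perplexity,
            method="exact",
            max_iter=max_iter,
            init="pca",
            random_state=seed,
        ).fit_transform(matrix.values)
    else:
        raise ValueError(f"unknown method {method!r}")
    cols = [f"{method}{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.ids, columns=cols)


@dataclass
class ExonCallMatrix:
    """Binary isoform x reference-exon usage matrix with read-count weights.

    A call is 1 when the exon's first-30bp or last-30bp probe (oriented
    5'->3' on the transcript strand) occurs verbatim in the isoform's cDNA.
    """

    isoform_ids: list[str]
    exon_ids: list[str]
    calls: np.ndarray  # (n_isoforms, n_exons) of {0,1}
    weights: np.ndarray  # (n_isoforms,) read counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.isoform_ids, columns=self.exon_ids)


def _reference_exons(isoforms: list[Isoform]) -> list:
    """Default reference exon set: exons of the gene's longest isoform
    (spliced length, ties by id), in transcription order."""
    rep = max(isoforms, key=lambda i: (i.spliced_length, i.id))
    exons = list(rep.exons)
    return exons if rep.strand == "+" else exons[::-1]


def exon_call_matrix(
    isoforms: list[Isoform],
    genome: Genome,
    reference_exons: list | None = None,
    probe_length: int = 30,
) -> ExonCallMatrix:
    """Call reference-exon usage in each isoform by exact probe matching.

    Probes are the first and last ``probe_length`` bases of each reference
    exon's transcript-oriented sequence (whole exon when shorter); a call is
    1 when either probe is an exact substring of the isoform cDNA.
    """
    if not isoforms:
        raise ValueError("no isoforms")
    strand = isoforms[0].strand
    ref = reference_exons if reference_exons is not None else _reference_exons(isoforms)
    if not ref:
        raise ValueError("empty reference exon set")
    probes: list[tuple[str, str, str]] = []
    for i, exon in enumerate(ref):
        seq = genome.fetch(exon.chrom, exon.start, exon.end)
        if strand == "-":
            seq = reverse_complement(seq)
        probes.append((f"exon_{i + 1}", seq[:probe_length], seq[-probe_length:]))
    calls = np.zeros((len(isoforms), len(probes)), dtype=int)
    for r, iso in enumerate(isoforms):
        cdna = extract_cdna(iso, genome)
        for c, (_, head, tail) in enumerate(probes):
            if head in cdna or tail in cdna:
                calls[r, c] = 1
    return ExonCallMatrix(
        isoform_ids=[iso.id for iso in isoforms],
        exon_ids=[p[0] for p in probes],
        calls=calls,
        weights=np.array([iso.total_reads for iso in isoforms], dtype=float),
    )


def weighted_pearson(matrix: ExonCallMatrix) -> pd.DataFrame:
    """Weighted Pearson correlation between exon-call columns.

    r(x, y) = sum w (x - xw)(y - yw) / sqrt(sum w (x - xw)^2 * sum w (y - yw)^2)
    with weighted means xw, yw. With integer weights this equals ordinary
    Pearson on the weight-expanded matrix. Zero-variance (constitutive)
    columns yield NaN entries rather than fabricated values.
    """
    w = matrix.weights
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    x = matrix.calls.astype(float)
    means = (w[:, None] * x).sum(axis=0) / w.sum()
    centered = x - means
    cov = (w[:, None, None] * centered[:, :, None] * centered[:, None, :]).sum(axis=0)
    var = np.diag(cov).copy()
    denom = np.sqrt(var[:, None] * var[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.DataFrame(r, index=matrix.exon_ids, columns=matrix.exon_ids)


def junction_frequencies(isoforms: list[Isoform]) -> pd.DataFrame:
    """Per-junction read tallies for one gene (sashimi-style table).

    Each distinct (donor, acceptor) intron's count is the summed reads of
    the isoforms containing it; ``fraction`` is count / gene total reads.
    Rows are ordered by genomic coordinates.
    """
    gene_total = sum(iso.total_reads for iso in isoforms)
    if gene_total <= 0:
        raise ValueError("gene has zero reads")
    tallies: dict[tuple[int, int], int] = {}
    for iso in isoforms:
        for j in iso.junctions:
            tallies[j] = tallies.get(j, 0) + iso.total_reads
    rows = [
        {
            "donor": donor,
            "acceptor": acceptor,
            "count": count,
            "fraction": count / gene_total,
        }
        for (donor, acceptor), count in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["donor", "acceptor", "count", "fraction"])
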