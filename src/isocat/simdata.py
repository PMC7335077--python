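"""Seeded synthetic data: genomes, modularly spliced gene models, artifacts.

The generator emulates the structure of capture-based long-read isoform
catalogs of large multi-exon genes: each gene has constitutive first and
last exons flanking a run of cassette exons that are included independently
per isoform (modular splicing), read counts follow a Zipf law (a few
dominant isoforms, a long tail), intron flanks carry canonical GT-AG
dinucleotides, and two artifact classes can be injected with ground-truth
labels:

* truncation artifacts — 5' exon loss from a parent isoform, either starting
  exactly at a parent exon boundary (detectable by boundary Rule 1) or at a
  point inside a retained parent exon (detectable by Rule 2);
* mono-exon artifacts — single-exon records at random intronic/downstream
  positions, modeling poly-A mispriming on genomic DNA.

Every draw derives from ``SimConfig.seed`` through per-gene child seeds, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GeneCatalog, Genome, GenomicInterval, Isoform

__all__ = ["SimConfig", "SimTruth", "simulate_catalog", "inject_artifacts", "simulate_study"]

_SAMPLE = "sim"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic catalog generator."""

    seed: int = 0
    n_genes: int = 5
    exons_per_gene: tuple[int, int] = (8, 12)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 1000)
    inclusion_prob: tuple[float, float] = (0.35, 0.9)
    n_isoforms_per_gene: tuple[int, int] = (6, 14)
    zipf_exponent: float = 1.5
    read_floor: int = 2
    truncation_rate: float = 0.25
    monoexon_rate: float = 0.1
    gc_fraction: float = 0.45
    flank: int = 500

    def __post_init__(self) -> None:
        for lo, hi in (
            self.exons_per_gene,
            self.exon_length,
            self.intron_length,
            self.n_isoforms_per_gene,
        ):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and positive")
        lo, hi = self.inclusion_prob
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("inclusion_prob range must lie in [0, 1]")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need at least 3 exons (two constitutive + cassettes)")


@dataclass
class SimTruth:
    """Ground-truth labels for every generated record.

    ``labels``: id -> true_isoform | truncation_artifact | monoexon_artifact;
    ``parents``: artifact id -> parent true-isoform id (monoexon: None);
    ``rules``: truncation artifact id -> "rule1" | "rule2".
    """

    labels: dict[str, str] = field(default_factory=dict)
    parents: dict[str, str | None] = field(default_factory=dict)
    rules: dict[str, str] = field(default_factory=dict)

    @property
    def artifact_ids(self) -> set[str]:
        return {i for i, lab in self.labels.items() if lab != "true_isoform"}

    @property
    def true_ids(self) -> set[str]:
        return {i for i, lab in self.labels.items() if lab == "true_isoform"}


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def simulate_catalog(config: SimConfig) -> tuple[Genome, GeneCatalog, SimTruth]:
    """Generate a random genome and a multi-gene true-isoform catalog.

    Each gene gets its own chromosome: random sequence at the configured GC
    fraction, a backbone exon chain with constitutive terminal exons, and
    cassette exons included independently per isoform. Splice chains are
    rejection-sampled to uniqueness; requesting more unique isoforms than
    2^n_cassettes supports raises ValueError. Intron flanks are overwritten
    with canonical GT-AG dinucleotides in transcription orientation. Read
    counts follow rank^(-zipf_exponent), scaled so the rarest isoform keeps
    ``read_floor`` reads.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_genes)
    genome = Genome()
    catalog = GeneCatalog(genes={}, samples=[_SAMPLE])
    truth = SimTruth()

    for g in range(config.n_genes):
        rng = np.random.default_rng(children[g])
        gene_id = f"gene{g + 1}"
        chrom = f"chr{g + 1}"
        strand = "+" if rng.random() < 0.5 else "-"

        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_exons)
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=n_exons - 1
        )
        exons: list[tuple[int, int]] = []
        pos = config.flank
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        chrom_len = pos + config.flank + 2000  # room for downstream mono-exon artifacts
        seq = _random_sequence(rng, chrom_len, config.gc_fraction)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if strand == "+":
                seq[e0 : e0 + 2] = [b"G", b"T"]
                seq[s1 - 2 : s1] = [b"A", b"G"]
            else:
                seq[e0 : e0 + 2] = [b"C", b"T"]
                seq[s1 - 2 : s1] = [b"A", b"C"]
        genome.sequences[chrom] = seq.tobytes().decode()

        n_cassettes = n_exons - 2
        n_iso = int(rng.integers(config.n_isoforms_per_gene[0], config.n_isoforms_per_gene[1] + 1))
        if n_iso > 2**n_cassettes:
            raise ValueError(
                f"{gene_id}: {n_iso} unique isoforms requested but only "
                f"2^{n_cassettes} cassette combinations exist"
            )
        probs = rng.uniform(config.inclusion_prob[0], config.inclusion_prob[1], size=n_cassettes)
        chains: list[tuple[int, ...]] = []
        seen: set[tuple[int, ...]] = set()
        while len(chains) < n_iso:
            included = tuple(i for i in range(n_cassettes) if rng.random() < probs[i])
            if included in seen:
                continue
            seen.add(included)
            chains.append(included)

        weights = np.arange(1, n_iso + 1, dtype=float) ** (-config.zipf_exponent)
        counts = np.floor(config.read_floor * weights / weights[-1]).astype(int)
        counts = np.maximum(counts, config.read_floor)

        isoforms = []
        for i, included in enumerate(chains):
            exon_idx = [0] + [1 + c for c in included] + [n_exons - 1]
            iso = Isoform(
                id=f"{gene_id}.iso{i + 1}",
                gene_id=gene_id,
                strand=strand,
                exons=[
                    GenomicInterval(chrom, exons[j][0], exons[j][1], strand) for j in exon_idx
                ],
                read_counts={_SAMPLE: int(counts[i])},
            )
            isoforms.append(iso)
            truth.labels[iso.id] = "true_isoform"
        catalog.genes[gene_id] = isoforms

    problems = catalog.validate()
    if problems:  # pragma: no cover - generator bug guard
        raise AssertionError(f"generated catalog violates invariants: {problems}")
    return genome, catalog, truth


def inject_artifacts(
    catalog: GeneCatalog, truth: SimTruth, config: SimConfig
) -> tuple[GeneCatalog, SimTruth]:
    """Add truncation and mono-exon mispriming artifacts with ground truth.

    Truncation artifacts are built constructively so the recorded rule
    provably applies: Rule-1 artifacts start exactly at a 5'-ward parent
    exon boundary (their boundary list is a contiguous suffix of the
    parent's); Rule-2 artifacts additionally move the TSS to a point
    strictly inside their first retained exon. Mono-exon artifacts are
    placed inside introns or downstream of the gene, away from any exon
    boundary, with 1-2 reads. Zero rates are a valid no-op.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 0xA27)))
    out = GeneCatalog(genes={}, samples=list(catalog.samples))
    new_truth = SimTruth(
        labels=dict(truth.labels), parents=dict(truth.parents), rules=dict(truth.rules)
    )
    for gene_id, isoforms in catalog.genes.items():
        augmented = list(isoforms)
        strand = isoforms[0].strand
        chrom = isoforms[0].chrom
        existing_chains = {tuple(iso.splice_boundaries) for iso in isoforms}

        candidates = [iso for iso in isoforms if len(iso.exons) >= 3]
        n_trunc = int(rng.binomial(len(isoforms), config.truncation_rate)) if candidates else 0
        for t in range(n_trunc):
            parent = candidates[int(rng.integers(len(candidates)))]
            rule = "rule1" if rng.random() < 0.5 else "rule2"
            # transcription-ordered exons
            tx_exons = parent.exons if strand == "+" else parent.exons[::-1]
            j = int(rng.integers(1, len(tx_exons) - 1))  # drop j 5' exons, keep >= 2
            kept = tx_exons[j:]
            if rule == "rule2":
                first = kept[0]
                delta = int(rng.integers(1, len(first) - 1))
                if strand == "+":
                    first = GenomicInterval(chrom, first.start + delta, first.end, strand)
                else:
                    first = GenomicInterval(chrom, first.start, first.end - delta, strand)
                kept = [first] + list(kept[1:])
            art = Isoform(
                id=f"{gene_id}.trunc{t + 1}",
                gene_id=gene_id,
                strand=strand,
                exons=sorted(kept, key=lambda e: e.start),
                read_counts={_SAMPLE: int(rng.integers(2, 5))},
            )
            chain = tuple(art.splice_boundaries)
            if chain in existing_chains:  # would collapse into a true isoform; skip slot
                continue
            existing_chains.add(chain)
            augmented.append(art)
            new_truth.labels[art.id] = "truncation_artifact"
            new_truth.parents[art.id] = parent.id
            new_truth.rules[art.id] = rule

        n_mono = int(rng.binomial(len(isoforms), config.monoexon_rate))
        gene_start = min(iso.exons[0].start for iso in isoforms)
        gene_end = max(iso.exons[-1].end for iso in isoforms)
        boundaries = {b for iso in isoforms for b in iso.boundary_list}
        for m in range(n_mono):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            for _ in range(50):  # rejection: avoid exon-boundary coincidence
                start = int(rng.integers(gene_start, gene_end + 1500))
                end = start + length
                if start not in boundaries and end not in boundaries:
                    break
            art = Isoform(
                id=f"{gene_id}.mono{m + 1}",
                gene_id=gene_id,
                strand=strand,
                exons=[GenomicInterval(chrom, start, end, strand)],
                read_counts={_SAMPLE: int(rng.integers(1, 3))},
            )
            augmented.append(art)
            new_truth.labels[art.id] = "monoexon_artifact"
            new_truth.parents[art.id] = None
        out.genes[gene_id] = augmented
    return out, new_truth


def simulate_study(config: SimConfig) -> tuple[Genome, GeneCatalog, SimTruth]:
    """Convenience wrapper: simulate a catalog and inject artifacts."""
    genome, catalog, truth = simulate_catalog(config)
    catalog, truth = inject_artifacts(catalog, truth, config)
    return genome, catalog, truth
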