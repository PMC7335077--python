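"""Core domain types for isoform catalogs.

All coordinates are 0-based half-open on the genomic forward strand,
regardless of transcript strand. Exons within an isoform are stored in
ascending genomic order; 5'/3' semantics (TSS, TTS, first exon) are derived
from the strand at access time. GFF/GTF I/O converts to and from the 1-based
inclusive convention at the boundary (see :mod:`isocat.catalog_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "GenomicInterval",
    "Isoform",
    "GeneCatalog",
    "Genome",
    "extract_cdna",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N} (case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative coordinate in {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains_point(self, pos: int, strict: bool = False) -> bool:
        """Whether a coordinate lies in the interval.

        ``strict`` uses open-interval containment (start < pos < end) on the
        raw coordinate value; the default is inclusive of both edge
        coordinates (start <= pos <= end), which is the tolerant reading used
        for transcript-terminus containment checks.
        """
        if strict:
            return self.start < pos < self.end
        return self.start <= pos <= self.end


@dataclass
class Isoform:
    """A full-length transcript model: an exon chain with read counts.

    ``read_counts`` maps sample label -> non-negative full-length read count.
    ``exons`` are ascending, pairwise disjoint, and share chrom/strand.
    """

    id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    read_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"isoform {self.id}: no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"isoform {self.id}: exons on multiple chromosomes {sorted(chroms)}")
        if any(e.strand != self.strand for e in self.exons):
            raise ValueError(f"isoform {self.id}: exon strand differs from transcript strand")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"isoform {self.id}: overlapping exons {a} / {b}")
        for label, n in self.read_counts.items():
            if n < 0:
                raise ValueError(f"isoform {self.id}: negative read count for sample {label!r}")

    # -- derived accessors (pure functions of the fields) ------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def total_reads(self) -> int:
        return sum(self.read_counts.values())

    @property
    def boundary_list(self) -> list[int]:
        """All 2m exon boundary coordinates, ascending, termini included."""
        out: list[int] = []
        for e in self.exons:
            out.append(e.start)
            out.append(e.end)
        return out

    @property
    def splice_boundaries(self) -> list[int]:
        """Internal (donor/acceptor) boundaries: boundary_list minus the termini."""
        return self.boundary_list[1:-1]

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Intron spans as (donor exon end, acceptor exon start) pairs, genomic order."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate (5' terminus)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tts(self) -> int:
        """Strand-aware transcription termination coordinate (3' terminus)."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def first_exon(self) -> GenomicInterval:
        """The 5'-most exon in transcription order."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def span(self) -> int:
        """Genomic footprint length, first exon start to last exon end."""
        return self.exons[-1].end - self.exons[0].start

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneCatalog:
    """Per-gene collections of isoforms; the unit all filters operate on."""

    genes: dict[str, list[Isoform]] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        seen: dict[str, str] = {}
        for gene_id, isoforms in self.genes.items():
            for iso in isoforms:
                if iso.gene_id != gene_id:
                    problems.append(f"isoform {iso.id}: gene_id {iso.gene_id!r} under key {gene_id!r}")
                if iso.id in seen:
                    problems.append(f"duplicate isoform id {iso.id}")
                seen[iso.id] = gene_id
                for label in iso.read_counts:
                    if label not in self.samples:
                        problems.append(f"isoform {iso.id}: unknown sample {label!r}")
        return problems

    def __iter__(self) -> Iterator[Isoform]:
        for isoforms in self.genes.values():
            yield from isoforms

    @property
    def n_isoforms(self) -> int:
        return sum(len(v) for v in self.genes.values())

    @property
    def total_reads(self) -> int:
        return sum(iso.total_reads for iso in self)

    def isoform(self, isoform_id: str) -> Isoform:
        for iso in self:
            if iso.id == isoform_id:
                return iso
        raise KeyError(isoform_id)


@dataclass
class Genome:
    """In-memory genome: chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    sequences: dict[str, str] = field(default_factory=dict)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(f"interval {chrom}:{start}-{end} out of bounds (length {len(seq)})")
        return seq[start:end]


def extract_cdna(isoform: Isoform, genome: Genome) -> str:
    """Spliced cDNA sequence of an isoform, read 5'->3'.

    Exon substrings are concatenated in genomic order and the whole string
    reverse-complemented for minus-strand transcripts, so the result always
    starts at the TSS.
    """
    parts = [genome.fetch(e.chrom, e.start, e.end) for e in isoform.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if isoform.strand == "-" else seq
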