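"""Splice-junction classification and external-evidence support scoring.

Catalog introns are classified canonical when their transcription-oriented
terminal dinucleotides are GT-AG, GC-AG, or AT-AC (donor..acceptor);
everything else is noncanonical. Junction support is scored from a
short-read splice-junction table (STAR ``SJ.out.tab`` dialect or a simple
5-column TSV), and transcription-start support from a BED file of 5'
coverage intervals overlapping each isoform's first exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import GeneCatalog, Genome, Isoform, reverse_complement

__all__ = [
    "JunctionRecord",
    "IsoformSupport",
    "extract_and_classify_junctions",
    "junction_support",
    "tss_support",
]

CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}


@dataclass
class JunctionRecord:
    """One distinct intron of the catalog, with flanking dinucleotides.

    ``donor``/``acceptor`` are the genomic half-open intron span boundaries
    (intron = [donor, acceptor)); dinucleotides are reported in
    transcription orientation.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str
    donor_dinuc: str
    acceptor_dinuc: str
    junction_class: str  # "canonical" | "noncanonical"
    support_count: int = 0


@dataclass
class IsoformSupport:
    isoform_id: str
    n_junctions: int
    n_supported: int
    tss_supported: bool = False

    @property
    def complete(self) -> bool:
        return self.n_supported == self.n_junctions


def classify_intron(genome: Genome, chrom: str, start: int, end: int, strand: str) -> JunctionRecord:
    """Classify one intron [start, end) from its first/last two bases."""
    if end - start < 4:
        raise ValueError(f"intron {chrom}:{start}-{end} shorter than 4 bases")
    left = genome.fetch(chrom, start, start + 2)
    right = genome.fetch(chrom, end - 2, end)
    if strand == "+":
        donor_dinuc, acceptor_dinuc = left, right
    else:
        donor_dinuc = reverse_complement(right)
        acceptor_dinuc = reverse_complement(left)
    cls = "canonical" if (donor_dinuc, acceptor_dinuc) in CANONICAL_PAIRS else "noncanonical"
    return JunctionRecord(
        chrom=chrom,
        donor=start,
        acceptor=end,
        strand=strand,
        donor_dinuc=donor_dinuc,
        acceptor_dinuc=acceptor_dinuc,
        junction_class=cls,
    )


def extract_and_classify_junctions(catalog: GeneCatalog, genome: Genome) -> list[JunctionRecord]:
    """All distinct catalog introns with canonical/noncanonical classes.

    Distinctness is per (chrom, start, end, strand); records are returned in
    coordinate order.
    """
    seen: dict[tuple[str, int, int, str], JunctionRecord] = {}
    for iso in catalog:
        for start, end in iso.junctions:
            key = (iso.chrom, start, end, iso.strand)
            if key not in seen:
                seen[key] = classify_intron(genome, iso.chrom, start, end, iso.strand)
    return [seen[k] for k in sorted(seen)]


def _read_evidence(path: str | Path) -> pd.DataFrame:
    """Parse a splice-junction evidence table.

    Accepted dialects (tab-separated, no header required):

    * STAR ``SJ.out.tab``: chrom, first intron base (1-based), last intron
      base (1-based), strand code (0 undefined / 1 '+' / 2 '-'), motif,
      annotated, unique reads, multimapped reads, overhang — unique reads
      are used as the support count.
    * simple: chrom, intron start (1-based), intron end (1-based), strand
      (+/-/0), count.

    Returns columns chrom, start, end (0-based half-open), strand, count.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not _looks_numeric(fields[1:3]):
                continue  # header line
            if len(fields) < 5:
                raise ValueError(f"evidence line {lineno}: expected >= 5 columns")
            try:
                chrom = fields[0]
                start_1 = int(fields[1])
                end_1 = int(fields[2])
                strand_field = fields[3]
                if len(fields) >= 9:  # STAR SJ.out.tab
                    strand = {"0": ".", "1": "+", "2": "-"}[strand_field]
                    count = int(fields[6])
                else:
                    strand = {"0": ".", "+": "+", "-": "-", ".": "."}[strand_field]
                    count = int(fields[4])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"evidence line {lineno}: malformed row ({exc})") from exc
            rows.append(
                {"chrom": chrom, "start": start_1 - 1, "end": end_1, "strand": strand, "count": count}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])


def _looks_numeric(fields: list[str]) -> bool:
    try:
        for f in fields:
            int(f)
        return True
    except ValueError:
        return False


def junction_support(
    catalog: GeneCatalog,
    genome: Genome,
    evidence_path: str | Path,
    min_reads: int = 1,
) -> tuple[list[JunctionRecord], list[IsoformSupport]]:
    """Annotate catalog junctions with external read support.

    A junction is supported when an evidence row matches its intron span and
    strand (unstranded rows match either strand) with count >= min_reads.
    Per-isoform support aggregates over the isoform's junction list;
    ``complete`` means every junction is supported.
    """
    junctions = extract_and_classify_junctions(catalog, genome)
    evidence = _read_evidence(evidence_path)
    support: dict[tuple[str, int, int], dict[str, int]] = {}
    for row in evidence.itertuples(index=False):
        key = (row.chrom, row.start, row.end)
        per_strand = support.setdefault(key, {})
        if row.strand == ".":
            per_strand["+"] = per_strand.get("+", 0) + row.count
            per_strand["-"] = per_strand.get("-", 0) + row.count
        else:
            per_strand[row.strand] = per_strand.get(row.strand, 0) + row.count

    supported: set[tuple[str, int, int, str]] = set()
    for rec in junctions:
        rec.support_count = support.get((rec.chrom, rec.donor, rec.acceptor), {}).get(rec.strand, 0)
        if rec.support_count >= min_reads:
            supported.add((rec.chrom, rec.donor, rec.acceptor, rec.strand))

    per_isoform = []
    for iso in catalog:
        keys = [(iso.chrom, s, e, iso.strand) for s, e in iso.junctions]
        per_isoform.append(
            IsoformSupport(
                isoform_id=iso.id,
                n_junctions=len(keys),
                n_supported=sum(1 for k in keys if k in supported),
            )
        )
    return junctions, per_isoform


def tss_support(
    catalog: GeneCatalog, coverage_path: str | Path, window: int = 0
) -> dict[str, bool]:
    """Per-isoform flag: does any 5'-coverage BED interval overlap exon 1?

    ``window`` optionally widens the first exon by +/- that many bases
    before the overlap test (0 = plain exon-1 overlap).
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(coverage_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: expected >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: malformed coordinates") from exc
            intervals.setdefault(chrom, []).append((start, end))

    flags: dict[str, bool] = {}
    for iso in catalog:
        exon1 = iso.first_exon
        lo, hi = exon1.start - window, exon1.end + window
        flags[iso.id] = any(
            s < hi and lo < e for s, e in intervals.get(iso.chrom, [])
        )
    return flags
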