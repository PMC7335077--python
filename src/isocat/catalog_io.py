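"""Catalog, abundance and genome I/O.

Reads transcript-grouped exon records from GFF3 or GTF (attribute dialects
``gene_id``/``transcript_id`` or ``ID``/``Parent``), paired with a per-isoform
full-length read-count TSV. File coordinates are 1-based inclusive and are
converted to the internal 0-based half-open convention on the way in.

The abundance TSV is accepted in two shapes:

* long: columns ``transcript_id, sample, count``
* wide: a ``transcript_id`` column plus one column per sample
  (a bare ``transcript_id, count`` file is a wide table with one sample)

``write_catalog`` emits GFF3 plus a wide abundance table, and
``read_catalog(write_catalog(c))`` reproduces ``c`` exactly.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import GeneCatalog, Genome, GenomicInterval, Isoform, extract_cdna

__all__ = [
    "read_catalog",
    "write_catalog",
    "read_genome",
    "write_genome",
    "extract_cdna",
]


class CatalogFormatError(ValueError):
    """Malformed catalog or abundance input."""


def _parse_feature(line: str, lineno: int):
    try:
        return feature_from_line(line)
    except Exception as exc:  # gffutils raises a mix of exception types
        raise CatalogFormatError(f"line {lineno}: cannot parse feature ({exc})") from exc


def _attr(feature, *names: str) -> str | None:
    for name in names:
        vals = feature.attributes.get(name)
        if vals:
            return vals[0]
    return None


def read_catalog(gff_path: str | Path, abundance_path: str | Path | None = None) -> GeneCatalog:
    """Load a GeneCatalog from a GFF3/GTF file and an optional abundance TSV.

    Transcripts absent from the abundance table get count 0 in every sample.
    Raises :class:`CatalogFormatError` on malformed lines (with line number),
    duplicate transcript ids, or transcripts whose exons disagree on
    chromosome or strand.
    """
    transcript_gene: dict[str, str] = {}
    transcript_declared: set[str] = set()
    exons: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []

    with open(gff_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 7:
                raise CatalogFormatError(f"line {lineno}: expected 9 tab-separated fields")
            feature = _parse_feature(line, lineno)
            ftype = feature.featuretype.lower()
            if ftype in ("transcript", "mrna"):
                tid = _attr(feature, "transcript_id", "ID")
                if tid is None:
                    raise CatalogFormatError(f"line {lineno}: transcript record without id")
                if tid in transcript_declared:
                    raise CatalogFormatError(f"line {lineno}: duplicate transcript id {tid!r}")
                transcript_declared.add(tid)
                gid = _attr(feature, "gene_id", "Parent")
                if gid is not None:
                    transcript_gene[tid] = gid
                if tid not in exons:
                    exons[tid] = []
                    order.append(tid)
            elif ftype == "exon":
                tid = _attr(feature, "transcript_id", "Parent")
                if tid is None:
                    raise CatalogFormatError(f"line {lineno}: exon record without transcript id")
                gid = _attr(feature, "gene_id")
                if gid is not None:
                    transcript_gene.setdefault(tid, gid)
                if feature.start is None or feature.end is None:
                    raise CatalogFormatError(f"line {lineno}: exon record without coordinates")
                if tid not in exons:
                    exons[tid] = []
                    order.append(tid)
                # GFF 1-based inclusive -> 0-based half-open
                exons[tid].append((feature.seqid, feature.start - 1, feature.end, feature.strand))

    counts, samples = _read_abundance(abundance_path)

    catalog = GeneCatalog(genes={}, samples=samples)
    for tid in order:
        recs = exons[tid]
        if not recs:
            raise CatalogFormatError(f"transcript {tid!r} has no exon records")
        gid = transcript_gene.get(tid)
        if gid is None:
            raise CatalogFormatError(f"transcript {tid!r} has no gene id")
        if len({r[0] for r in recs}) > 1:
            raise CatalogFormatError(f"transcript {tid!r}: exons on multiple chromosomes")
        if len({r[3] for r in recs}) > 1:
            raise CatalogFormatError(f"transcript {tid!r}: exons on multiple strands")
        strand = recs[0][3]
        if strand not in ("+", "-"):
            raise CatalogFormatError(f"transcript {tid!r}: missing or invalid strand {strand!r}")
        iso = Isoform(
            id=tid,
            gene_id=gid,
            strand=strand,
            exons=[GenomicInterval(c, s, e, strand) for c, s, e, _ in recs],
            read_counts={label: counts.get(tid, {}).get(label, 0) for label in samples},
        )
        catalog.genes.setdefault(gid, []).append(iso)
    return catalog


def _read_abundance(path: str | Path | None) -> tuple[dict[str, dict[str, int]], list[str]]:
    if path is None:
        return {}, []
    try:
        table = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    except Exception as exc:
        raise CatalogFormatError(f"cannot read abundance table {path}: {exc}") from exc
    if "transcript_id" not in table.columns:
        raise CatalogFormatError("abundance table lacks a 'transcript_id' column")
    counts: dict[str, dict[str, int]] = {}
    if set(table.columns) == {"transcript_id", "sample", "count"}:
        samples: list[str] = []
        for row in table.itertuples(index=False):
            label = str(row.sample)
            if label not in samples:
                samples.append(label)
            counts.setdefault(row.transcript_id, {})[label] = _as_count(row.count)
        return counts, samples
    samples = [c for c in table.columns if c != "transcript_id"]
    for _, row in table.iterrows():
        counts[row["transcript_id"]] = {label: _as_count(row[label]) for label in samples}
    return counts, samples


def _as_count(value) -> int:
    n = int(value)
    if n != float(value) or n < 0:
        raise CatalogFormatError(f"invalid read count {value!r}")
    return n


def write_catalog(catalog: GeneCatalog, gff_path: str | Path, abundance_path: str | Path) -> None:
    """Serialize a catalog to GFF3 + wide abundance TSV (round-trip exact)."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for gene_id, isoforms in catalog.genes.items():
        for iso in isoforms:
            start = iso.exons[0].start + 1
            end = iso.exons[-1].end
            buf.write(
                f"{iso.chrom}\tisocat\ttranscript\t{start}\t{end}\t.\t{iso.strand}\t.\t"
                f"ID={iso.id};Parent={gene_id}\n"
            )
            for e in iso.exons:
                buf.write(
                    f"{e.chrom}\tisocat\texon\t{e.start + 1}\t{e.end}\t.\t{iso.strand}\t.\t"
                    f"Parent={iso.id};gene_id={gene_id}\n"
                )
    Path(gff_path).write_text(buf.getvalue())

    rows = [
        {"transcript_id": iso.id, **{s: iso.read_counts.get(s, 0) for s in catalog.samples}}
        for iso in catalog
    ]
    table = pd.DataFrame(rows, columns=["transcript_id", *catalog.samples])
    table.to_csv(abundance_path, sep="\t", index=False)


def read_genome(fasta_path: str | Path) -> Genome:
    """Load a FASTA genome into memory (sequences uppercased)."""
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    return Genome(sequences=sequences)


def write_genome(genome: Genome, fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
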