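"""Isoform catalog curation: collapse, thresholds, and truncation filtering.

Long-read isoform catalogs are inflated by two artifact classes: cDNA
truncations (reverse-transcription or degradation fragments of longer
transcripts that mimic novel short isoforms) and poly-A mispriming on genomic
adenine runs (spurious, typically mono-exon records). The pipeline here
removes them in three steps:

1. collapse isoforms sharing an identical splice-junction chain (optional
   step 0, mirroring upstream read-cluster deduplication), and drop isoforms
   below a full-length read floor;
2. remove isoforms with fewer than ``min_exons`` non-contiguous genomic
   segments, then the least-abundant fraction ``q`` of each gene's isoforms;
3. remove truncation artifacts by comparing exon-boundary coordinate lists
   between isoform pairs of the same gene (Rules 1 and 2 below).

Rule 1: B is a truncation of A when B's full boundary list (all 2m exon
start/end coordinates, termini included) occurs as a *contiguous* run inside
A's boundary list. Contiguity is what protects retained-intron isoforms: an
isoform that retains an intron of A skips two interior boundaries of A, so
its list is a subset but not a contiguous one.

Rule 2 relaxes the termini: B is a truncation of A when (1) B's TSS falls
strictly inside an exon of A, (2) B's TTS falls inside an exon of A or at /
3'-ward of the 5' edge of the gene's 3'-most exon, and (3) B's internal
splice boundaries form a contiguous run inside A's boundary list.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .model import GeneCatalog, GenomicInterval, Isoform

__all__ = [
    "FilterConfig",
    "FilterReport",
    "TruncationRule",
    "exon_count",
    "collapse_identical",
    "threshold_filters",
    "is_truncation",
    "filter_truncations",
    "run_filter_pipeline",
]


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the curation pipeline.

    min_reads: full-length read floor per isoform (default 2).
    min_exons: minimum number of non-contiguous genomic segments (default 4).
    abundance_quantile: fraction q of each gene's least-abundant isoforms to
        drop, as a count floor(q * n_gene) (default 0.05).
    """

    min_reads: int = 2
    min_exons: int = 4
    abundance_quantile: float = 0.05
    enable_truncation_filter: bool = True
    enable_collapse: bool = True

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.min_exons < 1:
            raise ValueError("min_exons must be >= 1")
        if not 0.0 <= self.abundance_quantile < 1.0:
            raise ValueError("abundance_quantile must be in [0, 1)")


@dataclass
class FilterReport:
    """Removal log: (isoform id, gene id, reason) plus per-gene kept/removed tallies."""

    removed: list[tuple[str, str, str]] = field(default_factory=list)
    kept_count: dict[str, int] = field(default_factory=dict)
    removed_count: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "FilterReport") -> "FilterReport":
        merged = FilterReport(removed=self.removed + other.removed)
        genes = set(self.kept_count) | set(other.kept_count)
        for g in genes:
            merged.kept_count[g] = other.kept_count.get(g, self.kept_count.get(g, 0))
            merged.removed_count[g] = self.removed_count.get(g, 0) + other.removed_count.get(g, 0)
        return merged

    @property
    def removed_ids(self) -> set[str]:
        return {iso_id for iso_id, _, _ in self.removed}


class TruncationRule(enum.Enum):
    NOT_TRUNCATION = "not_truncation"
    RULE1 = "rule1"
    RULE2 = "rule2"


def exon_count(isoform: Isoform) -> int:
    """Number of non-contiguous genomic segments (junctions with gap > 0, plus one).

    Exons that touch or overlap are merged into one segment, so an abutting
    exon pair counts as a single "exon" for filtering purposes.
    """
    segments = 1
    current_end = isoform.exons[0].end
    for e in isoform.exons[1:]:
        if e.start > current_end:
            segments += 1
        current_end = max(current_end, e.end)
    return segments


def _finish(catalog: GeneCatalog, report: FilterReport, input_counts: dict[str, int]) -> None:
    for gene_id, n_in in input_counts.items():
        kept = len(catalog.genes.get(gene_id, []))
        report.kept_count[gene_id] = kept
        report.removed_count[gene_id] = n_in - kept


def collapse_identical(catalog: GeneCatalog) -> tuple[GeneCatalog, FilterReport]:
    """Merge isoforms of a gene that share exactly the same splice-boundary chain.

    The representative is the isoform with the longest genomic span (ties:
    more reads, then lexicographically smallest id); read counts are summed
    per sample. Mono-exon isoforms all have an empty chain and therefore
    collapse together.
    """
    report = FilterReport()
    input_counts = {g: len(v) for g, v in catalog.genes.items()}
    out = GeneCatalog(genes={}, samples=list(catalog.samples))
    for gene_id, isoforms in catalog.genes.items():
        groups: dict[tuple, list[Isoform]] = {}
        group_order: list[tuple] = []
        for iso in isoforms:
            key = (iso.strand, iso.chrom, tuple(iso.splice_boundaries))
            if key not in groups:
                groups[key] = []
                group_order.append(key)
            groups[key].append(iso)
        kept: list[Isoform] = []
        for key in group_order:
            members = groups[key]
            rep = max(members, key=lambda i: (i.span, i.total_reads, _neg_id(i.id)))
            if len(members) == 1:
                kept.append(rep)
                continue
            counts = {s: 0 for s in catalog.samples} if catalog.samples else {}
            for m in members:
                for s, n in m.read_counts.items():
                    counts[s] = counts.get(s, 0) + n
            kept.append(replace(rep, read_counts=counts))
            for m in members:
                if m.id != rep.id:
                    report.removed.append((m.id, gene_id, f"collapsed_into:{rep.id}"))
        out.genes[gene_id] = kept
    _finish(out, report, input_counts)
    return out, report


class _neg_id(str):
    """Order-reversing wrapper so max() prefers the lexicographically smallest id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


def threshold_filters(catalog: GeneCatalog, config: FilterConfig) -> tuple[GeneCatalog, FilterReport]:
    """Apply the read floor, the exon-count floor, and the per-gene abundance cut.

    In order: (i) drop isoforms with total_reads < min_reads; (ii) drop
    isoforms with exon_count < min_exons; (iii) per gene, drop the
    floor(q * n) lowest-read survivors (equal-read ties keep the earlier id).
    """
    report = FilterReport()
    input_counts = {g: len(v) for g, v in catalog.genes.items()}
    out = GeneCatalog(genes={}, samples=list(catalog.samples))
    for gene_id, isoforms in catalog.genes.items():
        survivors: list[Isoform] = []
        for iso in isoforms:
            if iso.total_reads < config.min_reads:
                report.removed.append((iso.id, gene_id, "low_reads"))
            elif exon_count(iso) < config.min_exons:
                report.removed.append((iso.id, gene_id, "low_exon_count"))
            else:
                survivors.append(iso)
        n_drop = int(config.abundance_quantile * len(survivors))
        if n_drop > 0:
            # ascending reads; among ties the later id is dropped first
            ranked = sorted(survivors, key=lambda i: (i.total_reads, _neg_id(i.id)))
            dropped = {iso.id for iso in ranked[:n_drop]}
            for iso in survivors:
                if iso.id in dropped:
                    report.removed.append((iso.id, gene_id, "low_abundance"))
            survivors = [iso for iso in survivors if iso.id not in dropped]
        out.genes[gene_id] = survivors
    _finish(out, report, input_counts)
    return out, report


def _is_contiguous_run(sub: list[int], full: list[int]) -> bool:
    """Whether ``sub`` occurs as a consecutive run inside ``full``."""
    n, m = len(sub), len(full)
    if n == 0:
        return True
    if n > m:
        return False
    for i in range(m - n + 1):
        if full[i : i + n] == sub:
            return True
    return False


def _gene_three_prime_exon(isoforms: list[Isoform]) -> GenomicInterval:
    """The exon (over all isoforms of a gene) whose strand-aware 3' terminus is most extreme."""
    strand = isoforms[0].strand
    exons = [e for iso in isoforms for e in iso.exons]
    if strand == "+":
        return max(exons, key=lambda e: (e.end, e.start))
    return min(exons, key=lambda e: (e.start, e.end))


def is_truncation(
    b: Isoform,
    a: Isoform,
    gene_three_prime_exon: GenomicInterval | None = None,
) -> TruncationRule:
    """Classify whether isoform ``b`` is a truncation artifact of isoform ``a``.

    ``gene_three_prime_exon`` is the gene's 3'-most exon computed over the
    whole pre-filter isoform set; when omitted it is computed from the pair
    alone. Rule 1 is reported preferentially when both rules fire.
    """
    if b.id == a.id or b.gene_id != a.gene_id:
        return TruncationRule.NOT_TRUNCATION
    if b.strand != a.strand or b.chrom != a.chrom:
        return TruncationRule.NOT_TRUNCATION

    a_bounds = a.boundary_list
    if _is_contiguous_run(b.boundary_list, a_bounds):
        return TruncationRule.RULE1

    # Rule 2, condition 1: TSS of B strictly inside an exon of A
    if not any(e.contains_point(b.tss, strict=True) for e in a.exons):
        return TruncationRule.NOT_TRUNCATION
    # condition 3: internal boundaries of B form a contiguous run in A
    if not _is_contiguous_run(b.splice_boundaries, a_bounds):
        return TruncationRule.NOT_TRUNCATION
    # condition 2: TTS of B inside an exon of A, or at/3'-ward of the 5' edge
    # of the gene's 3'-most exon
    tts_in_a = any(e.contains_point(b.tts) for e in a.exons)
    if not tts_in_a:
        last = gene_three_prime_exon or _gene_three_prime_exon([a, b])
        if b.strand == "+":
            tts_in_a = b.tts >= last.start
        else:
            tts_in_a = b.tts <= last.end
    if not tts_in_a:
        return TruncationRule.NOT_TRUNCATION
    return TruncationRule.RULE2


def filter_truncations(catalog: GeneCatalog) -> tuple[GeneCatalog, FilterReport]:
    """Remove truncation artifacts per gene by all-pairs Rule 1/2 comparison.

    Comparisons run against the *pre-filter* isoform set of the gene, so
    removing one isoform never rescues another (a chain a > b > c removes
    both b and c). An isoform flagged against a partner that is itself
    flagged against it (possible only for degenerate mono-exon pairs) keeps
    the higher-read member, ties broken by id.
    """
    report = FilterReport()
    input_counts = {g: len(v) for g, v in catalog.genes.items()}
    out = GeneCatalog(genes={}, samples=list(catalog.samples))
    for gene_id, isoforms in catalog.genes.items():
        if len(isoforms) < 2:
            out.genes[gene_id] = list(isoforms)
            continue
        by_strand: dict[tuple[str, str], list[Isoform]] = {}
        for iso in isoforms:
            by_strand.setdefault((iso.chrom, iso.strand), []).append(iso)
        three_prime = {key: _gene_three_prime_exon(group) for key, group in by_strand.items()}

        removed: dict[str, str] = {}
        for b in isoforms:
            last = three_prime[(b.chrom, b.strand)]
            for a in isoforms:
                if a.id == b.id:
                    continue
                rule = is_truncation(b, a, gene_three_prime_exon=last)
                if rule is TruncationRule.NOT_TRUNCATION:
                    continue
                back = is_truncation(a, b, gene_three_prime_exon=last)
                if back is not TruncationRule.NOT_TRUNCATION:
                    # mutual flag: drop the lower-read member (tie -> larger id)
                    if (b.total_reads, _neg_id(b.id)) < (a.total_reads, _neg_id(a.id)):
                        removed[b.id] = f"truncation_{rule.value}_of:{a.id}"
                    continue
                removed[b.id] = f"truncation_{rule.value}_of:{a.id}"
                break
        for iso in isoforms:
            if iso.id in removed:
                report.removed.append((iso.id, gene_id, removed[iso.id]))
        out.genes[gene_id] = [iso for iso in isoforms if iso.id not in removed]
    _finish(out, report, input_counts)
    return out, report


def run_filter_pipeline(
    catalog: GeneCatalog, config: FilterConfig | None = None
) -> tuple[GeneCatalog, FilterReport]:
    """Full curation pipeline: collapse, thresholds, truncation filter."""
    config = config or FilterConfig()
    report = FilterReport(kept_count={g: len(v) for g, v in catalog.genes.items()})
    current = catalog
    if config.enable_collapse:
        current, step = collapse_identical(current)
        report = report.merge(step)
    current, step = threshold_filters(current, config)
    report = report.merge(step)
    if config.enable_truncation_filter:
        current, step = filter_truncations(current)
        report = report.merge(step)
    return current, report
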