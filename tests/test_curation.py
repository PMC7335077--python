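"""Curation pipeline: exon counting, collapse, thresholds, truncation rules.

The truncation filter is checked against a brute-force oracle written
directly from the rule definitions (windowed list comparison), independent
of the library implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from isocat.curation import (
    FilterConfig,
    TruncationRule,
    collapse_identical,
    exon_count,
    filter_truncations,
    is_truncation,
    run_filter_pipeline,
    threshold_filters,
)
from isocat.model import Isoform

from conftest import make_catalog, make_isoform, random_gene

# ---------------------------------------------------------------- oracle --


def _windows(full: list[int], n: int) -> list[list[int]]:
    return [full[i : i + n] for i in range(len(full) - n + 1)]


def oracle_rule(b: Isoform, a: Isoform, gene_isoforms: list[Isoform]) -> str:
    """Direct transcription of the two truncation rules."""
    if b.strand != a.strand or b.chrom != a.chrom or b.gene_id != a.gene_id:
        return "none"
    ab = a.boundary_list
    bb = b.boundary_list
    if bb in _windows(ab, len(bb)):
        return "rule1"
    tss_inside = any(e.start < b.tss < e.end for e in a.exons)
    internal = b.splice_boundaries
    internal_ok = internal == [] or internal in _windows(ab, len(internal))
    tts_inside = any(e.start <= b.tts <= e.end for e in a.exons)
    if not tts_inside:
        exons = [e for iso in gene_isoforms for e in iso.exons]
        if b.strand == "+":
            last = max(exons, key=lambda e: (e.end, e.start))
            tts_inside = b.tts >= last.start
        else:
            last = min(exons, key=lambda e: (e.start, e.end))
            tts_inside = b.tts <= last.end
    if tss_inside and internal_ok and tts_inside:
        return "rule2"
    return "none"


def oracle_removed(isoforms: list[Isoform]) -> set[str]:
    removed = set()
    for b in isoforms:
        for a in isoforms:
            if a.id == b.id:
                continue
            fwd = oracle_rule(b, a, isoforms)
            if fwd == "none":
                continue
            back = oracle_rule(a, b, isoforms)
            if back == "none":
                removed.add(b.id)
                break
            if (b.total_reads, a.id) < (a.total_reads, b.id):
                removed.add(b.id)
    return removed


# ------------------------------------------------------------ exon_count --


@pytest.mark.parametrize(
    "exons, expected",
    [
        ([(100, 200), (300, 400)], 2),
        ([(100, 200), (200, 300)], 1),  # abutting exons form one segment
        ([(100, 200)], 1),
        ([(0, 10), (10, 20), (30, 40), (40, 50)], 2),
    ],
)
def test_exon_count_merges_contiguous_segments(exons, expected):
    assert exon_count(make_isoform("x", exons)) == expected


# -------------------------------------------------------------- collapse --


def test_collapse_merges_identical_splice_chains():
    a = make_isoform("a", [(50, 200), (300, 400)], reads=10)
    b = make_isoform("b", [(100, 200), (300, 400)], reads=5)
    out, report = collapse_identical(make_catalog([a, b]))
    kept = out.genes["geneA"]
    assert len(kept) == 1
    assert kept[0].id == "a"  # longer genomic span wins
    assert kept[0].total_reads == 15
    assert report.removed == [("b", "geneA", "collapsed_into:a")]


def test_collapse_merges_monoexon_spans():
    a = make_isoform("a", [(0, 100)], reads=1)
    b = make_isoform("b", [(500, 700)], reads=2)
    out, report = collapse_identical(make_catalog([a, b]))
    assert len(out.genes["geneA"]) == 1
    assert len(report.removed) == 1


def test_collapse_identity_on_distinct_chains():
    a = make_isoform("a", [(0, 100), (200, 300)])
    b = make_isoform("b", [(0, 100), (250, 300)])
    out, report = collapse_identical(make_catalog([a, b]))
    assert len(out.genes["geneA"]) == 2
    assert report.removed == []


# ------------------------------------------------------------ thresholds --


def test_low_reads_removed():
    a = make_isoform("a", [(0, 10), (20, 30), (40, 50), (60, 70)], reads=1)
    b = make_isoform("b", [(0, 10), (20, 30), (40, 50), (61, 70)], reads=2)
    out, report = threshold_filters(make_catalog([a, b]), FilterConfig())
    assert [i.id for i in out.genes["geneA"]] == ["b"]
    assert ("a", "geneA", "low_reads") in report.removed


def test_low_exon_count_removed():
    three = make_isoform("t3", [(0, 10), (20, 30), (40, 50)], reads=9)
    four = make_isoform("t4", [(0, 10), (20, 30), (40, 50), (60, 70)], reads=9)
    out, report = threshold_filters(make_catalog([three, four]), FilterConfig())
    assert [i.id for i in out.genes["geneA"]] == ["t4"]
    assert ("t3", "geneA", "low_exon_count") in report.removed


def test_abundance_quantile_removes_floor_q_n():
    isoforms = [
        make_isoform(
            f"i{k:02d}",
            [(0, 10), (20, 30), (40, 50), (60, 70 + k)],
            reads=k + 1,
        )
        for k in range(20)
    ]
    out, report = threshold_filters(make_catalog(isoforms), FilterConfig(min_reads=0))
    # floor(0.05 * 20) = 1: exactly the lowest-read isoform goes
    assert len(out.genes["geneA"]) == 19
    assert report.removed == [("i00", "geneA", "low_abundance")]


def test_abundance_tie_keeps_earlier_id():
    isoforms = [
        make_isoform(f"i{k}", [(0, 10), (20, 30), (40, 50), (60, 70 + k)], reads=5)
        for k in range(20)
    ]
    _, report = threshold_filters(make_catalog(isoforms), FilterConfig(min_reads=0))
    assert report.removed == [("i9", "geneA", "low_abundance")]  # last id among equal reads


# ------------------------------------------------------- truncation rules --


A = make_isoform("a", [(0, 100), (200, 300), (400, 500)])


def test_rule1_contiguous_boundary_subset():
    b = make_isoform("b", [(200, 300), (400, 500)])
    assert is_truncation(b, A) is TruncationRule.RULE1


def test_rule2_tss_inside_parent_exon():
    b = make_isoform("b", [(250, 300), (400, 500)])
    assert is_truncation(b, A) is TruncationRule.RULE2


def test_retained_intron_is_not_truncation():
    b = make_isoform("b", [(0, 100), (200, 500)])  # intron 300-400 retained
    assert is_truncation(b, A) is TruncationRule.NOT_TRUNCATION
    assert is_truncation(A, b) is TruncationRule.NOT_TRUNCATION


def test_strand_mismatch_never_truncation():
    b = make_isoform("b", [(200, 300), (400, 500)], strand="-")
    assert is_truncation(b, A) is TruncationRule.NOT_TRUNCATION


def test_truncation_chain_removes_all_descendants():
    a = make_isoform("a", [(0, 100), (200, 300), (400, 500), (600, 700)], reads=50)
    b = make_isoform("b", [(200, 300), (400, 500), (600, 700)], reads=20)
    c = make_isoform("c", [(400, 500), (600, 700)], reads=5)
    out, report = filter_truncations(make_catalog([a, b, c]))
    assert [i.id for i in out.genes["geneA"]] == ["a"]
    assert report.removed_ids == {"b", "c"}


def test_cassette_exon_siblings_both_kept():
    a = make_isoform("a", [(0, 100), (200, 300), (400, 500), (600, 700)])
    b = make_isoform("b", [(0, 100), (400, 500), (600, 700)])  # skips the cassette
    out, _ = filter_truncations(make_catalog([a, b]))
    assert {i.id for i in out.genes["geneA"]} == {"a", "b"}


def test_single_isoform_gene_unchanged():
    out, report = filter_truncations(make_catalog([A]))
    assert [i.id for i in out.genes["geneA"]] == ["a"]
    assert report.removed == []


def test_removal_uses_prefilter_set():
    # c is a truncation of b, and b of a; removing b must not rescue c
    a = make_isoform("a", [(0, 100), (200, 300), (400, 500), (600, 700)], reads=9)
    b = make_isoform("b", [(200, 300), (400, 500), (600, 700)], reads=9)
    c = make_isoform("c", [(400, 500), (600, 700)], reads=9)
    out, _ = filter_truncations(make_catalog([a, b, c]))
    assert [i.id for i in out.genes["geneA"]] == ["a"]


def test_truncation_filter_matches_oracle_on_random_catalogs():
    rng = np.random.default_rng(1234)
    mismatches = 0
    for _ in range(100):
        isoforms = random_gene(rng)
        out, report = filter_truncations(make_catalog(isoforms))
        assert report.removed_ids == oracle_removed(isoforms), "oracle disagreement"
        assert len(out.genes["geneA"]) + len(report.removed) == len(isoforms)
    assert mismatches == 0


def test_retained_intron_fixture_never_filtered():
    parent = make_isoform("p", [(0, 100), (200, 300), (400, 500), (600, 700)], reads=40)
    retained = make_isoform("r", [(0, 100), (200, 500), (600, 700)], reads=3)
    retained2 = make_isoform("r2", [(0, 100), (200, 300), (400, 700)], reads=3)
    out, _ = filter_truncations(make_catalog([parent, retained, retained2]))
    assert {i.id for i in out.genes["geneA"]} == {"p", "r", "r2"}


# ---------------------------------------------------------------- pipeline --


def test_pipeline_removes_injected_artifacts_with_reasons():
    true_iso = make_isoform(
        "t", [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)], reads=50
    )
    trunc = make_isoform("tr", [(250, 300), (400, 500), (600, 700), (800, 900)], reads=4)
    mono = make_isoform("mo", [(1100, 1200)], reads=2)
    out, report = run_filter_pipeline(make_catalog([true_iso, trunc, mono]))
    assert [i.id for i in out.genes["geneA"]] == ["t"]
    reasons = {iso_id: reason for iso_id, _, reason in report.removed}
    assert reasons["mo"] == "low_exon_count"
    assert reasons["tr"] == "truncation_rule2_of:t"


def test_pipeline_empty_catalog():
    out, report = run_filter_pipeline(make_catalog([]))
    assert out.n_isoforms == 0
    assert report.removed == []


def test_pipeline_noop_configuration():
    isoforms = [
        make_isoform("a", [(0, 100), (200, 300)], reads=1),
        make_isoform("b", [(210, 300)], reads=1),
    ]
    config = FilterConfig(
        min_reads=0,
        min_exons=1,
        abundance_quantile=0.0,
        enable_truncation_filter=False,
        enable_collapse=False,
    )
    out, report = run_filter_pipeline(make_catalog(isoforms), config)
    assert [i.id for i in out.genes["geneA"]] == ["a", "b"]
    assert report.removed == []


def test_pipeline_idempotent():
    rng = np.random.default_rng(99)
    for _ in range(20):
        catalog = make_catalog(random_gene(rng))
        once, _ = run_filter_pipeline(catalog)
        twice, report2 = run_filter_pipeline(once)
        assert {i.id for i in twice} == {i.id for i in once}
        assert report2.removed == []


def test_kept_plus_removed_counts_balance():
    rng = np.random.default_rng(321)
    for _ in range(20):
        isoforms = random_gene(rng)
        catalog = make_catalog(isoforms)
        total_in = catalog.total_reads
        out, report = run_filter_pipeline(catalog)
        n_removed = len({i for i, _, _ in report.removed})
        assert out.n_isoforms + n_removed == len(isoforms)
        assert out.total_reads <= total_in
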