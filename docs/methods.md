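# Methods

This note documents the models and procedures implemented in `isocat`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic test bed does and does not establish.

## Coordinates and domain model

All genomic intervals are 0-based half-open on the forward strand; GFF/GTF
I/O converts from/to the 1-based inclusive file convention at the boundary.
Exons are stored in ascending genomic order regardless of strand; 5′/3′
notions (TSS, TTS, first exon, cDNA orientation) are derived from the
strand at access time. The TSS coordinate is the first exon's start on the
plus strand and the last exon's end on the minus strand (i.e. the boundary
coordinate, not the index of the first transcribed base); the TTS is the
opposite terminus. Overlapping exon records within one transcript are
rejected rather than merged — silent merging would hide malformed inputs —
while *abutting* exons are tolerated and only merged for the purpose of
segment counting (below).

Multi-sample abundance tables are supported; an isoform's `total_reads`
pools all samples, which is the quantity every filter and statistic uses.

## Curation pipeline

The pipeline applies, in order:

1. **Collapse** (optional step 0, on by default): isoforms of a gene whose
   internal splice-boundary chains are identical are merged, summing read
   counts per sample. The representative is the member with the longest
   genomic span, ties broken by read count and then lexicographic id. All
   mono-exon records of a gene share the empty chain and therefore collapse
   together. This mirrors upstream deduplication of read clusters that
   differ only in terminal lengths.
2. **Read floor**: `min_reads` = 2 full-length reads by default. Isoform
   models supported by a single read are indistinguishable from singleton
   artifacts.
3. **Segment-count floor**: `min_exons` = 4 by default, counted as the
   number of non-contiguous genomic segments (exons that touch or overlap
   merge into one segment; equivalently, junctions with a positive gap,
   plus one). Mono-exon records — the signature of genomic poly-A
   mispriming — fail this filter. The default suits catalogs of large
   multi-exon genes; set it to 1 to disable.
4. **Abundance quantile**: per gene, the `floor(q · n)` lowest-read
   survivors are removed, `q` = 0.05. The count-based reading ("the least
   abundant 5% *of isoforms*") is deliberate: it removes isoforms, not
   read mass. Among equal-read isoforms the lexicographically earlier id
   is kept, making the cut deterministic. Note a consequence of the floor:
   the step is a no-op for genes with fewer than `1/q` isoforms, and
   repeated application reaches a fixed point once `floor(q · n)` = 0.
5. **Truncation filter**: all-pairs comparison within each gene.

### Truncation rules

For isoforms *B* (candidate artifact) and *A* (candidate parent) of the
same gene, chromosome, and strand, with `boundary_list` the ascending list
of all exon start/end coordinates:

- **Rule 1**: *B*'s full boundary list (termini included) occurs as a
  contiguous run inside *A*'s. Requiring the *termini* to sit exactly on
  *A*'s boundaries makes Rule 1 strict; requiring *contiguity* is what
  spares retained-intron isoforms, whose boundary lists skip the two
  boundaries of the retained intron and so are subsets but never
  contiguous runs.
- **Rule 2** (all three conditions): (1) *B*'s TSS lies strictly inside an
  exon interval of *A* — strict containment, because a TSS *on* a boundary
  is Rule 1's territory; (2) *B*'s TTS lies inside an exon of *A*
  (inclusive containment, tolerant of termini on boundaries) **or** at or
  3′-ward of the 5′ edge of the gene's 3′-most exon, computed strand-aware
  over the gene's entire pre-filter isoform set; (3) *B*'s internal splice
  boundaries form a contiguous run inside *A*'s boundary list. Rule 2
  models 5′ degradation products whose first exon starts mid-exon and
  whose termination is unremarkable for the gene.

Rule 1 is reported preferentially when both fire. *B* is removed when some
*A* flags it and *B* does not flag *A* back; mutual flags (possible only
for degenerate mono-exon pairs) keep the higher-read member, ties broken
by id. Comparisons always run against the gene's pre-filter set, so
removing one isoform never rescues another: a nested chain a ⊃ b ⊃ c
loses both b and c. Reads of removed truncations are discarded, not
reassigned to parents — the filter's claim is that the records are
artifacts, not that their reads belong to any particular parent.

The filter assumes collapse has run first (no identical chains remain);
`run_filter_pipeline` enforces this ordering.

## Diversity statistics

The Shannon index uses the natural logarithm (nats): H′ = −Σ p_i ln p_i
with p_i = n_i/N over isoforms with p_i > 0. Zero-count isoforms
contribute nothing; an all-zero gene raises an error in the scalar
function and yields NaN in the whole-catalog report. Lorenz curves rank
isoforms by descending percent abundance (ties by id ascending) and
accumulate partial sums. Quartiles of spliced-length distributions use
linear interpolation between order statistics — the conventional default,
chosen once and documented since nothing pins the method. Diversity is
normally computed on the curated catalog; callers can equally pass the
raw catalog, and ORF-level diversity is obtained by aggregating counts
over `unique_orfs` groups before calling `shannon_index`.

## Sequence features

k-mer vectors count all overlapping k-mers (default k = 6; 4096
dimensions) of the strand-resolved 5′→3′ cDNA, not the genomic sequence.
Windows containing letters outside {A,C,G,T} are skipped rather than
erroring, to tolerate masked genomes; a sequence with no valid window is
an error. Vectors are normalized to sum to 1 so inter-isoform distances
reflect composition, not length. Distances are Euclidean; clustering is
scipy's agglomerative algorithm (complete linkage by default), and
ordination is exact PCA (deterministic up to sign) or exact t-SNE
(theta = 0, 1000 iterations, perplexity 35, mandatory explicit seed).

Exon-call matrices probe each reference exon's first and last 30
transcript-oriented bases for exact substring matches in each isoform's
cDNA; either probe matching calls the exon present, so exons truncated at
one end still register. Reference exons shorter than 30 bp use the whole
exon as both probes. The default reference exon set is the exon chain of
the gene's longest isoform (spliced length, ties by id), overridable with
any user-supplied exon list. Weighted Pearson correlation between call
columns uses full-length read counts as row weights; with integer weights
it equals ordinary Pearson on the row-expanded matrix (this identity is a
test oracle). Zero-variance (constitutive or never-called) columns yield
missing values, not zeros — the correlation is undefined and fabricating a
number would distort downstream heatmaps.

## Junction validation

Introns are classified canonical when their transcription-oriented
terminal dinucleotides are GT-AG, GC-AG, or AT-AC; on the minus strand the
genomic forward flanks are reverse-complemented before comparison, so the
classification is invariant under mirroring the genome. Evidence tables
are auto-detected as STAR `SJ.out.tab` (9+ columns; unique-read count in
column 7; strand code 0/1/2) or a simple 5-column TSV with 1-based
inclusive intron coordinates. Unstranded evidence rows match either
strand, following aligner convention. An isoform's junction support is
complete when every junction meets the read threshold (default 1).
TSS support is any-overlap of a coverage BED interval with the isoform's
5′ exon; a `window` parameter can widen the exon for looser matching,
since coverage-based 5′ evidence has no universally agreed window.

## Proteogenomics

The built-in ORF caller scans the three forward frames for ATG-initiated
ORFs and returns the longest protein (ties to the 5′-most start), marking
ORFs that run off the 3′ end as incomplete. It is a deliberately simple
stand-in — genome-aware predictors handle non-ATG initiation, truncated
5′ ends, and homology evidence — and the CLI accepts protein FASTA from
any external predictor instead. Codons containing N translate to X.

Tryptic digestion cleaves after K/R except before P. With m missed
cleavages, all concatenations of up to m + 1 consecutive fragments are
emitted in positional order. Defaults are 0 missed cleavages and no length
filter — the most conservative reading when nothing else is specified —
and both are exposed as parameters. Peptide comparison is exact string
equality; isoleucine and leucine are **not** equated (their equal masses
matter for spectral matching, which is out of scope here — the comparison
is at the database-sequence level).

## Synthetic data generator

`simdata` emulates the structure of capture-based catalogs of large,
modularly spliced genes: each gene has 8–12 exons of 80–300 bp separated
by 200–1000 bp introns, with constitutive first/last exons and cassette
exons included independently per isoform (inclusion probability drawn per
exon from 0.35–0.9); 6–14 isoforms per gene with distinct splice chains;
read counts proportional to rank^(−1.5) (Zipf), scaled so the rarest
isoform keeps 2 reads — reproducing the skewed Lorenz shapes seen in real
catalogs; GT-AG intron flanks; GC fraction 0.45. Defaults were chosen once
as representative of multi-exon cell-surface-receptor genes and are not
tuned per test.

Artifacts are generated *constructively* so ground truth is exact rather
than post-classified: truncation artifacts drop 5′ exons of a parent
(Rule 1 applies by construction) and optionally move the TSS strictly
inside the first retained exon (Rule 2); mono-exon artifacts are placed at
random intronic/downstream positions away from any exon boundary, with
1–2 reads. The recorded rule for every injected truncation is verified
against `is_truncation` in the tests. All randomness flows from a single
seed through per-gene child seeds, so outputs are byte-identical across
runs and insertion-order independent.

What the generator does *not* model — and therefore what passing tests do
not establish about real data: sequencing error and splice-site wobble,
internal (non-5′) truncations, inter-gene mapping ambiguity, non-canonical
junctions, alternative TSS/TTS among true isoforms (all true isoforms of a
gene share terminal exons), and realistic inter-sample structure (read
counts are deterministic Zipf ranks, so genes with equal isoform counts
have identical diversity). The end-to-end recovery results are guarantees
about the algorithmic contract of the filters, not field performance
estimates.

## Numerical and determinism choices

Probabilistic components (t-SNE, simulation) take explicit seeds and are
deterministic given them. Tie-breaks are fixed everywhere (documented per
operation above) so all pipeline outputs are reproducible. Quantities with
tolerance semantics: k-mer rows sum to 1 within 1e-9; Shannon agreement
with direct summation is checked at 1e-12; weighted-vs-expanded Pearson at
1e-9. Degenerate inputs fail loudly (all-zero counts, zero-read genes,
empty references) except where a missing value is the honest answer
(zero-variance correlation columns).

## Problem sizes in the test suite

The default suite runs the truncation oracle on 500 random single-gene
catalogs (≤ 20 isoforms), end-to-end recovery on 100 seeded studies
(5 genes each), 1000 Shannon vectors, 200 weighted-Pearson fixtures,
100 two-family clustering seeds, 500 random digests, and 50 serialization
round-trips; the whole suite completes in a few seconds. These sizes give
stable pass/fail behavior while keeping iteration fast; all are trivially
increased by editing the loop bounds.

## Known limitations

- Rule 2's "within/beyond the 3′-most exon" depends on the gene's
  pre-filter isoform set; catalogs split across files can classify
  borderline TTS cases differently.
- The abundance quantile is count-based and therefore not idempotent for
  genes with ≥ 1/q isoforms remaining after a pass (see above); the
  pipeline as shipped is idempotent at the catalog sizes it targets.
- The exon-call search is substring-based: a 30-bp probe that happens to
  recur elsewhere in a transcript produces a spurious call; probes are
  long enough that this is negligible for realistic sequence but it is
  not impossible.
- `unique_orfs` groups by exact protein string; proteins differing by a
  single residue are distinct groups, with no notion of similarity.
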