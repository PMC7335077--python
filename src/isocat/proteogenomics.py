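"""ORF prediction, in-silico tryptic digestion, and novel-peptide discovery.

The ORF caller is a deliberately simple built-in: it scans the three forward
frames of the 5'->3' cDNA for ATG-initiated open reading frames and returns
the one with the longest protein (ties: 5'-most start). It makes no claim of
equivalence to genome-aware ORF predictors; externally predicted protein
FASTA can be substituted anywhere downstream.

Digestion follows trypsin specificity with the proline rule: cleave after
every K or R except when the next residue is P. With ``missed_cleavages``
m > 0, every concatenation of up to m+1 consecutive fragments is also
emitted. Novel peptides are the exact-string set difference between the
catalog peptide database and an identically parameterized digest of a
reference proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .model import Genome, GeneCatalog, extract_cdna

__all__ = [
    "Orf",
    "PeptideDB",
    "predict_orf",
    "predict_orfs",
    "unique_orfs",
    "digest",
    "build_peptide_db",
    "novel_peptides",
]

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)
_VALID_BASES = set("ACGTN")


@dataclass
class Orf:
    """An open reading frame on an isoform's cDNA (0-based half-open on cDNA)."""

    isoform_id: str
    start: int
    end: int
    protein: str
    complete: bool  # True when the ORF terminates at an in-sequence stop codon


def _translate(codon: str) -> str:
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE.get(codon, "X")


def predict_orf(cdna: str, isoform_id: str = "") -> Orf | None:
    """Longest ATG-initiated ORF across the three forward frames.

    Ties go to the 5'-most start. ORFs running off the 3' end (no in-frame
    stop) are returned with ``complete=False`` and trimmed to whole codons.
    Codons containing N translate to X; returns None when no ATG exists.
    """
    if not cdna:
        raise ValueError("empty sequence")
    seq = cdna.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    best: Orf | None = None
    n = len(seq)
    # first in-frame stop at/after each position, per frame
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        aa: list[str] = []
        end = start
        complete = False
        for pos in range(start, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOP_CODONS:
                end = pos + 3
                complete = True
                break
            aa.append(_translate(codon))
            end = pos + 3
        protein = "".join(aa)
        if best is None or len(protein) > len(best.protein):
            best = Orf(isoform_id=isoform_id, start=start, end=end, protein=protein, complete=complete)
    return best


def predict_orfs(catalog: GeneCatalog, genome: Genome) -> list[Orf]:
    """Predict one ORF per isoform (isoforms with no ATG are skipped)."""
    orfs = []
    for iso in catalog:
        orf = predict_orf(extract_cdna(iso, genome), isoform_id=iso.id)
        if orf is not None:
            orfs.append(orf)
    return orfs


def unique_orfs(orfs: list[Orf]) -> tuple[list[list[Orf]], int]:
    """Group ORFs by identical protein sequence.

    Returns (groups, number of distinct proteins); groups are ordered by
    their lexicographically smallest member id, members by id.
    """
    by_protein: dict[str, list[Orf]] = {}
    for orf in orfs:
        by_protein.setdefault(orf.protein, []).append(orf)
    groups = [sorted(members, key=lambda o: o.isoform_id) for members in by_protein.values()]
    groups.sort(key=lambda g: g[0].isoform_id)
    return groups, len(groups)


def digest_with_positions(
    protein: str, missed_cleavages: int = 0, min_length: int = 0
) -> list[tuple[int, str]]:
    """Tryptic (position, peptide) pairs of a protein, in positional order.

    Cleaves after every K or R unless the next residue is P (proline rule).
    With ``missed_cleavages`` m, every concatenation of at most m+1
    consecutive fragments is also emitted; ``min_length`` filters short
    peptides.
    """
    if not protein:
        raise ValueError("empty protein")
    fragments: list[tuple[int, str]] = []
    start = 0
    for i, residue in enumerate(protein):
        if residue in "KR" and i + 1 < len(protein) and protein[i + 1] != "P":
            fragments.append((start, protein[start : i + 1]))
            start = i + 1
    if start < len(protein):
        fragments.append((start, protein[start:]))

    peptides: list[tuple[int, str]] = []
    for i in range(len(fragments)):
        for span in range(1, missed_cleavages + 2):
            if i + span > len(fragments):
                break
            pos = fragments[i][0]
            pep = "".join(frag for _, frag in fragments[i : i + span])
            if len(pep) >= min_length:
                peptides.append((pos, pep))
    peptides.sort(key=lambda t: (t[0], len(t[1])))
    return peptides


def digest(protein: str, missed_cleavages: int = 0, min_length: int = 0) -> list[str]:
    """In-silico tryptic peptides of a protein, in positional order."""
    return [pep for _, pep in digest_with_positions(protein, missed_cleavages, min_length)]


@dataclass
class PeptideDB:
    """Tryptic peptide database: peptide sequence -> {(orf id, position in protein)}."""

    peptides: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    missed_cleavages: int = 0
    min_length: int = 0

    def __len__(self) -> int:
        return len(self.peptides)


def build_peptide_db(
    orfs: list[Orf], missed_cleavages: int = 0, min_length: int = 0
) -> PeptideDB:
    """Digest every distinct protein once and record peptide provenance."""
    db = PeptideDB(missed_cleavages=missed_cleavages, min_length=min_length)
    groups, _ = unique_orfs([o for o in orfs if o.protein])
    for members in groups:
        protein = members[0].protein
        for pos, pep in digest_with_positions(protein, missed_cleavages, min_length):
            for orf in members:
                db.peptides.setdefault(pep, set()).add((orf.isoform_id, pos))
    return db


def novel_peptides(
    db: PeptideDB, reference_proteome: str | Path | dict[str, str]
) -> dict[str, set[tuple[str, int]]]:
    """Peptides of ``db`` absent from the reference proteome's identical digest.

    ``reference_proteome`` is a protein FASTA path or a mapping of id ->
    protein sequence. Returns novel peptide -> source (orf id, position)
    sets. An empty reference yields every peptide (with a warning).
    """
    if isinstance(reference_proteome, (str, Path)):
        proteins = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(reference_proteome), "fasta")
        }
    else:
        proteins = dict(reference_proteome)
    if not proteins:
        import warnings

        warnings.warn("empty reference proteome: every peptide reported as novel", stacklevel=2)
    reference_peptides: set[str] = set()
    for seq in proteins.values():
        if seq:
            reference_peptides.update(digest(seq, db.missed_cleavages, db.min_length))
    return {
        pep: sources for pep, sources in db.peptides.items() if pep not in reference_peptides
    }
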