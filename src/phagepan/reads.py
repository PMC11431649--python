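"""Amplicon read cleaning: extraction, translation and the filter report.

Raw MiSeq-style amplicon reads covering the displayed heptapeptide and its
Gly-Gly-Gly-Ser spacer are translated and split into *cleaned* and *removed*
reads.  A read is removed when its peptide contains an invalid residue
('*' from a stop codon or 'X' from an ambiguous base) or when its linker
does not translate exactly to GGGS (including reads too short to cover it).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio import SeqIO

from .genetics import STOP, UNKNOWN, translate

PEPTIDE_LEN = 7
LINKER_AA = "GGGS"
REGION_NT = 3 * (PEPTIDE_LEN + len(LINKER_AA))  # 33 nt


class ReadStatus(str, Enum):
    CLEANED = "cleaned"
    REMOVED_INVALID_AA = "removed_invalid_aa"
    REMOVED_BAD_LINKER = "removed_bad_linker"
    REMOVED_SHORT = "removed_short"


@dataclass
class ReadBatch:
    """An ordered collection of nucleotide reads with identifiers."""

    reads: list[tuple[str, str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        normalized = []
        for read_id, seq in self.reads:
            seq = seq.upper()
            if seq and set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(
                    f"read {read_id!r} contains non-ACGTN characters: {bad}"
                )
            normalized.append((read_id, seq))
        self.reads = normalized

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class TranslatedRead:
    """One read after translation, with its filter status."""

    read_id: str
    peptide: str
    linker: str
    status: ReadStatus


@dataclass
class FilterReport:
    """Cleaned/removed totals for reads and unique sequences."""

    total_reads: int
    cleaned_reads: int
    removed_reads: int
    total_unique: int
    cleaned_unique: int
    removed_unique: int

    def __post_init__(self) -> None:
        if self.cleaned_reads + self.removed_reads != self.total_reads:
            raise ValueError("cleaned + removed must equal total reads")

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.removed_reads / self.total_reads

    @classmethod
    def from_counts(
        cls,
        total_reads: int,
        removed_reads: int,
        total_unique: int = 0,
        cleaned_unique: int = 0,
        removed_unique: int = 0,
    ) -> "FilterReport":
        """Build a report from published totals (no per-read data needed)."""
        return cls(
            total_reads=total_reads,
            cleaned_reads=total_reads - removed_reads,
            removed_reads=removed_reads,
            total_unique=total_unique,
            cleaned_unique=cleaned_unique,
            removed_unique=removed_unique,
        )

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "cleaned_reads": self.cleaned_reads,
            "removed_reads": self.removed_reads,
            "pct_removed": round(self.pct_removed, 2),
            "total_unique": self.total_unique,
            "cleaned_unique": self.cleaned_unique,
            "removed_unique": self.removed_unique,
        }


def read_fastq(path, source_label: str = "") -> ReadBatch:
    """Load a FASTQ or FASTQ.gz file into a ReadBatch."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        reads = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fastq")]
    return ReadBatch(reads, source_label=source_label or path.stem)


def read_fasta(path, source_label: str = "") -> ReadBatch:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        reads = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    return ReadBatch(reads, source_label=source_label or path.stem)


def write_fastq(batch: ReadBatch, path) -> None:
    """Write 4-line FASTQ with uniform placeholder qualities ('I')."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read_id, seq in batch.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def find_offset(batch: ReadBatch, anchor: str) -> int:
    """Locate the variable region by exact match of a 5' anchor sequence.

    Returns the offset just past the anchor, determined from the first read
    containing it; raises if no read matches.
    """
    anchor = anchor.upper()
    for read_id, seq in batch.reads:
        pos = seq.find(anchor)
        if pos >= 0:
            return pos + len(anchor)
    raise ValueError(f"anchor {anchor!r} not found in any read")


def translate_read(
    sequence: str, offset: int = 0, amber_policy: str = "stop"
) -> tuple[str, str, ReadStatus]:
    """Translate the 33-nt window at ``offset``; classify the read.

    Residues 1-7 are the displayed peptide, 8-11 the linker.  Reads too short
    for the full window are ``removed_short``; a peptide containing '*' or
    'X' is ``removed_invalid_aa`` (taking precedence over a bad linker); a
    linker differing from GGGS is ``removed_bad_linker``.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    window = sequence[offset : offset + REGION_NT]
    aa = translate(window, amber_policy=amber_policy)
    peptide, linker = aa[:PEPTIDE_LEN], aa[PEPTIDE_LEN:]
    if len(window) < REGION_NT:
        return peptide, linker, ReadStatus.REMOVED_SHORT
    if STOP in peptide or UNKNOWN in peptide:
        return peptide, linker, ReadStatus.REMOVED_INVALID_AA
    if linker != LINKER_AA:
        return peptide, linker, ReadStatus.REMOVED_BAD_LINKER
    return peptide, linker, ReadStatus.CLEANED


def extract_and_translate(
    batch: ReadBatch, offset: int = 0, amber_policy: str = "stop"
) -> list[TranslatedRead]:
    """Translate every read in the batch and assign exactly one status."""
    out = []
    for read_id, seq in batch.reads:
        peptide, linker, status = translate_read(seq, offset, amber_policy)
        out.append(TranslatedRead(read_id, peptide, linker, status))
    return out


def cleaned_peptides(translated: list[TranslatedRead]) -> list[str]:
    """Peptides of cleaned reads only, in input order."""
    return [t.peptide for t in translated if t.status is ReadStatus.CLEANED]


def filter_report(translated: list[TranslatedRead]) -> FilterReport:
    """Tally cleaned/removed reads and unique sequences.

    Unique counts are over peptide strings for cleaned reads and over the
    full peptide+linker failure strings for removed reads.
    """
    if not translated:
        raise ValueError("no reads")
    cleaned, removed = set(), set()
    n_cleaned = 0
    for t in translated:
        if t.status is ReadStatus.CLEANED:
            n_cleaned += 1
            cleaned.add(t.peptide)
        else:
            removed.add(t.peptide + t.linker)
    # cleaned and removed are disjoint pools; total unique is their sum
    return FilterReport(
        total_reads=len(translated),
        cleaned_reads=n_cleaned,
        removed_reads=len(translated) - n_cleaned,
        total_unique=len(cleaned) + len(removed),
        cleaned_unique=len(cleaned),
        removed_unique=len(removed),
    )
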