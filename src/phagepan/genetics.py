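"""Genetic-code utilities for NNK-encoded peptide libraries.

NNK degenerate codons (N = A/C/G/T, K = G/T) encode all 20 amino acids in
32 codons, including the amber stop TAG.  Commercial random-peptide
libraries such as Ph.D.-7 are built from NNK cassettes and propagated in
supE (amber-suppressor) hosts, where TAG is read as Gln.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

STOP = "*"
UNKNOWN = "X"
AMBER = "TAG"
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: forward table of the standard genetic code, codon -> one-letter residue
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = STOP

#: all 32 NNK codons in lexicographic order
NNK_CODONS: tuple[str, ...] = tuple(
    sorted(b1 + b2 + b3 for b1 in "ACGT" for b2 in "ACGT" for b3 in "GT")
)

#: residue -> NNK codons encoding it (amber TAG maps to '*' here)
NNK_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon in NNK_CODONS:
    _aa = CODON_TO_AA[_codon]
    NNK_BY_AA.setdefault(_aa, ())
    NNK_BY_AA[_aa] = NNK_BY_AA[_aa] + (_codon,)

#: NNK codon multiplicity per canonical residue (Leu/Arg/Ser = 3, ... )
NNK_MULTIPLICITY: dict[str, int] = {
    aa: len(codons) for aa, codons in NNK_BY_AA.items() if aa != STOP
}
#: number of NNK codons that encode a canonical residue (32 - amber)
NNK_CODING_CODONS = sum(NNK_MULTIPLICITY.values())


def translate_codon(codon: str, amber_policy: str = "stop") -> str:
    """Translate one codon to a one-letter residue.

    Any codon containing a non-ACGT base yields ``X``.  Stop codons yield
    ``*``, except TAG under ``amber_policy='glutamine'`` (supE suppression),
    which yields ``Q``.
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must have 3 bases, got {codon!r}")
    if any(b not in "ACGT" for b in codon):
        return UNKNOWN
    if codon == AMBER and amber_policy == "glutamine":
        return "Q"
    return CODON_TO_AA[codon]


def translate(seq: str, amber_policy: str = "stop") -> str:
    """Translate a nucleotide sequence codon-by-codon (complete codons only)."""
    seq = seq.upper()
    return "".join(
        translate_codon(seq[i : i + 3], amber_policy)
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def validate_peptide(peptide: str) -> None:
    """Raise ``ValueError`` naming the first non-canonical residue, if any."""
    for pos, aa in enumerate(peptide, start=1):
        if aa not in CANONICAL_AA:
            raise ValueError(
                f"invalid amino-acid letter {aa!r} at position {pos} "
                f"of peptide {peptide!r}"
            )
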