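"""Reference-anchored sequencing-neighbor identification and removal.

An overabundant clone leaves a halo of sequencing artifacts: peptides at
Hamming distance exactly 1 from it (six of seven residues matching the
reference at the same positions, the seventh differing).  This module
identifies those neighbors in a frequency table and removes them from the
analysis, recomputing abundances and ranks over the surviving pool.
Optionally the neighbors' copy numbers can instead be collapsed back into
the reference row (error collapsing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frequency import PeptideFrequencyTable
from .genetics import validate_peptide


@dataclass
class NeighborQuery:
    reference: str
    max_distance: int = 1

    def __post_init__(self) -> None:
        validate_peptide(self.reference)
        if self.max_distance < 1:
            raise ValueError("max_distance must be >= 1")


@dataclass
class NeighborReport:
    """Matched neighbor rows plus totals, retained for audit."""

    reference: str
    matches: pd.DataFrame  # peptide, copy_number, distance,
    #                        differing_position (1-based), substituted_residue

    @property
    def n_matched_unique(self) -> int:
        return len(self.matches)

    @property
    def matched_read_total(self) -> int:
        return int(self.matches["copy_number"].sum()) if len(self.matches) else 0


def _distances(peptides: pd.Series, reference: str) -> np.ndarray:
    arr = (
        peptides.str.encode("ascii")
        .to_numpy()
        .astype(f"S{len(reference)}")
        .view("S1")
        .reshape(len(peptides), len(reference))
    )
    ref = np.frombuffer(reference.encode(), dtype="S1")
    return (arr != ref).sum(axis=1), arr != ref


def find_hamming1(
    table: PeptideFrequencyTable, query: NeighborQuery | str
) -> NeighborReport:
    """Rows whose peptide differs from the reference at 1..max_distance
    positions.  The reference itself (distance 0) is never matched.

    For distance-1 matches the differing position (1-based) and the
    substituted residue are annotated; at larger distances both are NA.
    """
    if isinstance(query, str):
        query = NeighborQuery(query)
    ref = query.reference
    pep_lengths = table.df["peptide"].str.len().unique()
    if len(pep_lengths) and pep_lengths[0] != len(ref):
        raise ValueError(
            f"reference length {len(ref)} does not match table peptide "
            f"length {pep_lengths[0]}"
        )
    dist, mismatch = _distances(table.df["peptide"], ref)
    hit = (dist >= 1) & (dist <= query.max_distance)
    matches = table.df.loc[hit, ["peptide", "copy_number"]].copy()
    matches["distance"] = dist[hit]
    is_one = matches["distance"].to_numpy() == 1
    pos = np.where(is_one, mismatch[hit].argmax(axis=1) + 1, -1)
    matches["differing_position"] = pd.array(
        np.where(is_one, pos, np.nan), dtype="Int64"
    )
    matches["substituted_residue"] = [
        p[d - 1] if one else pd.NA
        for p, d, one in zip(matches["peptide"], pos, is_one)
    ]
    return NeighborReport(reference=ref, matches=matches.reset_index(drop=True))


def remove_neighbors(
    table: PeptideFrequencyTable,
    query: NeighborQuery | str,
    also_remove_reference: bool = False,
    collapse_into_reference: bool = False,
) -> tuple[PeptideFrequencyTable, NeighborReport]:
    """Drop (or collapse) neighbor rows and rebuild the table.

    By default the matched rows are discarded and abundances/ranks are
    recomputed over the surviving pool.  With ``collapse_into_reference``
    their copy numbers are added to the reference row instead, treating the
    neighbors as sequencing errors of the reference clone.
    """
    if isinstance(query, str):
        query = NeighborQuery(query)
    if also_remove_reference and collapse_into_reference:
        raise ValueError(
            "cannot both remove the reference and collapse neighbors into it"
        )
    report = find_hamming1(table, query)
    matched = set(report.matches["peptide"])
    counts = table.df.set_index("peptide")["copy_number"]
    if collapse_into_reference:
        extra = report.matched_read_total
        counts = counts.drop(index=matched & set(counts.index))
        counts.loc[query.reference] = counts.get(query.reference, 0) + extra
    else:
        drop = matched | ({query.reference} if also_remove_reference else set())
        counts = counts.drop(index=drop & set(counts.index))
    if counts.empty:
        raise ValueError("neighbor removal left an empty table")
    new = PeptideFrequencyTable.from_counts(
        counts, sample_label=table.sample_label
    )
    return new, report
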