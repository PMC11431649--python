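"""Peptide frequency tables, diversity summaries and abundance binning.

The central analytic object is the :class:`PeptideFrequencyTable`: one row
per distinct peptide with its copy number, relative abundance (copy number
divided by the total read count of the sample) and rank.  Diversity is
summarized by the percentage of distinct sequences and of singletons
(copy number exactly 1) relative to total reads; the abundance-bin
decomposition drives the stacked-bar view of a phage pool, where each bin's
height is its share of the pool and its width the number of unique
sequences it holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: default copy-number bins: singletons, then decade bins
DEFAULT_BINS: tuple[tuple[int, int | None], ...] = (
    (1, 1),
    (2, 10),
    (11, 100),
    (101, 1_000),
    (1_001, 10_000),
    (10_001, 100_000),
    (100_001, None),
)


@dataclass
class DiversitySummary:
    """Distinct-sequence and singleton share of a sample."""

    n_distinct: int
    n_singletons: int
    total_reads: int

    @property
    def pct_distinct(self) -> float:
        return 100.0 * self.n_distinct / self.total_reads

    @property
    def pct_singletons(self) -> float:
        return 100.0 * self.n_singletons / self.total_reads

    def to_dict(self) -> dict:
        return {
            "n_distinct": self.n_distinct,
            "n_singletons": self.n_singletons,
            "total_reads": self.total_reads,
            "pct_distinct": self.pct_distinct,
            "pct_singletons": self.pct_singletons,
        }


class PeptideFrequencyTable:
    """Peptide -> copy number, relative abundance and rank for one sample.

    Rows are ranked by descending copy number; ties are broken
    lexicographically by peptide so that tables are deterministic.
    """

    COLUMNS = ("peptide", "copy_number", "relative_abundance", "rank")

    def __init__(self, df: pd.DataFrame, sample_label: str = ""):
        self.df = df.reset_index(drop=True)
        self.sample_label = sample_label
        self.total_reads = int(df["copy_number"].sum())
        if (df["copy_number"] < 1).any():
            raise ValueError("copy numbers must be >= 1")
        if not np.isclose(df["relative_abundance"].sum(), 1.0, atol=1e-9):
            raise ValueError("relative abundances must sum to 1")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_distinct(self) -> int:
        return len(self.df)

    @classmethod
    def from_counts(
        cls, counts: dict[str, int] | pd.Series, sample_label: str = ""
    ) -> "PeptideFrequencyTable":
        counts = pd.Series(counts)
        if counts.empty:
            raise ValueError("no peptides to count")
        total = int(counts.sum())
        df = counts.rename_axis("peptide").rename("copy_number").reset_index()
        df = df.sort_values(
            ["copy_number", "peptide"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        df["copy_number"] = df["copy_number"].astype(int)
        df["relative_abundance"] = df["copy_number"] / total
        df["rank"] = np.arange(1, len(df) + 1)
        return cls(df, sample_label=sample_label)

    @classmethod
    def from_peptides(
        cls, peptides: Iterable[str], sample_label: str = ""
    ) -> "PeptideFrequencyTable":
        """Count a stream of cleaned peptides into a frequency table."""
        counts = pd.Series(list(peptides), dtype=object)
        if counts.empty:
            raise ValueError("no peptides to count")
        lengths = counts.str.len()
        if lengths.nunique() > 1:
            raise ValueError("peptides must all have the same length")
        return cls.from_counts(counts.value_counts(), sample_label=sample_label)

    def to_csv(self, path) -> None:
        """Write the supplementary-style CSV layout (abundance in percent)."""
        out = self.df[["peptide", "copy_number"]].copy()
        out["relative_abundance_pct"] = 100 * self.df["relative_abundance"]
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, sample_label: str = "") -> "PeptideFrequencyTable":
        df = pd.read_csv(path)
        label = sample_label or Path(path).stem
        return cls.from_counts(
            df.set_index("peptide")["copy_number"], sample_label=label
        )

    def abundance_of(self, peptide: str) -> float:
        """Relative abundance of one peptide (0.0 if absent)."""
        rows = self.df.loc[self.df["peptide"] == peptide, "relative_abundance"]
        return float(rows.iloc[0]) if len(rows) else 0.0


def count_peptides(
    peptides: Iterable[str], sample_label: str = ""
) -> PeptideFrequencyTable:
    return PeptideFrequencyTable.from_peptides(peptides, sample_label=sample_label)


def diversity(table: PeptideFrequencyTable) -> DiversitySummary:
    """Distinct and singleton percentages relative to total reads."""
    return DiversitySummary(
        n_distinct=len(table),
        n_singletons=int((table.df["copy_number"] == 1).sum()),
        total_reads=table.total_reads,
    )


def _validate_bins(bins) -> list[tuple[int, float]]:
    """Check the bins partition [1, inf); return (lo, hi) with inf for open."""
    edges = []
    expected_lo = 1
    for i, (lo, hi) in enumerate(bins):
        if lo != expected_lo:
            raise ValueError(
                f"bins must partition [1, inf): bin {i} starts at {lo}, "
                f"expected {expected_lo}"
            )
        hi_val = np.inf if hi is None else hi
        if hi_val < lo:
            raise ValueError(f"bin {i} is empty: [{lo}, {hi}]")
        edges.append((lo, hi_val))
        expected_lo = None if hi is None else hi + 1
    if expected_lo is not None:
        raise ValueError("last bin must be open-ended (hi = None)")
    return edges


def bin_abundances(
    table: PeptideFrequencyTable, bins=DEFAULT_BINS
) -> pd.DataFrame:
    """Decompose the pool into copy-number bins.

    Returns one row per bin (in order) with columns ``bin`` (label), ``lo``,
    ``hi``, ``n_unique`` (distinct peptides in the bin) and ``pct_of_pool``
    (summed relative abundance, in percent).  Empty bins are emitted with
    zeros.
    """
    edges = _validate_bins(bins)
    copy = table.df["copy_number"].to_numpy()
    rel = table.df["relative_abundance"].to_numpy()
    rows = []
    for lo, hi in edges:
        mask = (copy >= lo) & (copy <= hi)
        label = f"[{lo},{lo}]" if hi == lo else (
            f"[{lo},inf)" if np.isinf(hi) else f"[{lo},{int(hi)}]"
        )
        rows.append(
            {
                "bin": label,
                "lo": lo,
                "hi": hi,
                "n_unique": int(mask.sum()),
                "pct_of_pool": 100.0 * rel[mask].sum(),
            }
        )
    return pd.DataFrame(rows)


def top_n(table: PeptideFrequencyTable, n: int) -> pd.DataFrame:
    """First ``n`` rows by rank (all rows if ``n`` exceeds the table)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return table.df.head(n).copy()
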