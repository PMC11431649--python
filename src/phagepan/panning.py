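"""Biopanning recovery efficiencies and Sanger-vs-NGS reconciliation.

Recovery efficiency of a selection round is the output phage titer (the
eluate) divided by the input titer, both in pfu/mL.  A rising efficiency
across rounds is conventionally read as enrichment of binders — but it
cannot distinguish target binding from propagation-driven corruption,
which is exactly what the NGS comparison below is for: joining the small
set of Sanger-sequenced clones into the deep-sequencing landscape to see
their true ranks and frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .frequency import PeptideFrequencyTable


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant figures with conventional half-up ties
    (1.55e-6 -> 1.6e-6), as titer ratios are reported."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = digits - 1 - int(np.floor(np.log10(abs(x))))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TiterSeries:
    """Per-round input/output titers (pfu/mL) and derived efficiencies."""

    df: pd.DataFrame  # round, input_pfu_ml, output_pfu_ml

    def __post_init__(self) -> None:
        required = {"round", "input_pfu_ml", "output_pfu_ml"}
        if not required <= set(self.df.columns):
            raise ValueError(f"titer table needs columns {sorted(required)}")
        if (self.df[["input_pfu_ml", "output_pfu_ml"]] <= 0).any().any():
            raise ValueError("titers must be positive")

    @classmethod
    def read_csv(cls, path) -> "TiterSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df[["round", "input_pfu_ml", "output_pfu_ml"]].to_csv(
            path, index=False
        )


def recovery_efficiency(series: TiterSeries) -> pd.DataFrame:
    """Annotate the series with per-round recovery efficiency (output/input).

    Full precision is kept in ``recovery_efficiency``; ``recovery_2sf``
    carries the conventional 2-significant-figure presentation.
    """
    df = series.df.copy()
    df["recovery_efficiency"] = df["output_pfu_ml"] / df["input_pfu_ml"]
    df["recovery_2sf"] = [round_sig(x, 2) for x in df["recovery_efficiency"]]
    return df


@dataclass
class SangerTable:
    """Clone counts from Sanger sequencing of individually picked plaques."""

    df: pd.DataFrame  # peptide, clone_count, pct

    def __post_init__(self) -> None:
        if self.df["peptide"].duplicated().any():
            dup = self.df.loc[self.df["peptide"].duplicated(), "peptide"]
            raise ValueError(f"duplicate peptides in Sanger table: {list(dup)}")
        if (self.df["clone_count"] < 1).any():
            raise ValueError("clone counts must be >= 1")

    @property
    def total_clones(self) -> int:
        return int(self.df["clone_count"].sum())

    @property
    def n_peptides(self) -> int:
        return len(self.df)

    @classmethod
    def from_counts(cls, counts: dict[str, int] | pd.Series) -> "SangerTable":
        s = pd.Series(counts).astype(int)
        df = s.rename_axis("peptide").rename("clone_count").reset_index()
        df = df.sort_values(
            ["clone_count", "peptide"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        df["pct"] = 100.0 * df["clone_count"] / df["clone_count"].sum()
        return cls(df)

    @classmethod
    def read_csv(cls, path) -> "SangerTable":
        df = pd.read_csv(path)
        return cls.from_counts(df.set_index("peptide")["clone_count"])

    def pct_of(self, peptide: str) -> float:
        rows = self.df.loc[self.df["peptide"] == peptide, "pct"]
        return float(rows.iloc[0]) if len(rows) else 0.0


@dataclass
class ComparisonReport:
    """Sanger clones joined into the NGS landscape."""

    per_peptide: pd.DataFrame  # peptide, sanger_count, sanger_pct,
    #                            ngs_copy_number, ngs_relative_abundance, ngs_rank
    n_absent_from_top100: int
    n_absent_from_top1000: int
    n_not_found: int
    boundary_ties: bool  # rank ties straddle a top-N boundary


def _top_n_cutoff_rank(ngs: PeptideFrequencyTable, n: int) -> tuple[int, bool]:
    """Largest rank included in 'top n', extending through ties at the edge."""
    if len(ngs) <= n:
        return len(ngs), False
    copy = ngs.df["copy_number"].to_numpy()
    cutoff_copy = copy[n - 1]
    extended = int(np.searchsorted(-copy, -cutoff_copy, side="right"))
    return extended, extended > n


def compare_sanger_ngs(
    sanger: SangerTable, ngs: PeptideFrequencyTable
) -> ComparisonReport:
    """Exact-string join of Sanger peptides into the NGS frequency table.

    Sanger peptides absent from the NGS table get NA copy number and rank.
    Top-N membership uses the deterministic (lexicographically tie-broken)
    ranks; ties at the N boundary include all tied rows and are flagged.
    """
    ngs_idx = ngs.df.set_index("peptide")
    rows = []
    for _, r in sanger.df.iterrows():
        pep = r["peptide"]
        if pep in ngs_idx.index:
            hit = ngs_idx.loc[pep]
            rows.append(
                (pep, r["clone_count"], r["pct"], int(hit["copy_number"]),
                 float(hit["relative_abundance"]), int(hit["rank"]))
            )
        else:
            rows.append((pep, r["clone_count"], r["pct"], pd.NA, np.nan, pd.NA))
    per = pd.DataFrame(
        rows,
        columns=[
            "peptide", "sanger_count", "sanger_pct",
            "ngs_copy_number", "ngs_relative_abundance", "ngs_rank",
        ],
    )
    per["ngs_copy_number"] = per["ngs_copy_number"].astype("Int64")
    per["ngs_rank"] = per["ngs_rank"].astype("Int64")

    cut100, t100 = _top_n_cutoff_rank(ngs, 100)
    cut1000, t1000 = _top_n_cutoff_rank(ngs, 1000)
    ranks = per["ngs_rank"]
    absent100 = int((ranks.isna() | (ranks > cut100)).sum())
    absent1000 = int((ranks.isna() | (ranks > cut1000)).sum())
    return ComparisonReport(
        per_peptide=per,
        n_absent_from_top100=absent100,
        n_absent_from_top1000=absent1000,
        n_not_found=int(ranks.isna().sum()),
        boundary_ties=t100 or t1000,
    )
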