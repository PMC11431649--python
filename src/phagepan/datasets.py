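"""Bundled reference tables from a published three-round biopanning campaign
of a commercial NNK heptapeptide library (Ph.D.-7) against human CD4.

Three small tables ship with the package:

* per-round input/output titers of the selection,
* the Sanger clone table (57 individually picked plaques from the
  third-round eluate, 30 unique peptides — including the fast-propagating
  WSLGYTG clone at 2/57),
* the NGS filter-report totals for the naive library and the third-round
  eluate (read and unique-sequence counts before/after cleaning).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .panning import SangerTable, TiterSeries
from .reads import FilterReport

#: the fast-propagating reference peptide that corrupted the selection
REFERENCE_PEPTIDE = "WSLGYTG"


def _data(name: str):
    return files("phagepan.data").joinpath(name)


def load_titers() -> TiterSeries:
    """Per-round selection titers (pfu/mL)."""
    with _data("cd4_titers.csv").open() as fh:
        return TiterSeries(pd.read_csv(fh))


def load_sanger_clones() -> SangerTable:
    """Sanger clone counts from the third-round eluate (57 clones)."""
    with _data("cd4_sanger_clones.csv").open() as fh:
        df = pd.read_csv(fh)
    return SangerTable.from_counts(df.set_index("peptide")["clone_count"])


def load_filter_counts() -> dict[str, FilterReport]:
    """Published NGS filter totals, keyed by sample label."""
    with _data("cd4_ngs_filter_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return {
        row["sample"]: FilterReport(
            total_reads=int(row["total_reads"]),
            cleaned_reads=int(row["cleaned_reads"]),
            removed_reads=int(row["removed_reads"]),
            total_unique=int(row["total_unique"]),
            cleaned_unique=int(row["cleaned_unique"]),
            removed_unique=int(row["removed_unique"]),
        )
        for _, row in df.iterrows()
    }
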