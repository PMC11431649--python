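"""Recovery efficiencies and the Sanger-vs-NGS comparison on bundled data.

Uses the packaged reference tables from a three-round selection of a
commercial heptapeptide library against human CD4: per-round titers and the
57-clone Sanger table from the third-round eluate.
"""

from phagepan import PeptideFrequencyTable, compare_sanger_ngs, recovery_efficiency
from phagepan.datasets import load_sanger_clones, load_titers

annotated = recovery_efficiency(load_titers())
print("recovery efficiency per round (output titer / input titer):")
print(annotated[["round", "input_pfu_ml", "output_pfu_ml", "recovery_2sf"]]
      .to_string(index=False))
# Efficiency rises ~200-fold across rounds - usually read as enrichment,
# but it cannot tell binders from fast propagators.

sanger = load_sanger_clones()
print(f"\nSanger: {sanger.total_clones} clones, {sanger.n_peptides} unique peptides")
print(sanger.df.head(5).to_string(index=False))

# Join the Sanger picks into a mock NGS landscape in which the fast
# propagator dominates and most Sanger peptides are rare or absent.
counts = {"WSLGYTG": 950_000}
counts.update({f"CLN{i:04d}": 1000 - i for i in range(900)})
counts.update({p: 3 for p in sanger.df["peptide"][:10] if p != "WSLGYTG"})
ngs = PeptideFrequencyTable.from_counts(counts, sample_label="mock_eluate")
report = compare_sanger_ngs(sanger, ngs)
print(f"\nnot found in NGS:        {report.n_not_found}")
print(f"absent from NGS top 100: {report.n_absent_from_top100}")
print(f"absent from NGS top 1000:{report.n_absent_from_top1000}")
# Small Sanger samples badly misrepresent the pool: most picked clones sit
# far down the NGS ranking even when the pool is 95% one clone.
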