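"""Identify and remove Hamming-1 sequencing neighbors of a dominant clone.

A clone at ~96% of the pool leaves an error halo: sequencing substitutions
turn some of its reads into peptides one residue away from WSLGYTG.  These
inflate the distinct-sequence count and are removed (or collapsed back into
the reference) before downstream statistics.
"""

from phagepan import (
    CloneSpec, LibraryModel, PanningConfig, build_library, cleaned_peptides,
    count_peptides, emit_reads, extract_and_translate, find_hamming1,
    remove_neighbors, simulate_panning,
)

library = build_library(
    LibraryModel(n_clones=1000, seed=5),
    [CloneSpec("WSLGYTG", initial_weight=2.0, propagation_factor=40.0)],
)
config = PanningConfig(n_rounds=3, reads_per_sample=50_000,
                       substitution_rate=0.002, mode="expected")
freqs = simulate_panning(library, config)
batch, _ = emit_reads(freqs[-1], library, config, seed=5, sample_label="eluate")
table = count_peptides(
    cleaned_peptides(extract_and_translate(batch, offset=len(config.flank5))),
    sample_label="eluate",
)

report = find_hamming1(table, "WSLGYTG")
print(f"neighbors found: {report.n_matched_unique} unique, "
      f"{report.matched_read_total} reads")
print(report.matches.head(10).to_string(index=False))

before = table.abundance_of("WSLGYTG")
collapsed, _ = remove_neighbors(table, "WSLGYTG", collapse_into_reference=True)
after = collapsed.abundance_of("WSLGYTG")
print(f"\nreference abundance: {before:.4f} before, {after:.4f} after collapsing")
# Each matched row is annotated with the differing position and residue;
# collapsing re-attributes those reads to the clone they came from.
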