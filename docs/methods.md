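# Methods

## Scope and model

`phagepan` audits peptide phage-display selections from amplicon deep
sequencing. The object of study is a pool of phage clones, each displaying
a 7-residue peptide followed by a Gly-Gly-Gly-Ser spacer. Two samples are
compared: the naive library and the eluate after R rounds of biopanning.
The audit asks whether the selection output reflects target binding or
corruption by clones with an amplification (propagation) advantage —
target-unrelated peptides of the propagation-related kind.

### Selection/amplification model

Each clone i carries three parameters: initial weight `w_i` (normalized to
frequencies `f_i`), binding weight `b_i` (relative capture probability
during selection, 1 = neutral) and propagation factor `ρ_i` (relative
growth multiplier during amplification, 1 = library average). One round is

    selection:      f ← f·b / Σ f·b
    amplification:  f ← f·ρ / Σ f·ρ

Round 0 is the naive library. In `expected` mode these updates are applied
deterministically; in `stochastic` mode a single multinomial draw of
`bottleneck_size` phages (default 10^6) follows each step, modeling the
finite population carried between steps. The bottleneck-as-one-multinomial
is a modeling choice: real titers constrain the census size but not the
sampling process, and a single draw per step is the simplest mechanism that
produces drift of the right order.

For a single clone with advantage ρ among neutral competitors (all b
equal), the model has the closed form

    f_R = f0·ρ^R / (f0·ρ^R + (1 − f0)),

used throughout the tests as an independent oracle. No attempt is made to
model phage biology mechanistically (infection kinetics, plaque phenotype
genetics); the propagation advantage is one multiplicative factor.

### Library generation

Random peptides are drawn per position from the NNK codon distribution
(N = A/C/G/T, K = G/T; 32 codons covering all 20 amino acids), so residue
frequencies follow NNK multiplicity (Leu/Arg/Ser 3 codons, Ala/Gly/Pro/
Thr/Val 2, the rest 1). The amber stop TAG is one of the 32 NNK codons; the
display host is a supE amber suppressor, so the generator never emits TAG
(residue probabilities are multiplicity/31) and noiseless synthetic data is
100% cleanable. On the analysis side TAG handling is configurable:
`amber_policy="stop"` (default) translates it to `*`, `"glutamine"` to `Q`
as in a supE host. Clone peptides are kept distinct by redrawing
collisions; at the default sizes (≤10^5 clones out of 20^7 ≈ 1.3·10^9
sequences) this changes the residue distribution negligibly. Initial
weights are uniform or lognormal(μ, σ); spike-in clones keep their given
weight on the same relative scale (1.0 = the weight of a uniform clone).

### Read emission

A read is `flank5 (20 nt) + 21-nt variable region + 12-nt linker + flank3
(20 nt)`. The variable region is reverse-translated one NNK codon per
residue, chosen uniformly among that residue's NNK codons; the linker uses
a fixed codon spelling. The flanks are arbitrary fixed constants (the true
vector context of commercial libraries is not modeled) and configurable;
the analysis default is therefore `offset = len(flank5) = 20`, with an
anchor-search mode (`find_offset`) for real amplicons whose layout is
known. Three noise channels are applied: per-base substitution (uniform
over the 3 other bases), per-base ambiguity (`N`), and per-read truncation
cutting inside the linker. These produce exactly the three removal classes
of the cleaning stage (stop/`X` peptides, bad linkers, short reads).
Qualities are uniform placeholders — no base-quality model. A provenance
TSV logs each read's source clone and the coordinates of every applied
corruption, which the tests use to verify classifier agreement. All
randomness derives from one global seed via per-operation `SeedSequence`
spawn keys; the same seed yields byte-identical FASTQ.

## Cleaning rules

The 33-nt window at the configured offset is translated codon-by-codon
with the standard genetic code; any codon containing a non-ACGT base gives
`X`. Residues 1–7 are the peptide, 8–11 the linker. A read is cleaned iff
the peptide contains no `*`/`X` and the linker is exactly `GGGS` at the
amino-acid level (partial matches and too-short reads fail; the
nucleotide-level spelling is deliberately not inspected, since synonymous
linker codons are valid). Each read gets exactly one status; when both a
bad peptide and a bad linker apply, the invalid-amino-acid cause is
reported (a reporting convention — totals are unaffected). Reads are
assumed already oriented; an anchor-based offset finder is provided but no
reverse-complement search is attempted by default. The filter report
counts unique sequences over cleaned peptide strings and over removed
peptide+linker strings; the two pools are disjoint by construction and the
total unique count is their sum. Percentages are reported at 2 decimals.

## Frequency, diversity, bins

Relative abundance is copy number divided by **total reads** of the sample
(not distinct count) — the convention that reproduces 8/57 = 14.0% in the
bundled Sanger table. Ranks are assigned by descending copy number with
lexicographic tie-breaking, making tables deterministic and
order-invariant. Diversity is summarized as `pct_distinct = 100·D/N` and
`pct_singletons = 100·S/N` where D is the number of distinct peptides, S
the number with copy number exactly 1, N total reads. The default bin
edges are singletons `[1]`, `[2,10]`, then decade bins up to an open
`(10^5, ∞)` bin; the edges are configurable since published stacked-bar
plots rarely print them. Per bin the summary reports the distinct-peptide
count and the summed relative abundance (percent); bins partition `[1, ∞)`
and empty bins are emitted.

## Neighbor analysis

`find_hamming1` returns all table rows at Hamming distance exactly 1 from
a reference peptide (six of seven residues equal at the same positions),
annotated with the differing position and substituted residue; the
reference itself is never matched. A generalized `max_distance` is
available but defaults to 1 — the rule of interest, not a general
denoiser. Removal discards the matched rows and recomputes abundances and
ranks over the surviving pool (renormalization is over the surviving
total); `collapse_into_reference` instead re-attributes the neighbors'
copy numbers to the reference, treating them as sequencing errors of that
clone. Discard is the default because it matches the plain reading of
"removed from the analysis"; collapsing is the natural error-model
extension and is what the end-to-end tests use when checking the spike's
clone-level abundance against the closed form. Whether abundances are
computed before or after removal is exposed by simply choosing when to
call the operation; the pipeline records the order in its manifest.

## Panning metrics

Recovery efficiency is the plain titer ratio output/input per round, in
pfu/mL, as conventionally reported; eluate and input volumes differ across
rounds, so a volume-aware efficiency would differ — the plain ratio is
what published tables print, and that is what is implemented. Reported
values use 2 significant figures with half-up tie rounding (1.55·10^-6 →
1.6·10^-6, matching printed tables); full precision is retained. The
Sanger comparison is an exact-string join into the NGS table; absentees
get NA rank, and the summary counts peptides absent from the NGS top 100
and top 1000, where ties at the boundary extend membership and are
flagged.

## Synthetic data vs real data

The generator reproduces the statistical structure the analysis assumes:
NNK residue composition, a skewed or uniform clone-abundance law, a
fast-propagating spike-in, multi-round enrichment, and the three read-
failure classes. It does **not** emulate real base-quality profiles,
PCR/chimera artifacts, paired-end merging, strand orientation mixtures, or
the true vector flanks, and its bottleneck is a single multinomial. Tests
passing on synthetic data therefore validate the *bookkeeping and the
model arithmetic* — cleaning, counting, binning, neighbor logic,
enrichment dynamics — not the upstream read-processing choices a real
MiSeq run would need.

The default test/acceptance scenario uses a 5000-clone library sequenced
at 5000 reads (depth comparable to library size keeps the naive sample
singleton-rich, mirroring real naive libraries, where depth ≪ diversity),
a spike at twice the average naive weight with ρ = 40, and three rounds —
chosen so the spike's expected final abundance (96.2%) sits in the ≥95%
corruption regime. With 0.1% per-base substitution noise, roughly 1.5% of
the spike's reads carry exactly one amino-acid-changing substitution; this
is why exact-string counting understates the clone's abundance and why the
closed-form comparison is made after collapsing Hamming-1 neighbors.

## Numerical and statistical choices

- Frequency vectors are renormalized after every simulated step; expected-
  mode sums hold to 1e-12 and the closed form is asserted at 1e-12.
- Expected-mode read counts use largest-remainder rounding so emitted
  counts sum exactly to the requested depth.
- Stochastic checks compare means over ≥20 seeds against closed forms at
  3 standard errors. Binomial checks applied simultaneously at several
  positions use a pooled 3-SE test plus a Bonferroni-safe 4-SE per-position
  bound, keeping the family-wise false-alarm rate at the intended level.
- Rank ties are always broken lexicographically; bin specs are validated
  to partition `[1, ∞)`.
- Degenerate inputs fail loudly: empty read sets, zero titers, duplicate
  Sanger peptides, all-zero binding weights ("empty eluate"), overlapping
  bins. Zero requested reads emits an empty batch with a warning.

## Full-depth reference tables

The bundled CSVs carry the printed summary tables of the reference
campaign (titers, Sanger clones, filter totals). The full per-peptide NGS
frequency tables of that campaign are distributed as external
supplementary files and are not bundled; if placed under
`tests/data/supplementary/` as `naive.csv` and `round3_eluate.csv`
(columns `peptide,copy_number`), an additional test checks the reference
clone's ~95% eluate abundance and the 41%/0.04% singleton percentages at
full depth.

## Known limitations

- The Hamming-neighbor rule is reference-anchored; it is not a general
  abundance-aware denoiser and will not find errors of non-reference
  clones.
- No rarefaction or depth correction: singleton and distinct percentages
  depend on sequencing depth, so cross-sample comparisons at very
  different depths partly reflect depth (the simulator can reproduce this
  effect but the analysis does not correct for it).
- The propagation model is phenomenological; ρ is per-round multiplicative
  and constant, with no density dependence.
- Sanger/NGS joins are exact-string; a Sanger peptide observed with a
  sequencing error in NGS counts as absent.
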