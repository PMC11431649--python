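"""Synthetic phage-display library and biopanning simulator.

Generates NNK-encoded random-heptapeptide libraries (peptide + Gly-Gly-Gly-Ser
spacer, as displayed on pIII of M13 phage), simulates rounds of affinity
selection and bacterial amplification — including fast-propagating clones
that enrich independently of target binding — and emits noisy FASTQ reads
so the whole downstream analysis can be exercised offline.

The selection/amplification model is deliberately minimal: per round, each
clone's frequency is multiplied by its relative capture probability
(``binding_weight``), renormalized, then multiplied by its relative growth
rate (``propagation_factor``) and renormalized again.  For a single clone
with propagation advantage rho among neutral competitors this gives the
closed form  f_R = f0 rho^R / (f0 rho^R + (1 - f0)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genetics import NNK_BY_AA, NNK_MULTIPLICITY, validate_peptide

# Fixed synthetic amplicon context flanking the 33-nt variable+linker region.
# These are arbitrary constants (not a real vector sequence) and configurable.
FLANK5 = "GCTGACGTCATCAACCCGCT"
FLANK3 = "GGTGGAGGATCCGGTACCTA"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class CloneSpec:
    """One clone of the library: its displayed peptide and its phenotype.

    ``propagation_factor`` is the per-amplification growth multiplier relative
    to the library average (1.0 = neutral); ``binding_weight`` the relative
    capture probability during selection (1.0 = neutral).
    """

    peptide: str
    initial_weight: float = 1.0
    propagation_factor: float = 1.0
    binding_weight: float = 1.0

    def __post_init__(self) -> None:
        validate_peptide(self.peptide)
        if self.initial_weight <= 0:
            raise ValueError("initial_weight must be positive")
        if self.propagation_factor <= 0:
            raise ValueError("propagation_factor must be positive")
        if self.binding_weight < 0:
            raise ValueError("binding_weight must be non-negative")


@dataclass
class LibraryModel:
    """Parameters of the synthetic naive library."""

    n_clones: int
    abundance_law: str = "uniform"  # "uniform" | "lognormal"
    mu: float = 0.0
    sigma: float = 1.0
    peptide_length: int = 7
    linker_aa: str = "GGGS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if self.abundance_law not in ("uniform", "lognormal"):
            raise ValueError(f"unknown abundance_law {self.abundance_law!r}")


@dataclass
class PanningConfig:
    """Parameters of the selection/amplification simulation and read emission.

    Noise channels are chosen to produce exactly the read-failure classes the
    cleaning rules look for: substitutions can create stop codons or break the
    linker, ambiguous bases translate to 'X', truncations leave the linker
    incomplete.
    """

    n_rounds: int = 3
    reads_per_sample: int = 100_000
    substitution_rate: float = 0.0
    ambiguous_rate: float = 0.0
    truncation_rate: float = 0.0
    mode: str = "stochastic"  # "stochastic" | "expected"
    bottleneck_size: int = 1_000_000
    flank5: str = FLANK5
    flank3: str = FLANK3

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        for name in ("substitution_rate", "ambiguous_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        # per-read, not per-base: saturation (all reads truncated) is allowed
        if not 0 <= self.truncation_rate <= 1:
            raise ValueError("truncation_rate must be in [0, 1]")
        if self.substitution_rate + self.ambiguous_rate >= 1:
            raise ValueError("per-base corruption rates must sum to < 1")
        if self.mode not in ("stochastic", "expected"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ReadProvenance:
    """Ground-truth record of one emitted read: source clone and corruptions."""

    read_id: str
    clone_peptide: str
    flags: list[str] = field(default_factory=list)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-operation sub-stream of a single global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# residue sampling distribution under NNK (amber TAG excluded: in the supE
# host it is suppressed, and the generator never emits stop-containing
# peptides so that noiseless synthetic data is 100% cleanable)
_NNK_AAS = sorted(NNK_MULTIPLICITY)
_NNK_P = np.array([NNK_MULTIPLICITY[a] for a in _NNK_AAS], dtype=float)
_NNK_P /= _NNK_P.sum()


def build_library(
    model: LibraryModel, spike_ins: list[CloneSpec] | None = None
) -> list[CloneSpec]:
    """Draw the naive library: spike-ins verbatim plus NNK-random peptides.

    Random peptides are drawn one NNK codon per position, so per-position
    residue frequencies follow NNK codon multiplicity (e.g. Leu 3/31 after
    amber exclusion).  Peptides are kept distinct (collisions are redrawn).
    Initial weights follow ``model.abundance_law`` for random clones and the
    spike-ins' ``initial_weight`` on the same relative scale; the returned
    weights are normalized to sum to 1.
    """
    spike_ins = list(spike_ins or [])
    if len(spike_ins) > model.n_clones:
        raise ValueError("n_clones must be >= number of spike-ins")
    for spike in spike_ins:
        if len(spike.peptide) != model.peptide_length:
            raise ValueError(
                f"spike-in {spike.peptide!r} has length {len(spike.peptide)}, "
                f"expected {model.peptide_length}"
            )

    rng = _rng(model.seed, 0)
    n_random = model.n_clones - len(spike_ins)
    seen = {s.peptide for s in spike_ins}
    peptides: list[str] = []
    while len(peptides) < n_random:
        batch = rng.choice(
            _NNK_AAS, size=(n_random - len(peptides), model.peptide_length), p=_NNK_P
        )
        for row in batch:
            pep = "".join(row)
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)

    if model.abundance_law == "uniform":
        weights = np.ones(n_random)
    else:
        weights = rng.lognormal(model.mu, model.sigma, size=n_random)

    clones = spike_ins + [
        CloneSpec(pep, initial_weight=float(w)) for pep, w in zip(peptides, weights)
    ]
    total = sum(c.initial_weight for c in clones)
    for c in clones:
        c.initial_weight /= total
    return clones


def simulate_panning(
    library: list[CloneSpec], config: PanningConfig, seed: int = 0
) -> np.ndarray:
    """Simulate ``config.n_rounds`` rounds of selection and amplification.

    Returns an array of shape ``(n_rounds + 1, n_clones)`` of clone frequency
    vectors; row 0 is the naive library.  In ``expected`` mode the update is
    deterministic; in ``stochastic`` mode a multinomial bottleneck of
    ``config.bottleneck_size`` phages is drawn after each step.
    """
    f = np.array([c.initial_weight for c in library], dtype=float)
    if not np.isclose(f.sum(), 1.0):
        raise ValueError("library weights must be normalized to sum to 1")
    f /= f.sum()
    b = np.array([c.binding_weight for c in library], dtype=float)
    rho = np.array([c.propagation_factor for c in library], dtype=float)
    if not b.any():
        raise ValueError("empty eluate: all binding weights are zero")

    rng = _rng(seed, 1)
    out = [f.copy()]
    for _ in range(config.n_rounds):
        for factor in (b, rho):
            f = f * factor
            total = f.sum()
            if total == 0:
                raise ValueError("empty eluate: no clones survived selection")
            f = f / total
            if config.mode == "stochastic":
                counts = rng.multinomial(config.bottleneck_size, f)
                f = counts / config.bottleneck_size
        out.append(f.copy())
    return np.asarray(out)


def _reverse_translate_region(
    peptides_idx: np.ndarray, clone_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-read variable region: one uniformly chosen NNK codon per residue."""
    n_reads = clone_idx.shape[0]
    pep_len = peptides_idx.shape[1]
    var = np.empty((n_reads, 3 * pep_len), dtype="S1")
    codon_bytes = {
        aa: np.array([c.encode() for c in NNK_BY_AA[aa]], dtype="S3")
        .view("S1")
        .reshape(-1, 3)
        for aa in _NNK_AAS
    }
    u = rng.random((n_reads, pep_len))
    aa_per_read = peptides_idx[clone_idx]  # (n_reads, pep_len) residue indices
    for pos in range(pep_len):
        for ai, aa in enumerate(_NNK_AAS):
            mask = aa_per_read[:, pos] == ai
            if not mask.any():
                continue
            codons = codon_bytes[aa]
            choice = (u[mask, pos] * len(codons)).astype(int)
            var[mask, 3 * pos : 3 * pos + 3] = codons[choice]
    return var


def emit_reads(
    frequencies: np.ndarray,
    library: list[CloneSpec],
    config: PanningConfig,
    seed: int = 0,
    sample_label: str = "sample",
    linker_aa: str = "GGGS",
):
    """Emit a FASTQ-ready read batch from a clone frequency vector.

    Each read is flank5 + 3L-nt reverse-translated variable region + linker
    + flank3, with per-base substitutions, per-base 'N's and per-read
    truncations (cutting into the linker) applied per ``config``.  Returns
    ``(ReadBatch, list[ReadProvenance])``; provenance flags record each
    corruption with its 0-based read coordinate (``sub:i``/``amb:i``) or the
    truncated length (``trunc:n``).
    """
    from .reads import ReadBatch  # local import to avoid a cycle

    frequencies = np.asarray(frequencies, dtype=float)
    if len(frequencies) != len(library):
        raise ValueError("frequency vector length must match library size")
    if not np.isclose(frequencies.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    n_reads = config.reads_per_sample
    if n_reads == 0:
        warnings.warn("reads_per_sample is 0: emitting an empty batch")
        return ReadBatch([], source_label=sample_label), []

    rng = _rng(seed, 2)
    if config.mode == "expected":
        # deterministic expected counts by largest remainder
        raw = frequencies * n_reads
        counts = np.floor(raw).astype(int)
        short = n_reads - counts.sum()
        if short:
            order = np.argsort(-(raw - counts), kind="stable")
            counts[order[:short]] += 1
        clone_idx = np.repeat(np.arange(len(library)), counts)
    else:
        clone_idx = rng.choice(len(library), size=n_reads, p=frequencies)

    aa_index = {aa: i for i, aa in enumerate(_NNK_AAS)}
    pep_len = len(library[0].peptide)
    peptides_idx = np.array(
        [[aa_index[a] for a in c.peptide] for c in library], dtype=np.int64
    )
    var = _reverse_translate_region(peptides_idx, clone_idx, rng)

    validate_peptide(linker_aa)
    # fixed nucleotide spelling of the linker (first NNK codon per residue)
    linker_nt = "".join(NNK_BY_AA[aa][0] for aa in linker_aa)
    fixed5 = np.frombuffer(config.flank5.encode(), dtype="S1")
    fixed3 = np.frombuffer((linker_nt + config.flank3).encode(), dtype="S1")
    reads = np.concatenate(
        [
            np.broadcast_to(fixed5, (n_reads, len(fixed5))),
            var,
            np.broadcast_to(fixed3, (n_reads, len(fixed3))),
        ],
        axis=1,
    ).copy()
    length = reads.shape[1]

    # per-base corruption: one uniform draw decides substitution vs 'N'
    u = rng.random((n_reads, length))
    sub_mask = u < config.substitution_rate
    amb_mask = (~sub_mask) & (u < config.substitution_rate + config.ambiguous_rate)
    if sub_mask.any():
        base_idx = np.searchsorted(_BASES, reads[sub_mask])
        shift = rng.integers(1, 4, size=base_idx.shape)
        reads[sub_mask] = _BASES[(base_idx + shift) % 4]
    reads[amb_mask] = b"N"

    trunc_mask = rng.random(n_reads) < config.truncation_rate
    linker_start = len(config.flank5) + var.shape[1]
    cut_len = linker_start + rng.integers(0, len(linker_nt), size=n_reads)

    batch_reads: list[tuple[str, str]] = []
    provenance: list[ReadProvenance] = []
    for i in range(n_reads):
        read_id = f"{sample_label}_read{i:07d}"
        end = cut_len[i] if trunc_mask[i] else length
        seq = reads[i, :end].tobytes().decode()
        flags = [f"sub:{j}" for j in np.flatnonzero(sub_mask[i, :end])]
        flags += [f"amb:{j}" for j in np.flatnonzero(amb_mask[i, :end])]
        if trunc_mask[i]:
            flags.append(f"trunc:{end}")
        batch_reads.append((read_id, seq))
        provenance.append(ReadProvenance(read_id, library[clone_idx[i]].peptide, flags))
    return ReadBatch(batch_reads, source_label=sample_label), provenance


def write_provenance(provenance: list[ReadProvenance], path) -> None:
    """Write the ground-truth log as TSV: read_id, clone_peptide, flags."""
    with open(path, "w") as fh:
        fh.write("read_id\tclone_peptide\tcorruption_flags\n")
        for rec in provenance:
            fh.write(f"{rec.read_id}\t{rec.clone_peptide}\t{','.join(rec.flags)}\n")
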