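"""Tests of the NNK library generator and the panning simulator."""

import numpy as np
import pytest

from phagepan import (
    CloneSpec,
    LibraryModel,
    PanningConfig,
    build_library,
    cleaned_peptides,
    emit_reads,
    extract_and_translate,
    filter_report,
    simulate_panning,
    write_fastq,
)
from phagepan.genetics import CODON_TO_AA, NNK_CODONS, translate_codon
from phagepan.reads import ReadStatus


def closed_form(f0, rho, rounds):
    """Expected frequency of a single growth-advantaged clone among neutrals."""
    return f0 * rho**rounds / (f0 * rho**rounds + (1 - f0))


class TestBuildLibrary:
    def test_single_spike_identity(self):
        lib = build_library(LibraryModel(n_clones=1), [CloneSpec("WSLGYTG")])
        assert len(lib) == 1
        assert lib[0].peptide == "WSLGYTG"
        assert lib[0].initial_weight == 1.0

    def test_uniform_normalization(self):
        lib = build_library(LibraryModel(n_clones=1000, seed=7))
        assert len(lib) == 1000
        assert all(len(c.peptide) == 7 for c in lib)
        assert all(set(c.peptide) <= set("ACDEFGHIKLMNPQRSTVWY") for c in lib)
        np.testing.assert_allclose(
            [c.initial_weight for c in lib], 1 / 1000, rtol=1e-12
        )

    def test_peptides_are_distinct(self):
        lib = build_library(LibraryModel(n_clones=2000, seed=3))
        assert len({c.peptide for c in lib}) == 2000

    def test_nnk_residue_frequencies(self):
        """Per-position residue frequencies follow NNK codon multiplicity.

        Oracle: enumerate all 32 NNK codons; Leu is encoded by 3 of them and
        the amber stop by 1, so with amber excluded the expected Leu
        frequency per position is 3/31.
        """
        leu_codons = [c for c in NNK_CODONS if CODON_TO_AA[c] == "L"]
        stop_codons = [c for c in NNK_CODONS if CODON_TO_AA[c] == "*"]
        assert len(leu_codons) == 3 and len(stop_codons) == 1
        p_leu = len(leu_codons) / (len(NNK_CODONS) - len(stop_codons))

        lib = build_library(LibraryModel(n_clones=100_000, seed=1))
        residues = np.array([list(c.peptide) for c in lib])
        n = len(lib)
        se = np.sqrt(p_leu * (1 - p_leu) / n)
        # pooled over positions at 3 SE; per position with a Bonferroni-safe
        # bound (7 simultaneous binomial checks)
        pooled = (residues == "L").mean()
        assert abs(pooled - p_leu) < 3 * se / np.sqrt(7)
        for pos in range(7):
            observed = (residues[:, pos] == "L").mean()
            assert abs(observed - p_leu) < 4 * se

    def test_invalid_spike_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'Z'"):
            build_library(LibraryModel(n_clones=1), [CloneSpec("WSLGYTZ")])

    def test_more_spikes_than_clones_rejected(self):
        with pytest.raises(ValueError):
            build_library(
                LibraryModel(n_clones=1),
                [CloneSpec("AAAAAAA"), CloneSpec("CCCCCCC")],
            )

    def test_lognormal_weights_positive_and_normalized(self):
        lib = build_library(
            LibraryModel(n_clones=500, abundance_law="lognormal", sigma=2.0, seed=5)
        )
        w = np.array([c.initial_weight for c in lib])
        assert (w > 0).all()
        assert np.isclose(w.sum(), 1.0)


class TestSimulatePanning:
    def test_neutral_clones_are_a_fixed_point(self):
        lib = [CloneSpec("AAAAAAA", 0.3), CloneSpec("CCCCCCC", 0.7)]
        freqs = simulate_panning(lib, PanningConfig(n_rounds=5, mode="expected"))
        for row in freqs:
            np.testing.assert_allclose(row, [0.3, 0.7], atol=1e-12)

    @pytest.mark.parametrize("rho", [1.5, 2.0, 5.0, 25.0])
    @pytest.mark.parametrize("rounds", [1, 3, 10])
    def test_expected_mode_matches_closed_form(self, rho, rounds):
        f0 = 0.01
        lib = [
            CloneSpec("WSLGYTG", f0, propagation_factor=rho),
            CloneSpec("AAAAAAA", 1 - f0),
        ]
        freqs = simulate_panning(lib, PanningConfig(n_rounds=rounds, mode="expected"))
        for r in range(rounds + 1):
            assert freqs[r, 0] == pytest.approx(closed_form(f0, rho, r), abs=1e-12)

    def test_frequencies_sum_to_one_every_round(self, small_library):
        config = PanningConfig(n_rounds=4, mode="expected")
        freqs = simulate_panning(small_library, config)
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0, atol=1e-12)

    def test_advantaged_clone_strictly_increases(self):
        lib = [CloneSpec("WSLGYTG", 0.001, propagation_factor=2.0)] + [
            CloneSpec(p, 0.111) for p in (
                "AAAAAAA", "CCCCCCC", "DDDDDDD", "EEEEEEE", "FFFFFFF",
                "GGGGGGG", "HHHHHHH", "IIIIIII", "KKKKKKK",
            )
        ]
        total = sum(c.initial_weight for c in lib)
        for c in lib:
            c.initial_weight /= total
        freqs = simulate_panning(lib, PanningConfig(n_rounds=8, mode="expected"))
        spike = freqs[:, 0]
        assert (np.diff(spike) > 0).all()

    def test_stochastic_mean_matches_closed_form(self):
        """Monte-Carlo vs the closed form: mean over 20 seeds within 3 SE."""
        f0, rho, rounds = 0.01, 2.0, 3
        lib = [
            CloneSpec("WSLGYTG", f0, propagation_factor=rho),
            CloneSpec("AAAAAAA", 1 - f0),
        ]
        config = PanningConfig(
            n_rounds=rounds, mode="stochastic", bottleneck_size=1_000_000
        )
        finals = np.array(
            [simulate_panning(lib, config, seed=s)[-1, 0] for s in range(20)]
        )
        expected = closed_form(f0, rho, rounds)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se

    def test_all_zero_binding_is_empty_eluate(self):
        lib = [CloneSpec("AAAAAAA", 1.0, binding_weight=0.0)]
        with pytest.raises(ValueError, match="empty eluate"):
            simulate_panning(lib, PanningConfig(n_rounds=1, mode="expected"))

    def test_round_zero_is_naive_library(self, small_library):
        freqs = simulate_panning(small_library, PanningConfig(n_rounds=0))
        np.testing.assert_allclose(
            freqs[0], [c.initial_weight for c in small_library]
        )


class TestEmitReads:
    def test_zero_noise_is_fully_cleanable(self, small_library, naive_frequencies):
        config = PanningConfig(reads_per_sample=2000)
        batch, _ = emit_reads(naive_frequencies, small_library, config, seed=3)
        translated = extract_and_translate(batch, offset=len(config.flank5))
        report = filter_report(translated)
        assert report.removed_reads == 0
        peptides = set(cleaned_peptides(translated))
        assert peptides <= {c.peptide for c in small_library}

    def test_full_truncation_fails_linker_check(self, small_library, naive_frequencies):
        config = PanningConfig(reads_per_sample=500, truncation_rate=1.0)
        batch, prov = emit_reads(naive_frequencies, small_library, config, seed=5)
        translated = extract_and_translate(batch, offset=len(config.flank5))
        assert all(
            t.status in (ReadStatus.REMOVED_SHORT, ReadStatus.REMOVED_BAD_LINKER)
            for t in translated
        )
        assert all(any(f.startswith("trunc:") for f in p.flags) for p in prov)

    def test_substitution_removal_rate_matches_enumeration_oracle(self):
        """Removed-read fraction under substitutions only, vs an exact
        per-codon enumeration of mutation outcomes.

        With a single-clone library every read encodes the same peptide, so
        the per-read removal probability is 1 - prod over the 11 window
        codons of P(codon still translates acceptably), averaged over the
        generator's uniform NNK codon choice per residue.
        """
        p = 0.002
        clone = CloneSpec("WSLGYTG")
        lib = [clone]
        config = PanningConfig(
            reads_per_sample=100_000, substitution_rate=p, mode="stochastic"
        )

        from phagepan.genetics import NNK_BY_AA

        def p_codon_ok(codon, accept):
            """Enumerate all 64 mutated variants of a codon; each base stays
            with prob 1-p or becomes one of the 3 others with prob p/3."""
            total = 0.0
            for b0 in "ACGT":
                for b1 in "ACGT":
                    for b2 in "ACGT":
                        w = 1.0
                        for orig, new in zip(codon, b0 + b1 + b2):
                            w *= (1 - p) if orig == new else p / 3
                        if accept(translate_codon(b0 + b1 + b2)):
                            total += w
            return total

        p_read_ok = 1.0
        for aa in clone.peptide:  # random codon per residue, uniform over NNK
            codons = NNK_BY_AA[aa]
            p_read_ok *= np.mean(
                [p_codon_ok(c, lambda a: a not in "*X") for c in codons]
            )
        for aa in "GGGS":  # fixed linker codon: must still translate to aa
            codon = NNK_BY_AA[aa][0]
            p_read_ok *= p_codon_ok(codon, lambda a, want=aa: a == want)
        p_removed = 1 - p_read_ok

        batch, _ = emit_reads(np.array([1.0]), lib, config, seed=9)
        translated = extract_and_translate(batch, offset=len(config.flank5))
        observed = filter_report(translated).removed_reads / len(batch)
        se = np.sqrt(p_removed * (1 - p_removed) / len(batch))
        assert abs(observed - p_removed) < 3 * se

    def test_same_seed_byte_identical_fastq(self, tmp_path, small_library,
                                            naive_frequencies):
        config = PanningConfig(
            reads_per_sample=300, substitution_rate=0.01, truncation_rate=0.05
        )
        paths = []
        for i in (1, 2):
            batch, _ = emit_reads(naive_frequencies, small_library, config, seed=42)
            out = tmp_path / f"run{i}.fastq"
            write_fastq(batch, out)
            paths.append(out)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_empty_batch_warns(self, small_library, naive_frequencies):
        config = PanningConfig(reads_per_sample=0)
        with pytest.warns(UserWarning):
            batch, prov = emit_reads(naive_frequencies, small_library, config)
        assert len(batch) == 0 and prov == []

    def test_expected_mode_counts_match_frequencies(self):
        lib = [CloneSpec("AAAAAAA", 0.25), CloneSpec("CCCCCCC", 0.75)]
        config = PanningConfig(reads_per_sample=1000, mode="expected")
        batch, prov = emit_reads(np.array([0.25, 0.75]), lib, config, seed=0)
        from collections import Counter

        counts = Counter(p.clone_peptide for p in prov)
        assert counts["AAAAAAA"] == 250 and counts["CCCCCCC"] == 750

    def test_provenance_coordinates_predict_status(self, small_library,
                                                   naive_frequencies):
        """With ambiguous bases as the only corruption, the generator's
        logged 'N' coordinates determine the filter status exactly."""
        config = PanningConfig(reads_per_sample=3000, ambiguous_rate=0.004)
        batch, prov = emit_reads(naive_frequencies, small_library, config, seed=13)
        offset = len(config.flank5)
        translated = extract_and_translate(batch, offset=offset)
        by_id = {t.read_id: t for t in translated}
        for rec in prov:
            positions = [int(f.split(":")[1]) for f in rec.flags
                         if f.startswith("amb:")]
            in_peptide = any(offset <= j < offset + 21 for j in positions)
            in_linker = any(offset + 21 <= j < offset + 33 for j in positions)
            status = by_id[rec.read_id].status
            if in_peptide:
                assert status is ReadStatus.REMOVED_INVALID_AA
            elif in_linker:
                assert status is ReadStatus.REMOVED_BAD_LINKER
            else:
                assert status is ReadStatus.CLEANED
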