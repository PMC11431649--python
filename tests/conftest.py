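import pytest

from phagepan import (
    CloneSpec,
    LibraryModel,
    PanningConfig,
    build_library,
    simulate_panning,
)
from phagepan.datasets import REFERENCE_PEPTIDE


@pytest.fixture(scope="session")
def small_library():
    """50 NNK-random clones plus the WSLGYTG spike, uniform weights."""
    model = LibraryModel(n_clones=50, seed=7)
    return build_library(model, [CloneSpec(REFERENCE_PEPTIDE)])


@pytest.fixture(scope="session")
def naive_frequencies(small_library):
    return simulate_panning(small_library, PanningConfig(n_rounds=0))[0]


@pytest.fixture()
def corrupted_campaign():
    """A selection corrupted by a fast propagator reaching >=95% by round 3.

    1000 uniform clones; the spike starts at twice the average weight with a
    25x per-amplification growth advantage and no binding advantage, so its
    expected round-3 frequency is f0*rho^3 / (f0*rho^3 + 1 - f0) ~ 0.969.
    """
    model = LibraryModel(n_clones=1000, seed=11)
    spike = CloneSpec(REFERENCE_PEPTIDE, initial_weight=2.0, propagation_factor=25.0)
    library = build_library(model, [spike])
    config = PanningConfig(n_rounds=3, reads_per_sample=20_000, mode="expected")
    return library, config
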