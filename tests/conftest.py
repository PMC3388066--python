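import numpy as np
import pytest

from znfarray.simulate import (
    SimulationConfig,
    simulate_codon_alignment,
    simulate_repeat_library,
    simulate_znf_population,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_library():
    return simulate_repeat_library(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def small_population():
    cfg = SimulationConfig(seed=5, groups=("g1", "g2"), n_shared_alleles=1, dropout=0.0)
    return cfg, simulate_znf_population(cfg)


@pytest.fixture(scope="session")
def small_codon_data():
    """8-taxon, 80-site M2a-simulated alignment reused by slow model tests."""
    cfg = SimulationConfig(seed=41, n_codon_sites=80, n_taxa=8)
    aln, tree, truth = simulate_codon_alignment(cfg)
    return cfg, aln, tree, truth


@pytest.fixture(scope="session")
def model_fit_suite(small_codon_data):
    """All six site models fitted once on the shared alignment."""
    from znfarray.selection.models import fit_site_model

    _, aln, tree, _ = small_codon_data
    return {
        m: fit_site_model(aln, tree, model=m, n_restarts=1, optimize_branch_lengths=False)
        for m in ("M0", "M1a", "M2a", "M3", "M7", "M8")
    }
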