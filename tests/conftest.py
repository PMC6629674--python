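import numpy as np
import pytest

from mutspectra import (
    GenomeSpec,
    SimulationParams,
    generate_panel,
    load_blosum100,
    load_grantham,
)


@pytest.fixture(scope="session")
def grantham():
    return load_grantham()


@pytest.fixture(scope="session")
def blosum100():
    return load_blosum100()


@pytest.fixture(scope="session")
def small_panel():
    """Three-point GC gradient, small genomes: fast qualitative checks."""
    base = GenomeSpec(gc_target=0.25, n_genes=120, mean_len_codons=150, seed=11)
    panel = generate_panel((0.25, 0.45, 0.65), base_spec=base, seed=11)
    return {gid: recs for gid, (recs, _) in panel.items()}


def scaled_params(**kw):
    """Invasion parameters at the reduced demography used throughout tests."""
    defaults = dict(n_bottleneck=1_000, n_max=100_000.0)
    defaults.update(kw)
    return SimulationParams(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
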