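import numpy as np
import pandas as pd
import pytest

from stressmeth.synthetic_data import (
    SimulationConfig,
    make_design,
    simulate_methylation,
    simulate_study,
)


@pytest.fixture(scope="session")
def design4x6():
    return make_design(SimulationConfig())


@pytest.fixture(scope="session")
def default_study():
    """One in-memory default-size study shared across tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A written study directory (exercises the file round trip)."""
    d = tmp_path_factory.mktemp("study")
    simulate_study(SimulationConfig(seed=11), outdir=d)
    return d


def methylation_scenario(seed, n_sites, shift, config=None):
    """Flat helper: a single-chromosome methylation matrix with given
    per-site probability shifts under the default 4x6 design."""
    config = config or SimulationConfig(seed=seed, n_cpg=n_sites)
    rng = np.random.default_rng(seed)
    cpg = pd.DataFrame(
        {"chrom": ["chr1"] * n_sites,
         "pos": np.arange(10, 10 + n_sites * 10, 10)}
    )
    design = make_design(config)
    mat, baseline = simulate_methylation(config, cpg, shift, design, rng)
    return mat, design, baseline
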