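import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from divergescan.config import SimulationConfig
from divergescan import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=24, seed=11)


@pytest.fixture(scope="session")
def small_genomes(small_config):
    return sim.generate_gene_models(small_config)


@pytest.fixture(scope="session")
def small_simulation(small_config, tmp_path_factory):
    """A complete small synthetic study written to disk once per session."""
    outdir = tmp_path_factory.mktemp("sim")
    manifest = sim.simulate_all(small_config, outdir)
    return small_config, outdir, manifest
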