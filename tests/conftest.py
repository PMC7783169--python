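import pytest

from cifdyn.synthetic_evolution import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A ~10-strain simulated dataset with a mixture of intact and
    pseudogenized pairs, shared across read-only tests."""
    cfg = SimulationConfig(n_strains=10, seed=11, hgt_rate=0.4)
    catalog, tree, log = simulate_dataset(cfg)
    return cfg, catalog, tree, log


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    cfg = SimulationConfig(n_strains=10, seed=11, hgt_rate=0.4)
    catalog, tree, log = simulate_dataset(cfg, out_dir=out)
    return out, cfg, catalog, tree, log
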