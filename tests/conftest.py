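import numpy as np
import pytest

from sedm.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small but complete synthetic cohort shared across unit tests."""
    cfg = SimulationConfig(
        seed=42,
        n_case=10,
        n_control=8,
        n_se=40,
        chrom_lengths={"chrA": 10_000_000, "chrB": 10_000_000},
        n_val_case=10,
        n_val_control=5,
    )
    out = tmp_path_factory.mktemp("small_sim")
    return simulate(cfg, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
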