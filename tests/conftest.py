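import numpy as np
import pytest

from radialmvmr import SimConfig, SummaryDataset, generate_individual_data


def random_dataset(rng: np.random.Generator, n_snps: int = 30,
                   n_exposures: int = 3) -> SummaryDataset:
    """A generic random summary dataset (not from the structured generator)."""
    return SummaryDataset(
        snp_ids=[f"rs{j + 1}" for j in range(n_snps)],
        exposure_names=[f"X{k + 1}" for k in range(n_exposures)],
        gamma=rng.normal(0, 5, (n_snps, n_exposures)),
        se_gamma=rng.uniform(0.2, 1.0, (n_snps, n_exposures)),
        Gamma=rng.normal(0, 5, n_snps),
        se_Gamma=rng.uniform(0.2, 1.0, n_snps),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


@pytest.fixture(scope="session")
def sim_small():
    """One structured simulated dataset, small N (fast; instruments weak)."""
    cfg = SimConfig.simulation_one(seed=11, n_per_sample=4000)
    return generate_individual_data(cfg)


@pytest.fixture(scope="session")
def sim_medium():
    """One structured simulated dataset at moderate N (instruments strong)."""
    cfg = SimConfig.simulation_one(seed=7, n_per_sample=60_000)
    return generate_individual_data(cfg)
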