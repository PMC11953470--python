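import numpy as np
import pandas as pd
import pytest

from epitype.annotation import build_consensus_gene_models
from epitype.simulate import DMCBlock, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=40,
        n_probes=2000,
        dmc_blocks=[DMCBlock(n=50, delta_beta=0.4)],
        n_pairs=20,
        n_genes=100,
        seed=221027,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_models(small_cohort):
    return build_consensus_gene_models(small_cohort.gene_records)


def make_beta(rng, n_probes, n_samples, loc=0.5, sd=0.05):
    vals = np.clip(rng.normal(loc, sd, (n_probes, n_samples)), 0, 1)
    return pd.DataFrame(
        vals,
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
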