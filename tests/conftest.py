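import numpy as np
import pandas as pd
import pytest

from epimet import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def tiny_sim():
    """Small two-cohort bundle with planted effects, shared across tests."""
    cfg = SimulationConfig(
        n_probes=2000,
        n_genes=150,
        samples_per_group={"PT": 3, "LN": 3, "LU": 3},
        n_planted_dms_genes=20,
        n_isolated_planted=20,
        seed=7,
    )
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study conditions (desk scale)."""
    return simulate_cohorts(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_manifest():
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:03d}" for i in range(6)],
            "chromosome": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
            "position": [100, 9000, 10001, 400, 501, 2500],
            "cpg_context": ["island", "shore", "open_sea", "shelf", "island", "open_sea"],
        }
    )
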