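import numpy as np
import pandas as pd
import pytest

from dualomics.core_io import AbundanceTable
from dualomics.simulate import default_config, simulate_cohort


@pytest.fixture
def toy_table() -> AbundanceTable:
    """Four taxa, three samples, closed to 100."""
    data = pd.DataFrame(
        {
            "Bacteroides_vulgatus": [40.0, 10.0, 25.0],
            "Prevotella_copri": [30.0, 60.0, 25.0],
            "Faecalibacterium_prausnitzii": [20.0, 25.0, 25.0],
            "Ruminococcus_gnavus": [10.0, 5.0, 25.0],
        },
        index=["S1", "S2", "S3"],
    )
    return AbundanceTable(data, closure=100.0, rank="species")


@pytest.fixture(scope="session")
def small_cohort():
    """One default-regime synthetic cohort at reduced species count."""
    cfg = default_config(seed=42, n_species=60)
    return simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
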