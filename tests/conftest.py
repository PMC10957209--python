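import numpy as np
import pandas as pd
import pytest

import mimicsem as ms
from mimicsem.simulate import SyntheticConfig


@pytest.fixture(scope="session")
def small_config():
    """Reduced atlas (6 gray regions, 4 tracts -> 30 features) with a few
    strong true paths; complete data."""
    return SyntheticConfig(
        n_participants=5000,
        seed=42,
        n_gray_regions=6,
        n_white_tracts=4,
        missing_rate=0.0,
        true_paths={
            "SA_region01": 0.18,
            "SA_region02": 0.16,
            "GMV_region03": 0.20,
            "WMV_tract01": 0.17,
            "FA_tract02": 0.15,
        },
        within_metric_rho=0.2,
        cross_metric_rho=0.25,
        cross_tissue_rho=0.1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ms.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    return ms.assemble_frame(small_dataset.cognition, small_dataset.brain)


@pytest.fixture(scope="session")
def cfa_spec(small_dataset):
    return ms.MimicModelSpec(small_dataset.cognition.task_names)


@pytest.fixture(scope="session")
def missing_dataset():
    """Same structure with 5% MCAR missingness on the cognition columns."""
    cfg = SyntheticConfig(
        n_participants=3000,
        seed=7,
        n_gray_regions=3,
        n_white_tracts=2,
        missing_rate=0.05,
        true_paths={"SA_region01": 0.2, "WMV_tract01": 0.15},
    )
    return ms.generate_dataset(cfg)
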