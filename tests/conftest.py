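import numpy as np
import pandas as pd
import pytest

import ftir_sputum as fs


def screen_cohort(config: fs.CohortConfig):
    """Generate -> preprocess -> aggregate -> significance table."""
    cohort = fs.generate_cohort(config)
    per_sample = fs.aggregate_replicates(fs.preprocess_cohort(cohort))
    return per_sample, fs.screen_wavenumbers(per_sample)


@pytest.fixture(scope="session")
def default_screen():
    """Per-sample second-derivative cohort and screen for the default planted
    cohort (seed 1); shared across recovery and acceptance tests."""
    return screen_cohort(fs.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def null_rejection_flags():
    """Whether each of 20 seeded zero-effect cohorts produced any Holm rejection."""
    flags = []
    for seed in range(20):
        _, table = screen_cohort(fs.null_config(seed=seed))
        flags.append(bool(table["reject"].any()))
    return flags


@pytest.fixture
def tiny_cohort():
    grid = fs.WavenumberGrid([1000.0, 1010.0, 1020.0])
    matrix = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])
    meta = pd.DataFrame({
        "sample_id": ["S1", "S2"],
        "replicate": [1, 1],
        "class": ["cancer", "normal"],
        "smoking_status": ["smoker", "never_smoker"],
    })
    return fs.SpectrumCohort(grid, matrix, meta)
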