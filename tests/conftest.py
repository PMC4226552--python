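import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import aflpscan as a

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """6 populations x 12 individuals x 60 loci with a few spiked classes."""
    cfg = a.default_study_config(
        seed=123,
        n_pops=6,
        n_ind_per_pop=12,
        n_loci=60,
        fractions={
            "neutral": 0.8,
            "positive": 0.05,
            "balancing": 0.05,
            "sex_linked": 0.05,
            "batch_artifact": 0.0,
            "low_frequency": 0.05,
            "monomorphic": 0.0,
        },
    )
    return a.simulate(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return small_dataset[0]


@pytest.fixture()
def toy_matrix():
    """Hand-sized intensity matrix: 4 samples x 3 markers, no randomness."""
    samples = pd.DataFrame(
        {
            "population_id": ["p1", "p1", "p2", "p2"],
            "sex": ["female", "male", "female", "male"],
            "plate_id": ["A", "A", "B", "B"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    values = pd.DataFrame(
        [[1000.0, 10.0, 500.0], [950.0, 20.0, 0.0], [0.0, 900.0, 480.0], [30.0, 880.0, 510.0]],
        index=samples.index,
        columns=["AAtt1", "AAtt2", "CCgg5"],
    )
    return a.IntensityMatrix(values, samples)
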