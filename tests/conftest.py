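import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proteopanel import synthetic, vsn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale proteome: 120 proteins, 24 planted, same noise model."""
    return synthetic.SynthProteomeConfig(
        n_proteins=120, n_differential=24, group_sizes=(5, 5, 5), seed=7
    )


@pytest.fixture(scope="session")
def small_matrix(small_config):
    matrix, truth = synthetic.gen_proteome(small_config)
    return matrix, truth


@pytest.fixture(scope="session")
def small_normalized(small_matrix):
    matrix, _ = small_matrix
    return vsn.vsn_normalize(matrix)


@pytest.fixture(scope="session")
def default_matrix():
    """Full-scale generated cohort: 1081 x 22 with 204 planted effects."""
    matrix, truth = synthetic.gen_proteome(synthetic.SynthProteomeConfig(seed=11))
    return matrix, truth
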