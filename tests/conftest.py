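import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_2601)


@pytest.fixture(scope="session")
def qc_run_pair():
    """A default-condition synthetic 1:1 run pair shared across tests."""
    from ftmscorr.synthetic import RunSpec, generate_run_pair

    return generate_run_pair(RunSpec(seed=11))


@pytest.fixture(scope="session")
def qc_library(qc_run_pair):
    """Correction-function library fitted on run 1 of the shared pair."""
    from ftmscorr.suppression_analysis import build_function_library

    run1, _, _ = qc_run_pair
    return build_function_library(run1.pairs)


@pytest.fixture(scope="session")
def qc_exp_null(qc_run_pair):
    from ftmscorr.suppression_analysis import experimental_null

    run1, run2, _ = qc_run_pair
    return experimental_null(run1.pairs, run2.pairs)
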