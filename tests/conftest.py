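import pytest

from mitemir.pipeline import run_synthetic_pipeline
from mitemir.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """Generator output under the default study conditions."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the default synthetic cohort."""
    return run_synthetic_pipeline(SimConfig(seed=1), n_perm=1000)
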