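import numpy as np
import pytest

from panscan.pipeline import RunConfig, run_pipeline
from panscan.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset under the default study conditions."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run on the default synthetic configuration."""
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(RunConfig(sim=SimConfig(seed=42), out_dir=out))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
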