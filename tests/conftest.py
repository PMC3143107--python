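import pytest
from hypothesis import settings

from stemsrna.pipeline import PipelineConfig, run_pipeline, simulate
from stemsrna.synthetic_data import SimConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Default synthetic dataset (seed 1) shared across the suite."""
    d = tmp_path_factory.mktemp("sim")
    data = simulate(SimConfig(seed=1), d)
    return d, data


@pytest.fixture(scope="session")
def pipeline_bundle(sim_dataset):
    """Full pipeline run (with tables written) on the default dataset."""
    d, data = sim_dataset
    cfg = PipelineConfig.from_data_dir(d, d / "out", seed=1)
    bundle = run_pipeline(cfg)
    return cfg, bundle, data
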