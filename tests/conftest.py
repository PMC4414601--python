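import pytest

from mirreg.pipeline import run_pipeline
from mirreg.simulate import SimulationConfig, bundle_config, simulate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic bundle shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths, truth = simulate_bundle(SimulationConfig(seed=1), outdir)
    return paths, truth


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """A full pipeline run on the shared bundle."""
    paths, truth = bundle
    outdir = tmp_path_factory.mktemp("run")
    result = run_pipeline(bundle_config(paths), outdir, seed=1)
    return result, truth
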