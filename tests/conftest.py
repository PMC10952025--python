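import numpy as np
import pytest

from cernapipe import PipelineConfig, SimConfig, generate_bundle, run_pipeline


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study bundle (n=300 samples, seed 1)."""
    return generate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("pipeline_run")


@pytest.fixture(scope="session")
def pipeline_results(bundle, run_dir):
    """One full pipeline run on the default bundle, shared across tests."""
    return run_pipeline(bundle, PipelineConfig(seed=1), run_dir)


def small_config(seed: int, **overrides) -> SimConfig:
    """A scaled-down config for replicate simulations in tests."""
    defaults = dict(
        n_samples=120,
        n_mrna=120,
        n_lncrna=60,
        n_mirna=40,
        background_lnc_mir=40,
        background_mir_mrna=80,
        validation_n=60,
        n_random_gene_sets=10,
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
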