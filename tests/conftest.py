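import numpy as np
import pytest

from thermorqa.simulate import SimulationConfig, make_fixture_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A cohort small enough for end-to-end tests to stay fast."""
    return SimulationConfig(n_subjects=5, series_length=600, seed=7)


@pytest.fixture(scope="session")
def fixture_cohort(tmp_path_factory, small_cfg):
    """A complete miniature study on disk (manifest, series, hormones)."""
    outdir = tmp_path_factory.mktemp("cohort")
    paths = make_fixture_cohort(small_cfg.seed, outdir, small_cfg)
    return paths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
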