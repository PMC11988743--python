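import pandas as pd
import pytest

from editlens.simulate import SimulationConfig, simulate_study, write_study


@pytest.fixture(scope="session")
def small_study():
    """A compact study reused by read-only tests."""
    return simulate_study(SimulationConfig(n_genes=60, seed=7))


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory, small_study):
    d = tmp_path_factory.mktemp("study")
    paths = write_study(small_study, str(d))
    return paths


@pytest.fixture(scope="session")
def small_design(small_study) -> pd.Series:
    g = small_study.config.sample_group()
    return pd.Series(g).reindex(small_study.config.samples)
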