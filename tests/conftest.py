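import pandas as pd
import pytest

from peckorder.synth import SynthConfig, generate_all, make_profiles


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    return SynthConfig(seed=0)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Scaled-down study for fast end-to-end tests."""
    return SynthConfig(seed=0, n_taxa=80, depth_mean=4000, days=7)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_all(small_cfg)


@pytest.fixture(scope="session")
def profiles(default_cfg):
    return make_profiles(default_cfg)


@pytest.fixture
def hrlr_groups() -> pd.Series:
    return pd.Series(["HR"] * 8 + ["LR"] * 8,
                     index=[f"h{i:02d}" for i in range(16)], name="group")
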