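import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from icesink import synthetic as syn  # noqa: E402


@pytest.fixture(scope="session")
def wide_domain():
    """Coarse domain wide enough for long zonal drifts at high latitude."""
    return syn.DomainConfig(lon_min=-40.0, lon_max=40.0, lon_step=2.0,
                            lat_min=74.0, lat_max=84.0, lat_step=1.0,
                            depth_step=250.0, t_step=10.0)


@pytest.fixture(scope="session")
def still_ocean(wide_domain):
    return syn.make_uniform_field(domain=wide_domain)


@pytest.fixture(scope="session")
def default_suite():
    """One shared community suite with the default study conditions."""
    cfg = syn.SyntheticConfig(seed=11)
    return syn.make_community_suite(cfg)


def two_source_gamma():
    """Mixing matrix where the surface PA sink is a 60/40 blend of the
    surface and epipelagic FL sources with no unknown component."""
    return pd.DataFrame(
        [[0.6, 0.4, 0.0, 0.0, 0.0],
         [0.0, 1.0, 0.0, 0.0, 0.0],
         [0.0, 0.0, 1.0, 0.0, 0.0],
         [0.0, 0.0, 0.0, 1.0, 0.0]],
        index=list(syn.LAYERS), columns=list(syn.LAYERS) + ["Unknown"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
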