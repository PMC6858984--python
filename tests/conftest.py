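"""Shared fixtures: one session-scoped default synthetic survey.

The default park (seed 0) is expensive enough to share; tests must not
mutate it.
"""

import numpy as np
import pytest

from socmap.synthetic import (
    SurveyConfig,
    generate_park,
    recover_variogram,
    sample_survey,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SurveyConfig(seed=0)


@pytest.fixture(scope="session")
def default_park(default_cfg):
    return generate_park(default_cfg)


@pytest.fixture(scope="session")
def default_sites(default_park, default_cfg):
    return sample_survey(default_park, default_cfg)


@pytest.fixture(scope="session")
def default_vm(default_sites, default_cfg):
    """Variogram refitted from the default survey's residuals."""
    return recover_variogram(default_sites, default_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
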