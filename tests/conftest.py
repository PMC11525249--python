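import numpy as np
import pytest

from mnrm.estimate import FitOptions, fit
from mnrm.fixtures import fixture_generator


@pytest.fixture(scope="session")
def gpcm_bundle():
    """200 persons x 6 items, one latent trait (a GPCM)."""
    return fixture_generator("tiny_gpcm", seed=3)


@pytest.fixture(scope="session")
def two_dim_bundle():
    """1000 persons x 6 items, one trait plus a faking dimension."""
    return fixture_generator("two_dim_faking", seed=7)


@pytest.fixture(scope="session")
def rating_histograms():
    return fixture_generator("rating_histograms", seed=11)


@pytest.fixture(scope="session")
def anova_table():
    return fixture_generator("anova_fixture", seed=5)


@pytest.fixture(scope="session")
def gpcm_em_fit(gpcm_bundle):
    """Quadrature-EM fit of the GPCM fixture, shared across tests."""
    spec, items, latent, persons, responses = gpcm_bundle
    result = fit(
        responses,
        spec,
        [it.scoring_weights for it in items],
        FitOptions(algorithm="em_quadrature", seed=0),
    )
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
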