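"""Shared fixtures for the routegp test suite."""

import pytest

from routegp import (
    FlightSet,
    HyperPrior,
    Hyperparams,
    MaternParams,
    SimConfig,
    SiteGeometry,
    default_hyper,
    default_site,
    sample_flights,
)


@pytest.fixture
def site() -> SiteGeometry:
    return default_site()


@pytest.fixture
def hyper() -> Hyperparams:
    return default_hyper()


@pytest.fixture
def small_hyper() -> Hyperparams:
    """Hyperparameters on a small, well-conditioned scale for toy problems."""
    return Hyperparams(
        flight=MaternParams(2.0, 0.3),
        habitual=MaternParams(3.0, 0.4),
        noise_std=0.5,
    )


@pytest.fixture
def flights(site, hyper) -> FlightSet:
    """Four shared-route flights on a 30-point grid."""
    cfg = SimConfig(site=site, hyper=hyper, n_flights=4, grid_size=30, seed=7)
    return sample_flights(cfg)


@pytest.fixture
def prior(site) -> HyperPrior:
    return HyperPrior.default(site.beeline_length)
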