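"""Shared fixtures: synthetic worlds are expensive enough to build once."""

import pytest

from ch4iso.signatures import build_sector_signature_draws
from ch4iso.synthetic import TruthConfig, generate_world, make_scenario_catalogue


@pytest.fixture(scope="session")
def nf_world():
    """Noise-free synthetic world (zero IAV, zero observation noise)."""
    return generate_world(TruthConfig(seed=11).noise_free())


@pytest.fixture(scope="session")
def nf_draws(nf_world):
    """Single unperturbed signature draw for the noise-free world."""
    return build_sector_signature_draws(nf_world.signature_specs(), 1, 11,
                                        sigma_scale=0.0)


@pytest.fixture(scope="session")
def noisy_world():
    """Default synthetic world with IAV and observation noise on."""
    return generate_world(TruthConfig(seed=7))


@pytest.fixture(scope="session")
def noisy_draws(noisy_world):
    return build_sector_signature_draws(noisy_world.signature_specs(), 4, 7)


@pytest.fixture(scope="session")
def nf_catalogue(nf_world):
    """Full 96-scenario catalogue around the noise-free truth."""
    return make_scenario_catalogue(nf_world)
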