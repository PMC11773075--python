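import numpy as np
import pytest

from fishbioecon import SPECIES, simulate_fishery, make_effort_path, SimulationConfig


@pytest.fixture(scope="session")
def mackerel():
    """Indian mackerel preset: the best-documented of the four stocks."""
    return SPECIES["R_kanagurta"]


@pytest.fixture(scope="session")
def mackerel_bio(mackerel):
    return mackerel.params


@pytest.fixture(scope="session")
def mackerel_econ(mackerel):
    return mackerel.econ


@pytest.fixture(scope="session")
def all_presets():
    return list(SPECIES.values())


@pytest.fixture(scope="session")
def noise_free_series(mackerel_bio):
    """Contrast-rich, observation-error-free series at known truth."""
    depletion = 0.4
    path = make_effort_path(
        31, "one_way_trip", 0.3 * mackerel_bio.e_msy, 1.2 * mackerel_bio.e_msy, seed=11
    )
    cfg = SimulationConfig(
        true_params=mackerel_bio, initial_depletion=depletion, obs_sigma=0.0, seed=11
    )
    return simulate_fishery(cfg, path), depletion


def random_parameter_draw(rng):
    """One plausible (K, r, q, p, c) draw with an interior MEY (theta < 1)."""
    K = 10 ** rng.uniform(3, 7)
    r = rng.uniform(0.05, 1.5)
    q = 10 ** rng.uniform(-7, -3)
    price = 10 ** rng.uniform(2, 5)
    theta = rng.uniform(0.01, 0.95)
    c = theta * price * q * K
    return K, r, q, price, c
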