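import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import minipbpk as mp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pnd_spec():
    """Pyronaridine single-analyte model with the tabulated hamster
    physiology and fitted disposition parameters."""
    spec, _, _ = mp.load_config(mp.builtin_config_path("pyronaridine"))
    return spec


@pytest.fixture(scope="session")
def pnd_regimens():
    _, regimens, _ = mp.load_config(mp.builtin_config_path("pyronaridine"))
    return {"low": regimens[0], "high": regimens[1]}


@pytest.fixture(scope="session")
def art_spec():
    """Artesunate/dihydroartemisinin parent-metabolite model."""
    spec, _, _ = mp.load_config(mp.builtin_config_path("artesunate"))
    return spec


@pytest.fixture(scope="session")
def art_regimens():
    _, regimens, _ = mp.load_config(mp.builtin_config_path("artesunate"))
    return {"low": regimens[0], "high": regimens[1]}


@pytest.fixture(scope="session")
def art_single_dose(art_spec):
    """Single low-dose artesunate simulation through full elimination."""
    regimen = mp.DoseRegimen(dose_per_kg=60.0, body_weight=0.10201,
                             n_doses=1, interval_tau=24.0)
    return mp.simulate_regimen(art_spec, regimen, t_end=72.0)


@pytest.fixture(scope="session")
def pnd_14day(pnd_spec):
    """Fourteen daily low doses of pyronaridine (steady-state regime)."""
    regimen = mp.DoseRegimen(dose_per_kg=180.0, body_weight=0.10201,
                             n_doses=14, interval_tau=24.0)
    return mp.simulate_regimen(pnd_spec, regimen)


def random_state(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random nonnegative state spanning several orders of magnitude."""
    return 10.0 ** rng.uniform(-3, 6, n)
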