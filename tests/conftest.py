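import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aztreonam_pbpk as az

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compound():
    return az.load_compound()


@pytest.fixture(scope="session")
def rat_physiology():
    return az.load_physiology("rat")


@pytest.fixture(scope="session")
def rat_model():
    """Rat 50 mg/kg IV bolus with the calibrated clearance split."""
    return az.PBPKModel.for_species("rat", dose_mg_per_kg=50)


@pytest.fixture(scope="session")
def human_model():
    """Human 500 mg given as a 2-minute IV infusion."""
    return az.PBPKModel.for_species(
        "human",
        dose_mg=500,
        route="iv_infusion",
        infusion_duration_h=2.0 / 60.0,
    )


@pytest.fixture(scope="session")
def rat_sim(rat_model):
    return az.simulate(rat_model, t_end=24.0, output_resolution=0.005)


@pytest.fixture(scope="session")
def human_sim(human_model):
    return az.simulate(human_model, t_end=48.0, output_resolution=0.005)


@pytest.fixture(scope="session")
def rat_dense_profile(rat_model, rat_sim):
    return az.ConcentrationTimeProfile(
        time=rat_sim.time,
        concentration=rat_sim.plasma,
        dose=rat_model.regimen.dose,
        species="rat",
    )


def mono_exponential_profile(c0=100.0, k=0.5, t_end=24.0, n=481, dose=None):
    t = np.linspace(0.0, t_end, n)
    return az.ConcentrationTimeProfile(
        time=t, concentration=c0 * np.exp(-k * t), dose=dose
    )
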