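import numpy as np
import pytest

from algrow.model import GrowthParameters
from algrow.reactor import pilot_reactor
from algrow.synthetic import CampaignSpec, generate_campaign, reference_parameters


@pytest.fixture(scope="session")
def params():
    """Fitted reference growth parameters (with jackknife sigmas)."""
    return reference_parameters()


@pytest.fixture(scope="session")
def geometry():
    """The bundled 30 L pilot-scale reactor geometry."""
    return pilot_reactor()


@pytest.fixture(scope="session")
def identifiable_spec():
    """Small noise-free campaign whose temperature set-points span the
    growth range well enough to identify all three cardinal temperatures.

    The forward model uses the same fixed-step Euler discretization as the
    estimator replay, so the noise-free objective is exactly zero at the
    generating parameters.
    """
    return CampaignSpec(
        n_experiments=5,
        c_X0=(0.5, 0.8, 0.4, 0.6, 0.9),
        t_cyc=(2.0, 3.0, 2.5, 3.0, 2.0),
        T_set=(8.0, 16.0, 24.0, 28.0, 31.0),
        sampling_interval_min=60.0,
        sigma_od=0.0,
        sigma_dw=0.0,
        integrator="euler",
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_campaign():
    """Four-experiment campaign with realistic sensor noise."""
    spec = CampaignSpec(
        n_experiments=4,
        c_X0=(0.5, 0.8, 0.4, 0.6),
        t_cyc=(2.0, 3.0, 2.5, 3.0),
        T_set=(20.0, 22.0, 24.0, 31.0),
        sampling_interval_min=60.0,
        sigma_od=0.005,
        sigma_dw=0.01,
        seed=2,
    )
    return spec, generate_campaign(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
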