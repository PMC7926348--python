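import numpy as np
import pytest

from porestat import BathState, EnergyParams, PoreGeometry, SiteParams


@pytest.fixture
def fitted_params():
    """The canonical fitted parameter set used throughout the examples."""
    return EnergyParams(Uc=10.0, nf=-2.5), SiteParams(dmu=(2.3, 3.4, 2.8, 2.4))


@pytest.fixture
def geometry():
    return PoreGeometry()


@pytest.fixture
def bath_014():
    return BathState(0.14)


@pytest.fixture
def bath_05():
    return BathState(0.5)


def random_parameter_draw(rng: np.random.Generator):
    """A physically plausible random parameter set for property tests."""
    ep = EnergyParams(
        Uc=float(rng.uniform(0.5, 20.0)),
        nf=float(rng.uniform(-4.0, 0.0)),
    )
    sp = SiteParams(
        dmu=tuple(rng.uniform(0.0, 6.0, size=4)),
        D=tuple(rng.uniform(1e-11, 1e-9, size=4)),
    )
    bath = BathState(float(rng.uniform(0.01, 2.0)))
    return ep, sp, bath
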