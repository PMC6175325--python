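import numpy as np
import pytest

from rheowave.poroelastic import BiotParams
from rheowave.viscoelastic import ZenerParams


@pytest.fixture
def zener_unit() -> ZenerParams:
    """The canonical (E_e=1 Pa, tau_eps=2 s, tau_sig=1 s) Zener solid."""
    return ZenerParams(1.0, 2.0, 1.0)


@pytest.fixture
def biot_baseline() -> BiotParams:
    """Soft water-saturated frame: phi=0.5, tortuosity=1.25, mu_r=5 kPa."""
    return BiotParams(
        porosity=0.5,
        solid_density=2650.0,
        fluid_density=1000.0,
        solid_bulk=3.6e10,
        fluid_bulk=2.2e9,
        fluid_viscosity=1.0e-3,
        permeability=1.0e-11,
        tortuosity=1.25,
        frame_bulk=1.0e5,
        frame_shear=5.0e3,
    )


def random_biot(rng: np.random.Generator) -> BiotParams:
    """A physically valid random Biot medium (log-uniform where appropriate)."""
    return BiotParams(
        porosity=rng.uniform(0.2, 0.8),
        solid_density=rng.uniform(1200.0, 3000.0),
        fluid_density=rng.uniform(700.0, 1300.0),
        solid_bulk=10.0 ** rng.uniform(8.0, 11.0),
        fluid_bulk=10.0 ** rng.uniform(8.0, 10.0),
        fluid_viscosity=10.0 ** rng.uniform(-4.0, -2.0),
        permeability=10.0 ** rng.uniform(-13.0, -9.0),
        tortuosity=rng.uniform(1.0, 3.0),
        frame_bulk=10.0 ** rng.uniform(4.0, 7.0),
        frame_shear=10.0 ** rng.uniform(3.0, 7.0),
    )
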