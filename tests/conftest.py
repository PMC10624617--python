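"""Shared fixtures.

Expensive artefacts (toy crystal, quantum propagations) are session-scoped
so the suite builds them once.
"""

import numpy as np
import pytest

from pdpxtal.quantum import (
    DissipationModel,
    Pulse,
    VibronicSystem,
    ground_state,
    propagate,
)
from pdpxtal.synth import ToyCrystalSpec, make_toy_crystal


@pytest.fixture(scope="session")
def small_system():
    return VibronicSystem(mode_frequency=120.0, displacement=1.0, n_vib=8,
                          temperature=0.0)


@pytest.fixture(scope="session")
def pumped_states(small_system):
    """States of a short resonant-pump propagation with dissipation."""
    pump = Pulse(center_time=0.0, fwhm=60.0, peak_rabi_energy=0.01)
    dissipation = DissipationModel(s1_lifetime=50.0, vib_dephasing_time=1.0,
                                   elec_dephasing_time=50.0)
    return propagate(small_system, [pump], dissipation, (-150.0, 400.0),
                     dt=25.0, initial="ground")


@pytest.fixture(scope="session")
def toy_crystal():
    """Default 200-atom toy crystal, noise-free, f = 0.2."""
    return make_toy_crystal(ToyCrystalSpec(population_fraction=0.2, seed=1))


@pytest.fixture(scope="session")
def mini_toy_crystal():
    """A seconds-scale toy crystal for map/scaling/qweight unit tests."""
    from pdpxtal.xtal.types import UnitCellSymmetry

    spec = ToyCrystalSpec(cell=UnitCellSymmetry(24.0, 26.0, 28.0),
                          n_atoms=12, n_moved_atoms=2, d_min=1.5,
                          b_iso=8.0, cluster_scale=3.0,
                          population_fraction=0.3, seed=3)
    return make_toy_crystal(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
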