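import numpy as np
import pytest

from magnetolb import geometry as geo
from magnetolb.units import FluidProperties, UnitSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def blood():
    return FluidProperties()


@pytest.fixture
def paper_units(blood):
    """Lattice scaling at the headline resolution: 25 um, 0.63 m/s peak."""
    return UnitSystem.from_physical(25e-6, blood, u_phys_max=0.63)


@pytest.fixture(scope="session")
def small_cylinder():
    """Open-ended tube, R = 6 dx, for boundary/particle tests."""
    dom = geo.voxelize_cylinder(
        radius=6.3 * 25e-6, length=20 * 25e-6, axis=2, spacing=25e-6
    )
    geo.compute_wall_links(dom)
    return dom


@pytest.fixture(scope="session")
def periodic_cylinder():
    """Axially periodic tube (lattice units) for body-force-driven flow."""
    dom = geo.voxelize_cylinder(
        radius=6.3, length=1.0, axis=2, spacing=1.0, open_ends=False
    )
    geo.compute_wall_links(dom)
    return dom
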