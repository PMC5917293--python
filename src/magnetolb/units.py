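"""Physical <-> lattice unit scaling, relaxation-time parametrization and stability checks.

The lattice-Boltzmann solver works in lattice units in which the grid spacing,
the time step and a reference mass are all unity.  Three scale factors

* ``delta_x`` — lattice spacing [m]
* ``delta_t`` — time step [s]
* ``delta_m`` — lattice mass [kg]

non-dimensionalise every physical quantity.  Derived scales follow by
dimensional analysis, e.g. velocity ``delta_x/delta_t`` and energy
``delta_m * delta_x**2 / delta_t**2``.

The D3Q19 lattice speed of sound satisfies ``c_s**2 = 1/3`` (in lattice
units).  A low-Mach constraint caps the peak lattice velocity at ``c_s/30``
(~0.02); together with the fluid viscosity this fixes the admissible time
step and the BGK relaxation time ``tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CS2",
    "CS",
    "MMHG_PA",
    "FluidProperties",
    "UnitSystem",
    "StabilityReport",
    "lattice_viscosity",
    "relaxation_time",
    "max_lattice_velocity",
    "max_timestep",
    "check_stability",
    "convert",
    "mmhg_to_pa",
]

#: Lattice speed of sound squared for D3Q19 (lattice units).
CS2 = 1.0 / 3.0
#: Lattice speed of sound.
CS = math.sqrt(CS2)
#: Conventional conversion factor, Pa per mmHg.
MMHG_PA = 133.322

#: Boltzmann constant [J/K].
K_B = 1.380649e-23

#: Vacuum magnetic permeability [H/m].
MU0 = 4.0e-7 * math.pi


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid parameters of blood treated as a Newtonian liquid.

    Parameters
    ----------
    mu : float
        Dynamic viscosity [Pa s].  Default 0.004 (whole blood at a
        characteristic shear rate).
    rho : float
        Mass density [kg/m^3].  Default 1000.
    temperature : float
        Absolute temperature [K].  Default 310.15 (37 C); only enters the
        Brownian noise amplitude — the flow model itself is athermal.
    """

    mu: float = 0.004
    rho: float = 1000.0
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0 or self.temperature <= 0:
            raise ValueError("fluid properties must be strictly positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity [m^2/s]."""
        return self.mu / self.rho


@dataclass(frozen=True)
class UnitSystem:
    """Scale factors between physical and lattice units.

    ``to_lattice(q, kind)`` divides by the scale of that quantity kind and
    ``to_physical`` multiplies, so the round trip is an exact identity up to
    floating point.
    """

    delta_x: float
    delta_t: float
    delta_m: float

    def __post_init__(self) -> None:
        if self.delta_x <= 0 or self.delta_t <= 0 or self.delta_m <= 0:
            raise ValueError("unit scales must be strictly positive")

    # -- derived scales ----------------------------------------------------
    @property
    def velocity_scale(self) -> float:
        return self.delta_x / self.delta_t

    @property
    def acceleration_scale(self) -> float:
        return self.delta_x / self.delta_t**2

    @property
    def force_scale(self) -> float:
        return self.delta_m * self.delta_x / self.delta_t**2

    @property
    def energy_scale(self) -> float:
        # delta_m * delta_x^2 * delta_t^-2
        return self.delta_m * self.delta_x**2 / self.delta_t**2

    @property
    def pressure_scale(self) -> float:
        return self.delta_m / (self.delta_x * self.delta_t**2)

    @property
    def density_scale(self) -> float:
        return self.delta_m / self.delta_x**3

    def scale(self, kind: str) -> float:
        """Physical size of one lattice unit of the given quantity ``kind``."""
        try:
            return _SCALES[kind](self)
        except KeyError:
            raise ValueError(f"unknown quantity kind: {kind!r}") from None

    def to_lattice(self, value, kind: str):
        return value / self.scale(kind)

    def to_physical(self, value, kind: str):
        return value * self.scale(kind)

    @classmethod
    def from_physical(
        cls,
        delta_x: float,
        props: FluidProperties,
        *,
        delta_t: float | None = None,
        u_phys_max: float | None = None,
    ) -> "UnitSystem":
        """Build a unit system from the lattice spacing and fluid properties.

        Either an explicit ``delta_t`` or the peak physical velocity
        ``u_phys_max`` (from which the largest stable time step is derived)
        must be supplied.  ``delta_m`` is set to ``rho * delta_x**3`` so that
        a lattice density of 1 corresponds to the physical fluid density.
        """
        if delta_t is None:
            if u_phys_max is None:
                raise ValueError("need delta_t or u_phys_max")
            delta_t = max_timestep(delta_x, u_phys_max)
        return cls(delta_x=delta_x, delta_t=delta_t, delta_m=props.rho * delta_x**3)


_SCALES = {
    "length": lambda u: u.delta_x,
    "time": lambda u: u.delta_t,
    "mass": lambda u: u.delta_m,
    "velocity": lambda u: u.velocity_scale,
    "acceleration": lambda u: u.acceleration_scale,
    "force": lambda u: u.force_scale,
    "energy": lambda u: u.energy_scale,
    "pressure": lambda u: u.pressure_scale,
    "density": lambda u: u.density_scale,
}


def lattice_viscosity(props: FluidProperties, units: UnitSystem) -> float:
    """Kinematic viscosity in lattice units: ``(mu/rho) * delta_t / delta_x**2``."""
    return props.nu * units.delta_t / units.delta_x**2


def relaxation_time(nu_lat: float) -> float:
    """BGK relaxation time from the lattice viscosity.

    nu = c_s^2 (tau - 1/2) with c_s^2 = 1/3 and unit time step, so
    tau = 3 nu + 1/2.  tau -> 1/2 is the inviscid limit.
    """
    if nu_lat < 0:
        raise ValueError("lattice viscosity must be non-negative")
    return 3.0 * nu_lat + 0.5


def max_lattice_velocity() -> float:
    """Largest admissible lattice velocity, ``c_s/30`` (~0.0192, often quoted ~0.02).

    The low-Mach constraint is read as u/c_s < 1/30; with c_s = 1/sqrt(3)
    this gives the ~0.02 cap used to size the time step.
    """
    return CS / 30.0


def max_timestep(delta_x: float, u_phys_max: float) -> float:
    """Largest time step [s] keeping the peak lattice velocity within the cap.

    ``u_phys_max * delta_t / delta_x <= max_lattice_velocity()`` solved for
    ``delta_t``.
    """
    if delta_x <= 0 or u_phys_max <= 0:
        raise ValueError("delta_x and u_phys_max must be positive")
    return max_lattice_velocity() * delta_x / u_phys_max


@dataclass(frozen=True)
class StabilityReport:
    ok: bool
    violations: tuple[str, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def check_stability(tau: float, u_lat_peak: float) -> StabilityReport:
    """Check the BGK stability conditions: ``tau > 1/2`` and the Mach cap."""
    violations = []
    if tau <= 0.5:
        violations.append(
            f"relaxation time tau={tau:g} <= 0.5 (inviscid-flow limit): "
            "viscosity too small for stable BGK collision"
        )
    cap = max_lattice_velocity()
    if u_lat_peak > cap:
        violations.append(
            f"peak lattice velocity {u_lat_peak:g} exceeds the Mach cap "
            f"{cap:.4g} (u/c_s < 1/30)"
        )
    return StabilityReport(ok=not violations, violations=tuple(violations))


def convert(value, kind: str, direction: str, units: UnitSystem):
    """Convert ``value`` of quantity ``kind`` ``to_lattice`` or ``to_physical``."""
    if direction == "to_lattice":
        return units.to_lattice(value, kind)
    if direction == "to_physical":
        return units.to_physical(value, kind)
    raise ValueError(f"unknown direction: {direction!r}")


def mmhg_to_pa(p: float) -> float:
    """Pressure conversion, mmHg to Pa (1 mmHg = 133.322 Pa)."""
    return p * MMHG_PA
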