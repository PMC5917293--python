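"""Overdamped dynamics of paramagnetic nanoparticles in blood flow.

Particles are point-like (radius orders of magnitude below the lattice
spacing) and inertialess: Stokes drag balances the other forces
instantaneously, so the particle velocity is

    u_p = v(x_p) + beta (F + F_R),      beta = 1 / (6 pi mu (a + a_c))

with ``v`` the fluid velocity interpolated at the particle position, ``F``
the sum of the enabled deterministic forces (gravity/buoyancy, magnet
attraction, inter-particle dipolar forces, wall and pair lubrication) and
``F_R`` Gaussian Brownian noise scaled by fluctuation-dissipation.  The
magnetic core radius ``a`` alone sets the induced moment; a drug-carrying
coating of thickness ``a_c`` adds drag but no magnetisation.

Positions are integrated with explicit (Euler-Maruyama) steps; optional
sub-stepping caps the displacement per sub-step for stiff near-wall or
near-magnet configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    OUTLET,
    SOLID,
    VoxelDomain,
    nearest_wall_vector,
)
from .units import FluidProperties, K_B, MU0

__all__ = [
    "Magnet",
    "ForceParams",
    "ParticleSystem",
    "mobility",
    "dipole_field",
    "induced_moment",
    "pair_dipole_force",
    "magnet_particle_force",
    "wall_lubrication",
    "pair_lubrication",
    "maude_force",
    "gravity_buoyancy",
    "brownian_force",
    "interpolate_velocity",
    "compute_forces",
    "advance_particles",
    "drag_dominance",
    "spread_reaction_force",
]


@dataclass(frozen=True)
class Magnet:
    """Permanent magnet idealised as a point dipole."""

    position: np.ndarray   # m
    moment: np.ndarray     # A m^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))


@dataclass
class ForceParams:
    """Force-model configuration.

    Lubrication cutoffs ``h_e_wall`` / ``h_e_pair`` [m] bound the range of
    the short-range viscous repulsion; ``None`` means "one core radius",
    resolved per batch.  Individual force models can be switched off when
    negligible for a configuration.
    """

    gravity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m/s^2
    h_e_wall: float | None = None
    h_e_pair: float | None = None
    temperature: float = 310.15          # K
    mu0: float = MU0                     # H/m, fixed
    pair_cutoff_factor: float = 10.0     # dipolar pair forces beyond 10 a ignored
    enable_gravity: bool = True
    enable_magnetic: bool = True
    enable_pair_magnetic: bool = True
    enable_wall_lubrication: bool = True
    enable_pair_lubrication: bool = True
    enable_brownian: bool = True
    coupling: str = "one-way"            # "one-way" | "two-way"

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float)
        for name in ("h_e_wall", "h_e_pair"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ParticleSystem:
    """Arrays of particle state (positions and velocities are physical, SI)."""

    x: np.ndarray                   # (N, 3) m
    u: np.ndarray                   # (N, 3) m/s
    a: np.ndarray                   # (N,) core radius m
    a_c: np.ndarray                 # (N,) coating thickness m
    chi_v: np.ndarray               # (N,) volumetric susceptibility
    rho_p: np.ndarray               # (N,) material density kg/m^3
    ids: np.ndarray = None          # (N,) int labels

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        n = len(self.x)
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        for name in ("a", "a_c", "chi_v", "rho_p"):
            v = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (n,)
            ).copy()
            setattr(self, name, v)
        if np.any(self.a <= 0) or np.any(self.a_c < 0):
            raise ValueError("need a > 0 and a_c >= 0")
        if self.ids is None:
            self.ids = np.arange(n)

    @classmethod
    def monodisperse(
        cls,
        positions: np.ndarray,
        a: float,
        a_c: float = 0.0,
        chi_v: float = 5.7,
        rho_p: float = 5170.0,
    ) -> "ParticleSystem":
        """Identical particles at the given positions, initially at rest.

        Defaults are a pure-magnetite core (density 5170 kg/m^3) at the top
        of the reported susceptibility range (chi_v = 5.7, dimensionless).
        """
        positions = np.atleast_2d(positions)
        n = len(positions)
        return cls(
            x=positions.copy(),
            u=np.zeros((n, 3)),
            a=np.full(n, a),
            a_c=np.full(n, a_c),
            chi_v=np.full(n, chi_v),
            rho_p=np.full(n, rho_p),
        )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def a_total(self) -> np.ndarray:
        """Hydrodynamic radius a + a_c."""
        return self.a + self.a_c

    def remove(self, mask: np.ndarray) -> "ParticleSystem":
        """Return a new system without the masked particles."""
        keep = ~np.asarray(mask, dtype=bool)
        return ParticleSystem(
            x=self.x[keep], u=self.u[keep], a=self.a[keep], a_c=self.a_c[keep],
            chi_v=self.chi_v[keep], rho_p=self.rho_p[keep], ids=self.ids[keep],
        )


def mobility(a_total: np.ndarray, mu: float) -> np.ndarray:
    """Stokes mobility beta = 1/(6 pi mu a_total) [s/kg]."""
    return 1.0 / (6.0 * math.pi * mu * a_total)


def magnet_standoff(
    a: float, chi_v: float, moment: float, u_drift: float, mu: float,
    a_total: float | None = None,
) -> float:
    """Magnet distance [m] at which the on-axis magnetic drift is ``u_drift``.

    On the dipole axis the magnet-particle force is
    mu0 a^3 chi_v m0^2 / (pi d^7), so the overdamped drift
    beta F crosses a chosen velocity at

        d = [ mu0 a^3 chi_v m0^2 / (6 pi^2 mu a_total u_drift) ]^(1/7).

    Used to place the demo and sweep magnets so the magnetic forcing is a
    stated fraction of the flow speed rather than an absolute position —
    the drift falls off as d^-7, making absolute placement fragile.
    """
    if a_total is None:
        a_total = a
    return (
        MU0 * a**3 * chi_v * moment**2
        / (6.0 * math.pi**2 * mu * a_total * u_drift)
    ) ** (1.0 / 7.0)


# --------------------------------------------------------------------------
# Magnetic forces
# --------------------------------------------------------------------------
def dipole_field(magnet: Magnet, x: np.ndarray) -> np.ndarray:
    """Magnetic field H [A/m] of a point dipole at position(s) ``x``.

    H = (1/4 pi) [ 3 (m0 . r0) r0 / r^5 - m0 / r^3 ],  r0 from magnet to x.
    """
    x = np.asarray(x, dtype=float)
    r0 = x - magnet.position
    r2 = np.sum(r0 * r0, axis=-1)
    if np.any(r2 == 0):
        raise ValueError("field requested at the magnet position")
    r = np.sqrt(r2)
    mdotr = np.tensordot(r0, magnet.moment, axes=([-1], [0]))
    return (
        3.0 * mdotr[..., None] * r0 / r[..., None] ** 5
        - magnet.moment / r[..., None] ** 3
    ) / (4.0 * math.pi)


def induced_moment(a, chi_v, H: np.ndarray) -> np.ndarray:
    """Induced dipole moment m = (4 pi a^3 chi_v / 3) H [A m^2].

    Only the magnetic core radius ``a`` enters — the coating is
    non-magnetic.  The moment aligns instantaneously with the local field
    (rotation is fast relative to hydrodynamic time scales).
    """
    a = np.asarray(a, dtype=float)
    chi_v = np.asarray(chi_v, dtype=float)
    return (4.0 * math.pi / 3.0) * (a**3 * chi_v)[..., None] * np.asarray(H, float)


def pair_dipole_force(
    m_i: np.ndarray, x_i: np.ndarray, m_j: np.ndarray, x_j: np.ndarray,
    mu0: float = MU0,
) -> np.ndarray:
    """Force [N] on dipole i due to dipole j (point-dipole interaction).

    F = 3 mu0 / (4 pi r^5) [ (m_i.r) m_j + (m_j.r) m_i + (m_i.m_j) r
                             - 5 (m_i.r)(m_j.r) r / r^2 ],   r = x_i - x_j.

    Antisymmetric under i <-> j (Newton's third law); attractive for equal
    moments along the connecting line, repulsive (half the magnitude) for
    moments perpendicular to it.
    """
    m_i = np.asarray(m_i, float)
    m_j = np.asarray(m_j, float)
    r = np.asarray(x_i, float) - np.asarray(x_j, float)
    r2 = np.sum(r * r, axis=-1)
    if np.any(r2 == 0):
        raise ValueError("coincident dipoles")
    rmag = np.sqrt(r2)
    mir = np.sum(m_i * r, axis=-1)
    mjr = np.sum(m_j * r, axis=-1)
    mimj = np.sum(m_i * m_j, axis=-1)
    pref = 3.0 * mu0 / (4.0 * math.pi * rmag**5)
    bracket = (
        mir[..., None] * m_j
        + mjr[..., None] * m_i
        + mimj[..., None] * r
        - 5.0 * (mir * mjr / r2)[..., None] * r
    )
    return pref[..., None] * bracket


def magnet_particle_force(
    magnet: Magnet, x_p: np.ndarray, a, chi_v, mu0: float = MU0
) -> np.ndarray:
    """Force [N] of the permanent magnet on induced particle dipole(s).

    Composes the dipole field, the induced moment and the pair-dipole law;
    magnitude scales as r^-7 in magnet distance and a^3 in core radius.
    """
    H = dipole_field(magnet, x_p)
    m_i = induced_moment(a, chi_v, H)
    return pair_dipole_force(m_i, x_p, magnet.moment, magnet.position, mu0)


# --------------------------------------------------------------------------
# Lubrication
# --------------------------------------------------------------------------
def wall_lubrication(
    a, u_p: np.ndarray, r_w: np.ndarray, h_e: float, mu: float
) -> np.ndarray:
    """Short-range viscous wall force [N], active for h = |r_w| - a < h_e.

    F = -6 pi mu a^2 (u_p . rhat_w) [1/h - 1/h_e] rhat_w

    with rhat_w the unit particle-to-wall vector: the force opposes motion
    along the wall normal and diverges as the gap h closes.
    """
    a = np.asarray(a, dtype=float)
    u_p = np.atleast_2d(np.asarray(u_p, dtype=float))
    r_w = np.atleast_2d(np.asarray(r_w, dtype=float))
    d = np.linalg.norm(r_w, axis=-1)
    h = d - a
    if np.any(h <= 0):
        raise ValueError("wall penetration: |r_w| <= a")
    rhat = r_w / d[..., None]
    un = np.sum(u_p * rhat, axis=-1)
    mag = 6.0 * math.pi * mu * a**2 * un * (1.0 / h - 1.0 / h_e)
    mag = np.where(h < h_e, mag, 0.0)
    out = -mag[..., None] * rhat
    return out if np.asarray(u_p).ndim > 1 else out[0]


def pair_lubrication(
    a: float,
    u_i: np.ndarray, x_i: np.ndarray,
    u_j: np.ndarray, x_j: np.ndarray,
    h_e: float, mu: float,
) -> np.ndarray:
    """Lubrication force [N] on particle i from an identical particle j.

    F_i = -(6 pi / 4) mu a^2 (u_ij . rhat_ij) [1/h - 1/h_e] rhat_ij

    with u_ij = u_i - u_j, h = |r_ij| - 2a.  Repulsion diverges as the
    surface gap closes, preventing overlap; antisymmetric in i <-> j.
    """
    r = np.asarray(x_i, float) - np.asarray(x_j, float)
    d = np.linalg.norm(r, axis=-1)
    h = d - 2.0 * a
    if np.any(h <= 0):
        raise ValueError("particle overlap: |r_ij| <= 2a")
    rhat = r / d[..., None]
    urel = np.asarray(u_i, float) - np.asarray(u_j, float)
    un = np.sum(urel * rhat, axis=-1)
    mag = (6.0 * math.pi / 4.0) * mu * a**2 * un * (1.0 / h - 1.0 / h_e)
    mag = np.where(h < h_e, mag, 0.0)
    return -mag[..., None] * rhat


def maude_force(a: float, h: np.ndarray, u: float, mu: float = 0.004) -> np.ndarray:
    """Analytic sphere-approaching-a-wall force, F = F_0 (9a/(8h) + 1).

    F_0 = 6 pi mu a u is the free-stream Stokes drag.  Validation reference
    only — the solver itself uses the cutoff lubrication model.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("separation must be positive")
    F0 = 6.0 * math.pi * mu * a * u
    return F0 * (9.0 * a / (8.0 * h) + 1.0)


# --------------------------------------------------------------------------
# Body and stochastic forces
# --------------------------------------------------------------------------
def gravity_buoyancy(
    a_total, rho_p, rho_fluid: float, g: np.ndarray
) -> np.ndarray:
    """Net weight minus buoyancy [N]: (rho_p - rho_f) (4/3) pi a_total^3 g."""
    a_total = np.asarray(a_total, dtype=float)
    rho_p = np.asarray(rho_p, dtype=float)
    vol = (4.0 / 3.0) * math.pi * a_total**3
    return ((rho_p - rho_fluid) * vol)[..., None] * np.asarray(g, dtype=float)


def brownian_force(
    a_total, mu: float, temperature: float, dt: float,
    rng: np.random.Generator, n: int | None = None,
) -> np.ndarray:
    """Fluctuation-dissipation Brownian force [N], one 3-vector per particle.

    Each component is an independent Gaussian of zero mean and standard
    deviation sqrt(2 k_B T / (beta dt)); with the overdamped Euler update
    this yields per-axis displacement variance 2 D dt, D = k_B T beta
    (Stokes-Einstein).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a_total = np.atleast_1d(np.asarray(a_total, dtype=float))
    if n is None:
        n = len(a_total)
    beta = mobility(a_total, mu)
    sigma = np.sqrt(2.0 * K_B * temperature / (beta * dt))
    return sigma[:, None] * rng.standard_normal((n, 3))


# --------------------------------------------------------------------------
# Fluid-particle coupling
# --------------------------------------------------------------------------
def _trilinear(domain: VoxelDomain, x_p: np.ndarray):
    """Indices and weights of the 8 surrounding site centers."""
    x_p = np.atleast_2d(np.asarray(x_p, dtype=float))
    s = (x_p - domain.origin) / domain.spacing - 0.5
    base = np.floor(s).astype(np.int64)
    t = s - base
    dims = np.asarray(domain.dims)
    idx = np.empty((len(x_p), 8, 3), dtype=np.int64)
    wts = np.empty((len(x_p), 8))
    corner = 0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                off = np.array([dx, dy, dz])
                idx[:, corner] = np.clip(base + off, 0, dims - 1)
                w = np.where(off == 1, t, 1.0 - t)
                wts[:, corner] = np.prod(w, axis=-1)
                corner += 1
    return idx, wts


def interpolate_velocity(
    u_field: np.ndarray, domain: VoxelDomain, x_p: np.ndarray
) -> np.ndarray:
    """Trilinear interpolation of the fluid velocity at particle position(s).

    Solid sites are excluded and the remaining weights renormalised, so the
    interpolant only samples flow sites.  ``u_field`` has shape
    (3, nx, ny, nz) in the caller's units; output matches.
    """
    x_arr = np.atleast_2d(np.asarray(x_p, dtype=float))
    if not np.all(domain.contains_fluid(x_arr)):
        raise ValueError("particle position outside the flow domain")
    idx, wts = _trilinear(domain, x_arr)
    flat = np.ravel_multi_index(
        (idx[..., 0], idx[..., 1], idx[..., 2]), domain.dims
    )
    flow = domain.flow_mask.ravel()[flat]
    wts = wts * flow
    tot = wts.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("no flow site among interpolation neighbours")
    wts = wts / tot
    uf = u_field.reshape(3, -1)
    out = np.einsum("pk,cpk->pc", wts, uf[:, flat])
    return out if np.asarray(x_p).ndim > 1 else out[0]


def spread_reaction_force(
    force_field: np.ndarray,
    domain: VoxelDomain,
    x_p: np.ndarray,
    reaction: np.ndarray,
) -> None:
    """Deposit per-particle reaction forces onto the 8 surrounding sites.

    Trilinear weights (summing to 1) distribute each force; the total
    momentum deposited per step equals the summed reaction impulse exactly.
    ``force_field`` (3, nx, ny, nz) is accumulated in place, in the same
    units as ``reaction``.
    """
    x_p = np.atleast_2d(np.asarray(x_p, dtype=float))
    reaction = np.atleast_2d(np.asarray(reaction, dtype=float))
    idx, wts = _trilinear(domain, x_p)
    flat = np.ravel_multi_index((idx[..., 0], idx[..., 1], idx[..., 2]), domain.dims)
    ff = force_field.reshape(3, -1)
    for c in range(3):
        np.add.at(ff[c], flat, wts * reaction[:, c][:, None])


# --------------------------------------------------------------------------
# Force accumulation and time stepping
# --------------------------------------------------------------------------
def compute_forces(
    system: ParticleSystem,
    params: ForceParams,
    props: FluidProperties,
    magnets: tuple[Magnet, ...] = (),
    domain: VoxelDomain | None = None,
    include_lubrication: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of enabled deterministic forces per particle.

    Returns ``(F_total, F_magnetic)`` [N]; the magnetic part is kept
    separately for trajectory output.  Lubrication (when included) uses
    the particles' current velocities; the integrator instead applies it
    semi-implicitly via :func:`_apply_lubrication_implicit`, since the
    force is linear in velocity and stiff as the gap closes.
    """
    n = len(system)
    F = np.zeros((n, 3))
    Fmag = np.zeros((n, 3))

    if params.enable_gravity and np.any(params.gravity != 0):
        F += gravity_buoyancy(system.a_total, system.rho_p, props.rho, params.gravity)

    moments = None
    if params.enable_magnetic and magnets:
        for magnet in magnets:
            H = dipole_field(magnet, system.x)
            m_i = induced_moment(system.a, system.chi_v, H)
            if moments is None:
                moments = m_i
            else:
                moments = moments + m_i
            Fmag += pair_dipole_force(
                m_i, system.x, magnet.moment, magnet.position, params.mu0
            )
        F += Fmag

    if params.enable_pair_magnetic and n > 1 and moments is not None:
        F += _pair_dipole_sum(system, moments, params)

    if include_lubrication and params.enable_pair_lubrication and n > 1:
        F += _pair_lubrication_sum(system, params, props)

    if include_lubrication and params.enable_wall_lubrication and domain is not None:
        r_w = np.atleast_2d(nearest_wall_vector(domain, system.x))
        d = np.linalg.norm(r_w, axis=-1)
        he_arr = (
            system.a.copy() if params.h_e_wall is None
            else np.full(n, params.h_e_wall)
        )
        near = d - system.a < he_arr
        for k in np.flatnonzero(near):
            F[k] += wall_lubrication(
                system.a[k], system.u[k], r_w[k], he_arr[k], props.mu
            )

    return F, Fmag


def _near_pairs(x, thresholds):
    """Index pairs (i < j) with |x_i - x_j| below the pairwise threshold."""
    d = np.linalg.norm(x[:, None] - x[None], axis=-1)
    iu, ju = np.triu_indices(len(x), k=1)
    sel = d[iu, ju] < thresholds[iu, ju]
    return iu[sel], ju[sel]


def _pair_dipole_sum(system, moments, params):
    x = system.x
    n = len(x)
    F = np.zeros((n, 3))
    cutoff = params.pair_cutoff_factor * system.a
    iu, ju = _near_pairs(x, cutoff[:, None] + cutoff[None, :])
    if len(iu):
        fij = pair_dipole_force(
            moments[iu], x[iu], moments[ju], x[ju], params.mu0
        )
        np.add.at(F, iu, fij)
        np.add.at(F, ju, -fij)
    return F


def _pair_lubrication_sum(system, params, props):
    x, u, a = system.x, system.u, system.a
    n = len(x)
    F = np.zeros((n, 3))
    aij_mat = 0.5 * (a[:, None] + a[None, :])  # identical in practice
    he = params.h_e_pair
    thresh = 2 * aij_mat + (he if he is not None else aij_mat)
    iu, ju = _near_pairs(x, thresh)
    for i, j in zip(iu, ju):
        aij = aij_mat[i, j]
        h_e = he if he is not None else aij
        fij = pair_lubrication(aij, u[i], x[i], u[j], x[j], h_e, props.mu)
        F[i] += fij.reshape(3)
        F[j] -= fij.reshape(3)
    return F


def drag_dominance(v: np.ndarray, beta, F: np.ndarray, F_R: np.ndarray = 0.0):
    """Ratio |beta (F + F_R)| / |v| of forced drift to fluid advection.

    Much less than one (threshold 0.01 by convention) means particle motion
    is drag-dominated and insensitive to coating thickness; infinite when
    the fluid is locally at rest.
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    drift = np.atleast_2d(np.asarray(beta)[..., None] * (np.asarray(F) + F_R))
    vmag = np.linalg.norm(v, axis=-1)
    dmag = np.linalg.norm(drift, axis=-1)
    with np.errstate(divide="ignore"):
        ratio = np.where(vmag > 0, dmag / np.where(vmag > 0, vmag, 1.0), np.inf)
    return ratio if np.asarray(v).ndim > 1 else float(ratio[0])


def advance_particles(
    system: ParticleSystem,
    velocity_at,
    params: ForceParams,
    props: FluidProperties,
    dt: float,
    rng: np.random.Generator,
    magnets: tuple[Magnet, ...] = (),
    domain: VoxelDomain | None = None,
    max_disp: float | None = None,
) -> dict:
    """One explicit overdamped step (in place); returns diagnostics.

    ``velocity_at(x) -> (N, 3)`` supplies the interpolated fluid velocity in
    m/s.  With ``max_disp`` set, the step is split into sub-steps so no
    particle moves further than ``max_disp`` per sub-step (stiff forces near
    walls or the magnet).  Particles landing in an outlet voxel or leaving
    the grid are flagged ``exited``; a particle about to enter a solid voxel
    is slid along the wall (its wall-normal displacement is removed), which
    only triggers when a finite step overshoots the diverging lubrication
    repulsion.

    Returns dict with ``exited`` (bool mask), ``F`` and ``F_mag`` [N] from
    the last sub-step, and ``n_substeps``.
    """
    n = len(system)
    exited = np.zeros(n, dtype=bool)
    if n == 0:
        return {"exited": exited, "F": np.zeros((0, 3)),
                "F_mag": np.zeros((0, 3)), "n_substeps": 0}
    if dt <= 0:
        raise ValueError("dt must be positive")
    remaining = dt
    n_sub = 0
    F = Fmag = np.zeros((n, 3))
    beta = mobility(system.a_total, props.mu)
    while remaining > 1e-12 * dt:
        F, Fmag = compute_forces(
            system, params, props, magnets, domain, include_lubrication=False
        )
        if np.any(~np.isfinite(F)):
            raise FloatingPointError("NaN/inf in particle forces")
        active = ~exited
        v = np.zeros((n, 3))
        if np.any(active):
            v[active] = np.atleast_2d(velocity_at(system.x[active]))
        u_det = v + beta[:, None] * F
        if max_disp is not None:
            speed = np.max(np.linalg.norm(u_det[active], axis=-1), initial=0.0)
            sub_dt = remaining if speed == 0 else min(remaining, max_disp / speed)
            # bound the sub-step count: stiffer motion is handled by the
            # per-particle displacement clamp below (it ends in the contact
            # constraints anyway: wall clamp, pair separation floor)
            sub_dt = max(sub_dt, remaining / 64.0)
        else:
            sub_dt = remaining
        if params.enable_brownian and props.temperature > 0:
            F_R = brownian_force(
                system.a_total, props.mu, params.temperature, sub_dt, rng
            )
        else:
            F_R = np.zeros((n, 3))
        u_new = u_det + beta[:, None] * F_R
        _apply_lubrication_implicit(
            system, params, props, domain, u_new, beta, active
        )
        u_new[exited] = 0.0
        disp = u_new * sub_dt
        if max_disp is not None:
            norms = np.linalg.norm(disp, axis=-1)
            over = norms > max_disp
            if np.any(over):
                disp[over] *= (max_disp / norms[over])[:, None]
                u_new[over] = disp[over] / sub_dt
        x_new = system.x + disp

        _separate_overlaps(system, x_new, active)

        if domain is not None and domain.surface is not None:
            # contact clamp: a finite step can jump the (nanometre-thin)
            # lubrication layer entirely; hold the center at least half the
            # cutoff clear of the wall and make the velocity consistent
            for gap in np.unique(system.a):
                he = params.h_e_wall if params.h_e_wall is not None else gap
                grp = active & (system.a == gap)
                if not np.any(grp):
                    continue
                clamped = domain.surface.push_inside(
                    x_new[grp], gap + 0.5 * he
                )
                moved = np.linalg.norm(clamped - x_new[grp], axis=-1) > 0
                if np.any(moved):
                    xg = x_new[grp]
                    ug = u_new[grp]
                    xg[moved] = clamped[moved]
                    ug[moved] = (clamped[moved] - system.x[grp][moved]) / sub_dt
                    x_new[grp] = xg
                    u_new[grp] = ug

        if domain is not None:
            exited_now, _ = _resolve_boundaries(
                system, domain, x_new, u_new, active
            )
            exited |= exited_now
        system.u = u_new
        system.x = x_new
        remaining -= sub_dt
        n_sub += 1
        if n_sub > 100000:
            raise RuntimeError("sub-stepping failed to converge")
    return {"exited": exited, "F": F, "F_mag": Fmag, "n_substeps": n_sub}


def _separate_overlaps(system, x_new, active, floor_frac: float = 1e-3):
    """Push overlapping pairs apart to a minimal surface gap (in place).

    The implicit lubrication damps the closing velocity with the gap at
    the start of the sub-step, so a single step can still overshoot into
    contact; the diverging repulsion is represented geometrically by a
    floor on the surface separation (``floor_frac`` of the mean radius).
    """
    n = len(system)
    if n < 2:
        return
    aij = 0.5 * (system.a[:, None] + system.a[None, :])
    iu, ju = _near_pairs(x_new, 2 * aij * (1 + floor_frac))
    for i, j in zip(iu, ju):
        if not (active[i] and active[j]):
            continue
        rvec = x_new[i] - x_new[j]
        d = np.linalg.norm(rvec)
        if d == 0:
            continue
        target = 2 * aij[i, j] * (1 + floor_frac)
        push = 0.5 * (target - d)
        rhat = rvec / d
        x_new[i] += push * rhat
        x_new[j] -= push * rhat


def _apply_lubrication_implicit(system, params, props, domain, u_new, beta,
                                active=None):
    """Damp velocities by the lubrication closures, implicitly (in place).

    The lubrication force is linear in the (relative) velocity, so the
    overdamped balance including it has a closed form: the wall-normal
    velocity component is divided by ``1 + beta * c(h)``, the pair relative
    normal velocity by ``1 + 2 beta * c_p(h)``, with the divergent-as-h->0
    coefficients of the respective force laws.  This removes the stiffness
    of the explicit evaluation (whose per-step gain exceeds 1 as the gap
    closes) and guarantees gaps shrink at most exponentially — neither
    wall penetration nor particle overlap can occur in exact arithmetic.
    """
    n = len(system)
    mu = props.mu
    if active is None:
        active = np.ones(n, dtype=bool)
    if params.enable_pair_lubrication and n > 1:
        aij_mat = 0.5 * (system.a[:, None] + system.a[None, :])
        he0 = params.h_e_pair
        thresh = 2 * aij_mat + (he0 if he0 is not None else aij_mat)
        for i, j in zip(*_near_pairs(system.x, thresh)):
            if not (active[i] and active[j]):
                continue
            aij = aij_mat[i, j]
            h_e = he0 if he0 is not None else aij
            rvec = system.x[i] - system.x[j]
            d = np.linalg.norm(rvec)
            h = d - 2.0 * aij
            if h >= h_e or d == 0:
                continue
            rhat = rvec / d
            c = (6.0 * math.pi / 4.0) * mu * aij**2 * (1.0 / h - 1.0 / h_e)
            bij = 0.5 * (beta[i] + beta[j])
            un_rel = np.dot(u_new[i] - u_new[j], rhat)
            delta = un_rel * (1.0 - 1.0 / (1.0 + 2.0 * bij * c))
            u_new[i] -= 0.5 * delta * rhat
            u_new[j] += 0.5 * delta * rhat
    if params.enable_wall_lubrication and domain is not None and np.any(active):
        r_w = np.full((n, 3), np.inf)
        r_w[active] = np.atleast_2d(
            nearest_wall_vector(domain, system.x[active])
        )
        d = np.linalg.norm(r_w, axis=-1)
        he_arr = (
            system.a if params.h_e_wall is None
            else np.full(n, params.h_e_wall)
        )
        near = np.flatnonzero(active & (d - system.a < he_arr))
        for k in near:
            h = d[k] - system.a[k]
            if d[k] == 0:
                continue
            if h <= 0:
                raise ValueError("wall penetration: particle inside the wall")
            nhat = r_w[k] / d[k]
            c = 6.0 * math.pi * mu * system.a[k] ** 2 * (1.0 / h - 1.0 / he_arr[k])
            un = np.dot(u_new[k], nhat)
            u_new[k] -= un * (1.0 - 1.0 / (1.0 + beta[k] * c)) * nhat


def _resolve_boundaries(system, domain, x_new, u_new, active):
    """Classify proposed positions: outlet exit, wall slide, or fluid."""
    n = len(x_new)
    exited = np.zeros(n, dtype=bool)
    slid = np.zeros(n, dtype=bool)
    dims = np.asarray(domain.dims)
    idx = domain.position_to_index(x_new)
    inb = np.all((idx >= 0) & (idx < dims), axis=-1)
    idx_c = np.clip(idx, 0, dims - 1)
    st = domain.site_type[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
    exited = active & (~inb | (st == OUTLET))
    hit_wall = active & inb & (st == SOLID)
    if np.any(hit_wall):
        for k in np.flatnonzero(hit_wall):
            r_w = nearest_wall_vector(domain, system.x[k])
            d = np.linalg.norm(r_w)
            if d == 0:
                continue
            nhat = r_w / d
            # remove the wall-normal displacement component (slide contact)
            disp = x_new[k] - system.x[k]
            disp -= np.dot(disp, nhat) * nhat
            x_new[k] = system.x[k] + disp
            u_new[k] -= np.dot(u_new[k], nhat) * nhat
            slid[k] = True
            # if still solid (corner), stay put
            if not domain.contains_fluid(x_new[k]):
                x_new[k] = system.x[k]
    return exited, slid
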