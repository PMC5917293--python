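"""Wall, inlet and outlet conditions for the lattice solver.

Walls are handled link-wise after streaming: plain (halfway) bounce-back
reflects each population crossing a cut link back to its origin site, while
the Bouzidi-Firdaouss-Lallemand (BFL) scheme linearly interpolates using
the sub-grid wall fraction ``q`` of the link, placing the no-slip plane on
the true surface rather than halfway along the link.

Inlets impose a pulsatile parabolic velocity profile: each inlet site
carries a weight ``max(0, 1 - (r/R)^2)`` of the instantaneous peak velocity
taken from a tabulated waveform.  Outlets impose either a fixed density
(Dirichlet, default) or a zero-gradient population copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import C, OPP, W, equilibrium, macroscopic_moments
from .units import CS2, max_lattice_velocity
from .geometry import VoxelDomain, INLET, CylinderSurface, TorusSurface

__all__ = [
    "Waveform",
    "InletSpec",
    "parabolic_weights",
    "eval_waveform",
    "two_harmonic_pulse",
    "read_waveform_csv",
    "write_waveform_csv",
    "make_inlet",
    "apply_velocity_inlet",
    "apply_pressure_outlet",
    "apply_bounce_back",
    "apply_bfl",
]


# --------------------------------------------------------------------------
# Waveforms
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class Waveform:
    """Tabulated peak inlet velocity over one cardiac period.

    ``times`` [s] must be increasing and lie within one period; evaluation
    is periodic with linear interpolation between samples.
    """

    times: np.ndarray      # s
    values: np.ndarray     # m/s
    period: float          # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.period <= 0:
            raise ValueError("waveform period must be positive")
        if self.times.size == 0:
            raise ValueError("waveform has no samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("waveform times must be strictly increasing")
        if self.times[-1] - self.times[0] > self.period:
            raise ValueError("samples must cover at most one period")

    @classmethod
    def constant(cls, value: float, period: float = 1.0) -> "Waveform":
        return cls(times=np.array([0.0]), values=np.array([value]), period=period)

    def __call__(self, t) -> np.ndarray | float:
        return eval_waveform(self, t)

    @property
    def mean(self) -> float:
        """Period-average of the periodic linear interpolant."""
        tt = np.concatenate([self.times, [self.times[0] + self.period]])
        vv = np.concatenate([self.values, [self.values[0]]])
        return float(np.trapezoid(vv, tt) / self.period)


def eval_waveform(w: Waveform, t) -> np.ndarray | float:
    """Periodic linear interpolation of the waveform at time(s) ``t`` [s]."""
    tmod = (np.asarray(t, dtype=float) - w.times[0]) % w.period + w.times[0]
    tt = np.concatenate([w.times, [w.times[0] + w.period]])
    vv = np.concatenate([w.values, [w.values[0]]])
    out = np.interp(tmod, tt, vv)
    return float(out) if np.isscalar(t) else out


def two_harmonic_pulse(
    peak_velocity: float, bpm: float, n_samples: int = 64
) -> Waveform:
    """Synthetic two-harmonic cardiac pulse (fixture).

    A smooth systolic peak and diastolic trough built from the first two
    Fourier modes, normalized so the maximum equals ``peak_velocity``.
    """
    if bpm <= 0:
        raise ValueError("heart rate must be positive")
    period = 60.0 / bpm
    s = np.linspace(0.0, 1.0, n_samples, endpoint=False)
    shape = 0.5 - 0.4 * np.cos(2 * np.pi * s) - 0.1 * np.cos(4 * np.pi * s)
    shape = np.clip(shape / shape.max(), 0.0, None)
    return Waveform(times=s * period, values=peak_velocity * shape, period=period)


def read_waveform_csv(path, period: float | None = None) -> Waveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    v = df["peak_velocity_m_s"].to_numpy(dtype=float)
    if period is None:
        period = float(t[-1] - t[0] + (t[1] - t[0] if len(t) > 1 else 1.0))
    return Waveform(times=t, values=v, period=period)


def write_waveform_csv(w: Waveform, path) -> None:
    pd.DataFrame({"time_s": w.times, "peak_velocity_m_s": w.values}).to_csv(
        path, index=False
    )


# --------------------------------------------------------------------------
# Inlets
# --------------------------------------------------------------------------
@dataclass
class InletSpec:
    """One velocity inlet: member sites, parabolic weights, direction, waveform."""

    sites: np.ndarray        # (M, 3) lattice indices
    weights: np.ndarray      # (M,) in [0, 1]
    direction: np.ndarray    # unit 3-vector, pointing into the domain
    waveform: Waveform

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("inlet direction must be non-zero")
        self.direction = self.direction / n


def parabolic_weights(
    positions: np.ndarray,
    normal: np.ndarray,
    lumen_radius: float | None = None,
    spacing: float = 0.0,
) -> np.ndarray:
    """Per-site weights ``max(0, 1 - (r/R)^2)`` over an inlet plane.

    ``r`` is the in-plane distance from the lumen centroid; ``R`` is the
    lumen radius on the plane (analytic when known, else the largest site
    distance plus half a voxel).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        raise ValueError("empty inlet plane")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    centroid = positions.mean(axis=0)
    rel = positions - centroid
    rel = rel - np.outer(rel @ normal, normal)  # project into the plane
    r = np.linalg.norm(rel, axis=1)
    if lumen_radius is None:
        lumen_radius = r.max() + 0.5 * spacing
    if lumen_radius <= 0:
        raise ValueError("lumen radius must be positive")
    return np.maximum(0.0, 1.0 - (r / lumen_radius) ** 2)


def make_inlet(
    domain: VoxelDomain,
    direction: np.ndarray,
    waveform: Waveform,
) -> InletSpec:
    """Build an InletSpec from the domain's inlet-tagged sites."""
    sites = np.argwhere(domain.site_type == INLET)
    if len(sites) == 0:
        raise ValueError("domain has no inlet sites")
    positions = domain.voxel_centers(sites)
    radius = None
    surf = domain.surface
    if isinstance(surf, CylinderSurface):
        radius = surf.radius
    elif isinstance(surf, TorusSurface):
        radius = surf.tube_radius
    weights = parabolic_weights(positions, direction, radius, domain.spacing)
    return InletSpec(sites=sites, weights=weights, direction=direction,
                     waveform=waveform)


def apply_velocity_inlet(
    f: np.ndarray,
    inlet: InletSpec,
    t: float,
    velocity_scale: float,
    f_star: np.ndarray | None = None,
    rho0: float = 1.0,
) -> None:
    """Impose the pulsatile parabolic velocity profile at the inlet (in place).

    The imposed velocity at each site is ``weight * waveform(t)`` (converted
    to lattice units by ``velocity_scale = delta_x/delta_t``) along the
    inlet direction.  The unknown (inward-pointing) populations are closed
    like a moving wall on the inlet face: bounce-back of the outgoing
    post-collision populations plus the wall-velocity momentum term
    ``2 w_i rho0 (c_i . u) / cs2``, which injects exactly the mass flux
    ``rho0 u`` per site and transmits the profile at second order.  When
    ``f_star`` (post-collision, pre-streaming populations) is not supplied,
    the site's own post-streaming populations stand in — adequate for
    smooth flow but first-order.
    """
    u_peak_lat = eval_waveform(inlet.waveform, t) / velocity_scale
    cap = max_lattice_velocity()
    if abs(u_peak_lat) > cap:
        raise ValueError(
            f"inlet lattice velocity {u_peak_lat:.4g} exceeds the Mach cap "
            f"{cap:.4g}; reduce the time step or the waveform amplitude"
        )
    ix, iy, iz = inlet.sites.T
    u_site = (
        inlet.direction[:, None] * (inlet.weights * u_peak_lat)[None, :]
    )
    src = f if f_star is None else f_star
    for i in range(1, 19):
        cn = float(C[i] @ inlet.direction)
        if cn <= 0:
            continue  # outgoing or tangent: leave as streamed
        cu = np.tensordot(C[i].astype(float), u_site, axes=([0], [0]))
        f[i, ix, iy, iz] = (
            src[OPP[i], ix, iy, iz] + 2.0 * W[i] * rho0 * cu / CS2
        )


def apply_pressure_outlet(
    f: np.ndarray,
    outlet_sites: np.ndarray,
    rho_out: float = 1.0,
    mode: str = "dirichlet",
    normal: np.ndarray | None = None,
) -> None:
    """Impose the outlet closure (in place).

    ``dirichlet``: populations set to equilibrium at fixed density
    ``rho_out`` and the site's current (extrapolated) velocity.
    ``zero_gradient``: populations copied from the neighbour one site
    upstream along ``normal`` (vanishing normal gradient).
    """
    if len(outlet_sites) == 0:
        raise ValueError("empty outlet")
    ix, iy, iz = np.asarray(outlet_sites).T
    if mode == "dirichlet":
        if rho_out <= 0:
            raise ValueError("outlet density must be positive")
        rho_site, u_site = macroscopic_moments(f[:, ix, iy, iz])
        f[:, ix, iy, iz] = equilibrium(np.full_like(rho_site, rho_out), u_site)
    elif mode == "zero_gradient":
        if normal is None:
            raise ValueError("zero_gradient outlet needs a normal direction")
        step = -np.sign(np.asarray(normal)).astype(int)  # one site upstream
        f[:, ix, iy, iz] = f[:, ix + step[0], iy + step[1], iz + step[2]]
    else:
        raise ValueError(f"unknown outlet mode: {mode!r}")


# --------------------------------------------------------------------------
# Wall schemes (post-streaming, link-wise)
# --------------------------------------------------------------------------
def apply_bounce_back(
    f_new: np.ndarray,
    f_star: np.ndarray,
    domain: VoxelDomain,
) -> None:
    """Halfway bounce-back on every cut link (in place on ``f_new``).

    ``f_star`` are the post-collision (pre-streaming) populations; the
    population that would cross the wall returns to its origin site with
    reversed velocity.
    """
    for i, (sites, _q) in domain.wall_links.items():
        ix, iy, iz = sites.T
        f_new[OPP[i], ix, iy, iz] = f_star[i, ix, iy, iz]


def apply_bfl(
    f_new: np.ndarray,
    f_star: np.ndarray,
    domain: VoxelDomain,
) -> None:
    """Bouzidi-Firdaouss-Lallemand linear interpolated bounce-back (in place).

    For a cut link of fraction ``q`` at flow site ``x``:

    * ``q < 1/2``:  f_opp(x) = 2q f*_i(x) + (1 - 2q) f*_i(x - c_i)
    * ``q >= 1/2``: f_opp(x) = 1/(2q) f*_i(x) + (1 - 1/(2q)) f*_opp(x)

    Falls back to plain bounce-back on a link whose upstream neighbour
    ``x - c_i`` is not a flow site.  At ``q = 1/2`` both branches reduce to
    plain bounce-back.
    """
    dims = np.asarray(domain.dims)
    flow = domain.flow_mask
    for i, (sites, q) in domain.wall_links.items():
        if q is None:
            raise ValueError(f"missing q fractions on wall links, direction {i}")
        ix, iy, iz = sites.T
        fi_here = f_star[i, ix, iy, iz]
        out = np.empty(len(q))

        lo = q < 0.5
        if np.any(lo):
            up = sites[lo] - C[i]
            per = np.asarray(domain.periodic)
            up[:, per] %= dims[per]
            in_grid = np.all((up >= 0) & (up < dims), axis=1)
            up_ok = np.zeros(len(up), dtype=bool)
            ug = up[in_grid]
            up_ok[in_grid] = flow[ug[:, 0], ug[:, 1], ug[:, 2]]
            upc = np.clip(up, 0, dims - 1)
            f_up = f_star[i, upc[:, 0], upc[:, 1], upc[:, 2]]
            ql = q[lo]
            interp = 2.0 * ql * fi_here[lo] + (1.0 - 2.0 * ql) * f_up
            out[lo] = np.where(up_ok, interp, fi_here[lo])

        hi = ~lo
        if np.any(hi):
            qh = q[hi]
            f_opp_here = f_star[OPP[i], ix[hi], iy[hi], iz[hi]]
            out[hi] = fi_here[hi] / (2.0 * qh) + (1.0 - 0.5 / qh) * f_opp_here

        f_new[OPP[i], ix, iy, iz] = out
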