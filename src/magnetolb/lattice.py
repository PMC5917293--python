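"""D3Q19 LBGK collision-streaming kernel with second-order body forcing.

The solver evolves 19 discrete populations ``f_i(x, t)`` per lattice site.
One step is relaxation toward a local second-order Maxwell-Boltzmann
equilibrium at rate ``1/tau`` (BGK), plus a Guo-style forcing term that
injects a hydrodynamic body force at second order, followed by streaming of
each population one link along its lattice velocity.

All arrays are in lattice units.  Populations are stored with the velocity
index first, ``f.shape == (19, nx, ny, nz)``; vector fields are stored as
``(3, nx, ny, nz)``.  The kernel itself is geometry-agnostic — streaming is
fully periodic and wall/inlet/outlet handling is layered on top by the
boundary-condition module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import CS2

__all__ = [
    "C",
    "W",
    "OPP",
    "FluidField",
    "equilibrium",
    "forcing_term",
    "collide_lbgk",
    "stream_periodic",
    "macroscopic_moments",
    "equation_of_state",
]

# --------------------------------------------------------------------------
# D3Q19 stencil: rest velocity, 6 axis-aligned, 12 face diagonals.
# Weights 1/3, 1/18, 1/36; c_s^2 = 1/3.
# --------------------------------------------------------------------------
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0],
        [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1],
        [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1],
        [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

W = np.array(
    [1.0 / 3.0]
    + [1.0 / 18.0] * 6
    + [1.0 / 36.0] * 12
)

#: Index of the opposite velocity, c[OPP[i]] == -c[i].
OPP = np.array(
    [int(np.flatnonzero((C == -c).all(axis=1))[0]) for c in C], dtype=np.int64
)


def _bshape(ndim_extra: int) -> tuple[int, ...]:
    return (19,) + (1,) * ndim_extra


def equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order Maxwell-Boltzmann equilibrium populations.

    f0_i = w_i rho [1 + c_i.u/cs2 + (c_i.u)^2/(2 cs2^2) - u.u/(2 cs2)]

    Parameters
    ----------
    rho : array, shape S
        Lattice density (> 0).
    u : array, shape (3,) + S
        Lattice velocity.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("equilibrium requires strictly positive density")
    cu = np.tensordot(C, u, axes=([1], [0]))  # (19,) + S
    cu /= CS2                                 # 3 c.u
    usq = np.sum(u * u, axis=0)
    usq /= 2.0 * CS2
    out = 0.5 * cu * cu
    out += cu
    out += 1.0 - usq
    out *= W.reshape(_bshape(rho.ndim))
    out *= rho
    return out


def forcing_term(F: np.ndarray, u: np.ndarray, tau: float) -> np.ndarray:
    """Guo second-order forcing components F_i.

    F_i = w_i (1 - 1/(2 tau)) [ (c_i - u).F / cs2 + (c_i.u)(c_i.F) / cs2^2 ]

    Moments: sum_i F_i = 0 and sum_i F_i c_i = (1 - 1/(2 tau)) F, so together
    with the half-force velocity shift in :func:`macroscopic_moments` the
    scheme reproduces the body force at second order.
    """
    F = np.asarray(F, dtype=float)
    u = np.asarray(u, dtype=float)
    cF = np.tensordot(C, F, axes=([1], [0]))
    cu = np.tensordot(C, u, axes=([1], [0]))
    uF = np.sum(u * F, axis=0)
    w = W.reshape(_bshape(F.ndim - 1))
    return w * (1.0 - 0.5 / tau) * ((cF - uF) / CS2 + cu * cF / CS2**2)


def collide_lbgk(
    f: np.ndarray,
    f0: np.ndarray,
    tau: float,
    forcing: np.ndarray | None = None,
) -> np.ndarray:
    """BGK relaxation toward equilibrium, plus optional forcing components.

    Returns ``f - (f - f0)/tau + forcing`` (lattice time step is 1).
    """
    if tau <= 0.5:
        raise ValueError("collide_lbgk requires tau > 0.5")
    out = f - (f - f0) / tau
    if forcing is not None:
        out = out + forcing
    return out


def stream_periodic(f: np.ndarray) -> np.ndarray:
    """Propagate every population one link along its velocity, periodically.

    Wall, inlet and outlet links are subsequently corrected by the boundary
    module; only fully periodic transport happens here.
    """
    out = np.empty_like(f)
    for i, c in enumerate(C):
        out[i] = np.roll(f[i], shift=tuple(c), axis=(0, 1, 2))
    return out


def macroscopic_moments(
    f: np.ndarray, F: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Density and velocity from the populations.

    rho = sum_i f_i;  u = (sum_i f_i c_i + F/2) / rho  (half-force shift for
    second-order consistency of the forced scheme).
    """
    rho = np.sum(f, axis=0)
    mom = np.tensordot(C.T.astype(float), f, axes=([1], [0]))  # (3,) + S
    if F is not None:
        mom = mom + 0.5 * np.asarray(F, dtype=float)
    u = mom / rho
    return rho, u


def equation_of_state(rho: np.ndarray) -> np.ndarray:
    """Ideal-gas-like lattice pressure p = rho c_s^2."""
    return np.asarray(rho, dtype=float) * CS2


@dataclass
class FluidField:
    """Populations plus per-site body force on a regular grid (lattice units)."""

    f: np.ndarray                      # (19, nx, ny, nz)
    body_force: np.ndarray = None      # (3, nx, ny, nz)
    rho: np.ndarray = field(default=None, repr=False)
    u: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.f.shape[0] != 19:
            raise ValueError("populations must have leading dimension 19")
        if self.body_force is None:
            self.body_force = np.zeros((3,) + self.f.shape[1:])

    @classmethod
    def uniform(cls, dims: tuple[int, int, int], rho: float = 1.0) -> "FluidField":
        """Quiescent field at uniform density."""
        f = np.broadcast_to(
            W.reshape(19, 1, 1, 1) * rho, (19,) + tuple(dims)
        ).copy()
        return cls(f=f)

    def update_moments(self) -> tuple[np.ndarray, np.ndarray]:
        self.rho, self.u = macroscopic_moments(self.f, self.body_force)
        return self.rho, self.u
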