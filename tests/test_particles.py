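import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magnetolb import geometry as geo
from magnetolb import particles as par
from magnetolb.particles import (
    ForceParams,
    Magnet,
    ParticleSystem,
    advance_particles,
    brownian_force,
    compute_forces,
    dipole_field,
    drag_dominance,
    gravity_buoyancy,
    induced_moment,
    interpolate_velocity,
    magnet_particle_force,
    maude_force,
    mobility,
    pair_dipole_force,
    pair_lubrication,
    spread_reaction_force,
    wall_lubrication,
)
from magnetolb.units import MU0, K_B, FluidProperties

finite3 = st.lists(
    st.floats(-1.0, 1.0, allow_nan=False), min_size=3, max_size=3
).map(np.array)


class TestDipoleField:
    def test_axial_magnitude(self):
        """On the dipole axis |H| = 2 m / (4 pi r^3)."""
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 3000.0]))
        H = dipole_field(mag, np.array([0.0, 0.0, 0.03]))
        assert np.linalg.norm(H) == pytest.approx(
            2 * 3000 / (4 * np.pi * 0.03**3), rel=1e-12
        )
        assert np.linalg.norm(H) == pytest.approx(1.77e7, rel=0.01)

    def test_equatorial_branch(self):
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 5.0]))
        r = 0.02
        H = dipole_field(mag, np.array([r, 0.0, 0.0]))
        assert np.allclose(H, -mag.moment / (4 * np.pi * r**3), rtol=1e-12)

    def test_inverse_cube_decay(self):
        mag = Magnet(np.zeros(3), np.array([0.0, 1000.0, 0.0]))
        rs = np.geomspace(1e-3, 1e-1, 15)
        mags = [
            np.linalg.norm(dipole_field(mag, np.array([0.0, r, 0.0])))
            for r in rs
        ]
        slope = np.polyfit(np.log(rs), np.log(mags), 1)[0]
        assert slope == pytest.approx(-3.0, abs=1e-6)

    def test_zero_separation_rejected(self):
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            dipole_field(mag, np.zeros(3))


class TestInducedMoment:
    def test_zero_radius(self):
        assert np.allclose(induced_moment(0.0, 5.7, np.array([1e5, 0, 0])), 0.0)

    def test_cubic_in_radius(self):
        H = np.array([0.0, 1e5, 0.0])
        m1 = induced_moment(1e-7, 5.7, H)
        m2 = induced_moment(2e-7, 5.7, H)
        assert np.linalg.norm(m2) == pytest.approx(8 * np.linalg.norm(m1))

    def test_reported_magnitude(self):
        # 65 nm magnetite core at the top of the susceptibility range
        m = induced_moment(65e-9, 5.7, np.array([0.0, 0.0, 1e5]))
        assert np.linalg.norm(m) == pytest.approx(6.56e-16, rel=0.01)

    def test_core_radius_only(self):
        """Coating is non-magnetic: the moment ignores a_c entirely."""
        sys_bare = ParticleSystem.monodisperse(np.zeros((1, 3)), a=65e-9)
        sys_coat = ParticleSystem.monodisperse(np.zeros((1, 3)), a=65e-9, a_c=65e-9)
        H = np.array([0.0, 0.0, 1e5])
        assert np.allclose(
            induced_moment(sys_bare.a, sys_bare.chi_v, H),
            induced_moment(sys_coat.a, sys_coat.chi_v, H),
        )


def _sympy_pair_force():
    """Independent symbolic oracle: F_i = -grad_{x_i} U for the point-dipole
    interaction energy U = mu0/(4 pi) [ (m1.m2) r^-3 - 3 (m1.r)(m2.r) r^-5 ]."""
    import sympy as sp

    x1 = sp.symbols("p1x p1y p1z")
    x2 = sp.symbols("p2x p2y p2z")
    m1 = sp.symbols("m1x m1y m1z")
    m2 = sp.symbols("m2x m2y m2z")
    mu0 = sp.symbols("mu0", positive=True)
    r = [a - b for a, b in zip(x1, x2)]
    r2 = sum(c**2 for c in r)
    rn = sp.sqrt(r2)
    m1m2 = sum(a * b for a, b in zip(m1, m2))
    m1r = sum(a * b for a, b in zip(m1, r))
    m2r = sum(a * b for a, b in zip(m2, r))
    U = mu0 / (4 * sp.pi) * (m1m2 / rn**3 - 3 * m1r * m2r / rn**5)
    F = [-sp.diff(U, xi) for xi in x1]
    return sp.lambdify((x1, x2, m1, m2, mu0), F, "numpy")


class TestPairDipoleForce:
    def test_matches_symbolic_gradient_oracle(self, rng):
        oracle = _sympy_pair_force()
        for _ in range(12):
            x1 = rng.normal(size=3)
            x2 = rng.normal(size=3)
            if np.linalg.norm(x1 - x2) < 0.1:
                continue
            m1 = rng.normal(size=3)
            m2 = rng.normal(size=3)
            ours = pair_dipole_force(m1, x1, m2, x2)
            ref = np.array(oracle(x1, x2, m1, m2, MU0))
            assert np.allclose(ours, ref, rtol=1e-12, atol=1e-300)

    @settings(max_examples=40)
    @given(m1=finite3, m2=finite3, x1=finite3, x2=finite3)
    def test_newtons_third_law(self, m1, m2, x1, x2):
        if np.linalg.norm(x1 - x2) < 1e-3:
            return
        Fi = pair_dipole_force(m1, x1, m2, x2)
        Fj = pair_dipole_force(m2, x2, m1, x1)
        assert np.allclose(Fi, -Fj, rtol=1e-14, atol=1e-14 * np.abs(Fi).max())

    def test_collinear_attraction(self):
        m = 1e-14
        r = 1e-6
        F = pair_dipole_force(
            np.array([0, 0, m]), np.array([0, 0, r]),
            np.array([0, 0, m]), np.zeros(3),
        )
        expect = -3 * MU0 * m**2 / (2 * np.pi * r**4)
        assert F.reshape(3)[2] == pytest.approx(expect, rel=1e-12)

    def test_perpendicular_repulsion_half_magnitude(self):
        m = 1e-14
        r = 1e-6
        Fperp = pair_dipole_force(
            np.array([0, 0, m]), np.array([r, 0, 0]),
            np.array([0, 0, m]), np.zeros(3),
        )
        expect = 3 * MU0 * m**2 / (4 * np.pi * r**4)
        assert Fperp.reshape(3)[0] == pytest.approx(expect, rel=1e-12)

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            pair_dipole_force(np.ones(3), np.zeros(3), np.ones(3), np.zeros(3))


class TestMagnetParticleForce:
    def test_pulled_toward_magnet(self):
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 3000.0]))
        F = magnet_particle_force(mag, np.array([0.0, 0.0, 0.05]), 65e-9, 5.7)
        assert F.reshape(3)[2] < 0  # toward the magnet at the origin

    def test_distance_exponent(self):
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 3000.0]))
        rs = np.geomspace(0.01, 0.1, 25)
        mags = [
            np.linalg.norm(magnet_particle_force(
                mag, np.array([0.0, 0.0, r]), 65e-9, 5.7))
            for r in rs
        ]
        slope = np.polyfit(np.log(rs), np.log(mags), 1)[0]
        assert slope == pytest.approx(-7.0, abs=1e-3)

    def test_radius_exponent(self):
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 3000.0]))
        radii = np.geomspace(20e-9, 500e-9, 25)
        mags = [
            np.linalg.norm(magnet_particle_force(
                mag, np.array([0.0, 0.0, 0.03]), a, 5.7))
            for a in radii
        ]
        slope = np.polyfit(np.log(radii), np.log(mags), 1)[0]
        assert slope == pytest.approx(3.0, abs=1e-3)


class TestWallLubrication:
    def test_zero_at_cutoff(self):
        a, h_e = 500e-9, 500e-9
        r_w = np.array([0.0, -(a + h_e), 0.0])
        F = wall_lubrication(a, np.array([0.0, -1e-3, 0.0]), r_w, h_e, 0.004)
        assert np.allclose(F, 0.0)

    def test_zero_for_tangential_motion(self):
        a = 500e-9
        r_w = np.array([0.0, -1.2 * a, 0.0])
        F = wall_lubrication(a, np.array([1e-3, 0.0, 0.0]), r_w, a, 0.004)
        assert np.allclose(F, 0.0, atol=1e-30)

    def test_opposes_approach(self):
        a = 500e-9
        r_w = np.array([0.0, -1.5 * a, 0.0])  # wall below
        u_p = np.array([0.0, -1e-3, 0.0])     # moving toward it
        F = wall_lubrication(a, u_p, r_w, a, 0.004)
        assert F.reshape(3)[1] > 0            # pushes away from the wall

    def test_penetration_flagged(self):
        a = 500e-9
        with pytest.raises(ValueError):
            wall_lubrication(a, np.zeros(3), np.array([0, -0.5 * a, 0]), a, 0.004)


class TestPairLubrication:
    def test_zero_for_equal_velocities(self):
        a = 500e-9
        u = np.array([1e-3, 2e-3, 0.0])
        F = pair_lubrication(a, u, np.zeros(3), u, np.array([2.5 * a, 0, 0]),
                             a, 0.004)
        assert np.allclose(F, 0.0, atol=1e-30)

    def test_antisymmetry(self, rng):
        a = 250e-9
        x_i = np.zeros(3)
        x_j = np.array([2.4 * a, 0.0, 0.0])
        u_i, u_j = rng.normal(size=3) * 1e-3, rng.normal(size=3) * 1e-3
        Fi = pair_lubrication(a, u_i, x_i, u_j, x_j, a, 0.004)
        Fj = pair_lubrication(a, u_j, x_j, u_i, x_i, a, 0.004)
        assert np.allclose(Fi, -Fj, rtol=1e-14)

    def test_repels_on_approach(self):
        a = 250e-9
        Fi = pair_lubrication(
            a, np.array([-1e-3, 0, 0]), np.array([2.2 * a, 0, 0]),
            np.zeros(3), np.zeros(3), a, 0.004,
        )
        assert Fi.reshape(3)[0] > 0

    def test_no_overlap_during_driven_approach(self):
        """Integrated approach with pair lubrication never overlaps."""
        a = 250e-9
        props = FluidProperties()
        system = ParticleSystem.monodisperse(
            np.array([[0.0, 0.0, 0.0], [4 * a, 0.0, 0.0]]), a=a
        )
        system.u = np.array([[1e-3, 0.0, 0.0], [-1e-3, 0.0, 0.0]])
        params = ForceParams(enable_brownian=False, enable_gravity=False,
                             enable_magnetic=False)
        rng = np.random.default_rng(0)
        push = 1e-3 / mobility(np.array([a]), props.mu)[0]

        def velocity_at(x):
            # head-on squeeze: background flow pushing the pair together
            v = np.zeros_like(np.atleast_2d(x))
            v[:, 0] = np.where(np.atleast_2d(x)[:, 0] < 2 * a, 1e-3, -1e-3)
            return v

        min_gap = np.inf
        for _ in range(400):
            # sub-steps short enough to resolve the lubrication layer
            advance_particles(system, velocity_at, params, props, 1e-4, rng,
                              max_disp=0.5 * a)
            gap = np.linalg.norm(system.x[0] - system.x[1]) - 2 * a
            min_gap = min(min_gap, gap)
        assert min_gap > 0


class TestMaudeForce:
    def test_far_field_limit(self):
        a, u = 500e-9, 1e-3
        F0 = 6 * math.pi * 0.004 * a * u
        assert maude_force(a, 1e3 * a, u) == pytest.approx(F0, rel=2e-3)

    def test_equal_gap_value(self):
        a, u = 500e-9, 1e-3
        F0 = 6 * math.pi * 0.004 * a * u
        assert maude_force(a, a, u) == pytest.approx(2.125 * F0, rel=1e-12)

    def test_double_drag_at_nine_eighths(self):
        a, u = 25e-9, 1e-3
        F0 = 6 * math.pi * 0.004 * a * u
        assert maude_force(a, 9 * a / 8, u) == pytest.approx(2 * F0, rel=1e-12)

    def test_rejects_contact(self):
        with pytest.raises(ValueError):
            maude_force(1e-7, 0.0, 1e-3)


class TestGravityBuoyancy:
    def test_neutral_buoyancy(self):
        F = gravity_buoyancy(1e-7, 1000.0, 1000.0, np.array([0, 0, -9.81]))
        assert np.allclose(F, 0.0)

    def test_no_gravity(self):
        F = gravity_buoyancy(1e-7, 5170.0, 1000.0, np.zeros(3))
        assert np.allclose(F, 0.0)

    def test_magnetite_settling_speed(self):
        """Overdamped settling beta |F| equals the Stokes closed form."""
        a, mu = 500e-9, 0.004
        F = gravity_buoyancy(a, 5170.0, 1000.0, np.array([0, 0, -9.81]))
        v = mobility(np.array([a]), mu)[0] * np.linalg.norm(F)
        expect = 2 * a**2 * (5170 - 1000) * 9.81 / (9 * mu)
        assert v == pytest.approx(expect, rel=1e-12)
        assert v == pytest.approx(5.7e-7, rel=0.01)


class TestBrownianForce:
    def test_zero_temperature(self, rng):
        F = brownian_force(np.array([65e-9]), 0.004, 0.0, 1e-6, rng)
        assert np.allclose(F, 0.0)

    def test_unbiased(self, rng):
        F = brownian_force(np.full(100_000, 65e-9), 0.004, 310.15, 1e-6, rng)
        sigma = F.std()
        assert np.abs(F.mean(axis=0)).max() < 4 * sigma / np.sqrt(100_000)

    def test_msd_matches_stokes_einstein(self, rng):
        """Free diffusion: MSD(t) = 6 D t with D = k_B T / (6 pi mu a)."""
        a, mu, T = 65e-9, 0.004, 310.15
        D = K_B * T / (6 * math.pi * mu * a)
        assert D == pytest.approx(8.7e-13, rel=0.01)
        n, steps, dt = 1000, 1500, 1e-6
        beta = mobility(np.full(n, a), mu)
        x = np.zeros((n, 3))
        for _ in range(steps):
            x += beta[:, None] * brownian_force(np.full(n, a), mu, T, dt, rng) * dt
        msd = np.mean(np.sum(x**2, axis=1))
        expect = 6 * D * steps * dt
        stderr = expect * np.sqrt(2.0 / (3 * n))
        assert abs(msd - expect) < 3 * stderr

    def test_reproducible_under_seed(self):
        a = np.array([65e-9])
        F1 = brownian_force(a, 0.004, 310.15, 1e-6, np.random.default_rng(3))
        F2 = brownian_force(a, 0.004, 310.15, 1e-6, np.random.default_rng(3))
        assert np.array_equal(F1, F2)


class TestInterpolation:
    def test_uniform_field(self, small_cylinder, rng):
        u = np.zeros((3,) + tuple(small_cylinder.dims))
        u[0] = 1.23
        u[2] = -0.5
        x = small_cylinder.surface.point + np.array([1e-5, -2e-5, 0])
        x[2] = 10 * 25e-6
        v = interpolate_velocity(u, small_cylinder, x)
        assert np.allclose(v, [1.23, 0.0, -0.5], rtol=1e-12)

    def test_linear_field_exact(self):
        dom = geo.voxelize_slab(gap=60.0, length=8.0, spacing=1.0)
        u = np.zeros((3,) + tuple(dom.dims))
        idx = np.indices(dom.dims, dtype=float)
        centers_y = (idx[1] + 0.5) * dom.spacing
        u[2] = 0.1 + 0.03 * centers_y
        x = np.array([1.2, 30.7, 3.4])
        v = interpolate_velocity(u, dom, x)
        assert v[2] == pytest.approx(0.1 + 0.03 * 30.7, rel=1e-12)

    def test_site_center_returns_site_value(self):
        dom = geo.voxelize_slab(gap=60.0, length=8.0, spacing=1.0)
        u = np.random.default_rng(1).random((3,) + tuple(dom.dims))
        x = dom.voxel_centers(np.array([1, 30, 4]))
        v = interpolate_velocity(u, dom, x)
        assert np.allclose(v, u[:, 1, 30, 4], rtol=1e-12)

    def test_outside_domain_rejected(self, small_cylinder):
        with pytest.raises(ValueError):
            interpolate_velocity(
                np.zeros((3,) + tuple(small_cylinder.dims)),
                small_cylinder, np.array([0.0, 0.0, 0.0]),
            )


class TestSpreadReaction:
    def test_weights_sum_to_one(self):
        dom = geo.voxelize_slab(gap=30.0, length=8.0, spacing=1.0)
        field = np.zeros((3,) + tuple(dom.dims))
        spread_reaction_force(field, dom, np.array([[1.3, 15.2, 3.8]]),
                              np.array([[1.0, -2.0, 0.5]]))
        assert np.allclose(field.sum(axis=(1, 2, 3)), [1.0, -2.0, 0.5],
                           rtol=1e-12)

    def test_site_center_gets_everything(self):
        dom = geo.voxelize_slab(gap=30.0, length=8.0, spacing=1.0)
        field = np.zeros((3,) + tuple(dom.dims))
        x = dom.voxel_centers(np.array([1, 14, 5]))
        spread_reaction_force(field, dom, x[None], np.array([[0.0, 0.0, 2.0]]))
        assert field[2, 1, 14, 5] == pytest.approx(2.0)
        assert field.sum() == pytest.approx(2.0)

    def test_total_momentum_bookkeeping(self, rng):
        dom = geo.voxelize_slab(gap=30.0, length=8.0, spacing=1.0)
        field = np.zeros((3,) + tuple(dom.dims))
        n = 17
        x = np.stack([
            rng.uniform(0.5, 2.5, n), rng.uniform(3, 27, n),
            rng.uniform(0.5, 7.5, n),
        ], axis=1)
        F = rng.normal(size=(n, 3))
        spread_reaction_force(field, dom, x, F)
        assert np.allclose(field.sum(axis=(1, 2, 3)), F.sum(axis=0), rtol=1e-12)


class TestDragDominance:
    def test_zero_forces(self):
        assert drag_dominance(np.array([1e-3, 0, 0]), 1e8, np.zeros(3)) == 0.0

    def test_halves_when_viscosity_doubles(self):
        F = np.array([1e-12, 0, 0])
        v = np.array([1e-3, 0, 0])
        b1 = mobility(np.array([65e-9]), 0.004)
        b2 = mobility(np.array([65e-9]), 0.008)
        assert drag_dominance(v, b2, F) == pytest.approx(
            drag_dominance(v, b1, F) / 2
        )

    def test_quiescent_fluid_reports_infinite(self):
        assert np.isinf(drag_dominance(np.zeros(3), 1e8, np.array([1e-12, 0, 0])))


class TestAdvance:
    def _quiet(self):
        return ForceParams(
            enable_brownian=False, enable_gravity=False, enable_magnetic=False,
            enable_wall_lubrication=False, enable_pair_lubrication=False,
        )

    def test_pure_tracer(self, rng):
        """All forces off: the particle follows the fluid velocity exactly."""
        props = FluidProperties()
        system = ParticleSystem.monodisperse(np.zeros((1, 3)), a=65e-9)

        def velocity_at(x):
            return np.full((len(np.atleast_2d(x)), 3), [1e-3, 0.0, 2e-3])

        advance_particles(system, velocity_at, self._quiet(), props, 0.5, rng)
        assert np.allclose(system.u[0], [1e-3, 0.0, 2e-3], rtol=1e-14)
        assert np.allclose(system.x[0], [5e-4, 0.0, 1e-3], rtol=1e-14)

    def test_settling_in_quiescent_fluid(self, rng):
        props = FluidProperties()
        params = ForceParams(
            gravity=np.array([0.0, 0.0, -9.81]), enable_brownian=False,
            enable_magnetic=False, enable_wall_lubrication=False,
            enable_pair_lubrication=False,
        )
        system = ParticleSystem.monodisperse(np.zeros((1, 3)), a=500e-9)

        def velocity_at(x):
            return np.zeros((len(np.atleast_2d(x)), 3))

        advance_particles(system, velocity_at, params, props, 1.0, rng)
        expect = 2 * (500e-9) ** 2 * (5170 - 1000) * 9.81 / (9 * props.mu)
        assert -system.u[0, 2] == pytest.approx(expect, rel=1e-12)

    def test_nan_force_aborts(self, rng):
        props = FluidProperties()
        system = ParticleSystem.monodisperse(
            np.array([[0.0, 0.0, 0.01]]), a=65e-9
        )
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, np.inf]))
        params = ForceParams(enable_brownian=False, enable_gravity=False)
        with pytest.raises(FloatingPointError):
            advance_particles(
                system, lambda x: np.zeros((1, 3)), params,
                props, 1e-3, rng, magnets=(mag,),
            )

    def test_outlet_exit_detected(self, small_cylinder, rng):
        props = FluidProperties()
        dom = small_cylinder
        start = dom.surface.point.copy()
        start[2] = 18 * 25e-6  # near the outlet end

        system = ParticleSystem.monodisperse(start[None], a=65e-9)

        def velocity_at(x):
            return np.full((len(np.atleast_2d(x)), 3), [0.0, 0.0, 1e-3])

        info = advance_particles(
            system, velocity_at, self._quiet(), props, 0.1, rng, domain=dom
        )
        assert info["exited"][0]


class TestComputeForces:
    def test_toggles_remove_contributions(self):
        props = FluidProperties()
        system = ParticleSystem.monodisperse(
            np.array([[0.0, 0.0, 0.03]]), a=65e-9
        )
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 3000.0]))
        on = ForceParams(gravity=np.array([0, 0, -9.81]))
        off = ForceParams(gravity=np.array([0, 0, -9.81]),
                          enable_magnetic=False, enable_gravity=False)
        F_on, Fmag = compute_forces(system, on, props, magnets=(mag,))
        F_off, _ = compute_forces(system, off, props, magnets=(mag,))
        assert np.linalg.norm(F_on) > 0
        assert np.allclose(F_off, 0.0)
        assert np.linalg.norm(Fmag) > 0

    def test_magnetic_part_reported_separately(self):
        props = FluidProperties()
        system = ParticleSystem.monodisperse(
            np.array([[0.0, 0.0, 0.03]]), a=65e-9
        )
        mag = Magnet(np.zeros(3), np.array([0.0, 0.0, 3000.0]))
        params = ForceParams(enable_gravity=False)
        F, Fmag = compute_forces(system, params, props, magnets=(mag,))
        assert np.allclose(F, Fmag)
        assert np.allclose(
            Fmag[0], magnet_particle_force(mag, system.x[0], 65e-9, 5.7)
        )
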