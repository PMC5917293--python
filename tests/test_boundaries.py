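import numpy as np
import pytest

from magnetolb import boundaries as bc
from magnetolb import geometry as geo
from magnetolb import lattice as lat
from magnetolb.driver import LatticeSolver
from magnetolb.units import CS2


class TestParabolicWeights:
    def _disc_sites(self, R, dx):
        g = np.arange(-R - dx, R + dx, dx) + dx / 2
        X, Y = np.meshgrid(g, g)
        pts = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=1)
        return pts[np.hypot(pts[:, 0], pts[:, 1]) < R]

    def test_centroid_weight_is_one(self):
        pts = self._disc_sites(10.0, 1.0)
        w = bc.parabolic_weights(pts, np.array([0, 0, 1.0]), lumen_radius=10.0)
        center = np.argmin(np.hypot(pts[:, 0], pts[:, 1]))
        assert w[center] == pytest.approx(1.0, abs=0.01)

    def test_rim_weight_vanishes(self):
        pts = self._disc_sites(10.0, 1.0)
        w = bc.parabolic_weights(pts, np.array([0, 0, 1.0]), lumen_radius=10.0)
        rim = np.hypot(pts[:, 0], pts[:, 1]) > 9.5
        assert np.all(w[rim] < 0.11)

    def test_disc_average_approaches_half(self):
        for R, tol in ((10.0, 0.02), (40.0, 0.005)):
            pts = self._disc_sites(R, 1.0)
            w = bc.parabolic_weights(pts, np.array([0, 0, 1.0]), lumen_radius=R)
            assert w.mean() == pytest.approx(0.5, abs=tol)

    def test_empty_inlet_raises(self):
        with pytest.raises(ValueError):
            bc.parabolic_weights(np.empty((0, 3)), np.array([0, 0, 1.0]))


class TestWaveform:
    def test_samples_reproduced(self):
        w = bc.Waveform(times=[0.0, 0.2, 0.5], values=[1.0, 3.0, 2.0], period=1.0)
        assert bc.eval_waveform(w, 0.2) == 3.0

    def test_periodicity(self):
        w = bc.two_harmonic_pulse(0.63, bpm=68)
        for t in (0.0, 0.1, 0.37):
            assert bc.eval_waveform(w, t) == pytest.approx(
                bc.eval_waveform(w, t + w.period), rel=1e-12
            )

    def test_linear_midpoint(self):
        w = bc.Waveform(times=[0.0, 0.4], values=[1.0, 2.0], period=1.0)
        assert bc.eval_waveform(w, 0.2) == pytest.approx(1.5)

    def test_two_harmonic_peak_and_period(self):
        w = bc.two_harmonic_pulse(0.63, bpm=68)
        assert w.period == pytest.approx(60 / 68)
        assert w.values.max() == pytest.approx(0.63)
        assert w.values.min() >= 0.0

    def test_csv_round_trip(self, tmp_path):
        w = bc.two_harmonic_pulse(0.5, bpm=60, n_samples=16)
        path = tmp_path / "wave.csv"
        bc.write_waveform_csv(w, path)
        back = bc.read_waveform_csv(path, period=w.period)
        assert np.allclose(back.times, w.times)
        assert np.allclose(back.values, w.values)

    def test_rejects_bad_samples(self):
        with pytest.raises(ValueError):
            bc.Waveform(times=[0.0, 0.0], values=[1.0, 2.0], period=1.0)
        with pytest.raises(ValueError):
            bc.Waveform(times=[], values=[], period=1.0)


def _drive_tube(u_peak, n_steps=4000, waveform=None, length=32):
    """Straight tube with a velocity inlet; returns (domain, solver, u_lat_peak)."""
    dx = 25e-6
    dom = geo.voxelize_cylinder(10 * dx, length * dx, axis=2, spacing=dx)
    geo.compute_wall_links(dom)
    vel_scale = dx / 2.083e-5  # tau = 0.9 at blood viscosity
    wf = waveform or bc.Waveform.constant(u_peak)
    inlet = bc.make_inlet(dom, np.array([0, 0, 1.0]), wf)
    solver = LatticeSolver(
        dom, 0.9, wall_scheme="bfl", inlets=(inlet,), velocity_scale=vel_scale
    )
    solver.run(n_steps, dt_s=2.083e-5)
    return dom, solver, u_peak / vel_scale


class TestVelocityInlet:
    def test_zero_waveform_keeps_rest_state(self):
        dom, solver, _ = _drive_tube(0.0, n_steps=50)
        _, u = solver.moments()
        assert np.max(np.abs(u[:, dom.flow_mask])) < 1e-14

    def test_steady_tube_mean_is_half_peak(self):
        dom, solver, u_lat = _drive_tube(4e-4)
        _, u = solver.moments()
        mid = u[2][:, :, 16][dom.flow_mask[:, :, 16]]
        assert mid.mean() / u_lat == pytest.approx(0.5, rel=0.03)

    def test_over_cap_velocity_raises(self):
        dx = 25e-6
        dom = geo.voxelize_cylinder(10 * dx, 8 * dx, axis=2, spacing=dx)
        geo.compute_wall_links(dom)
        inlet = bc.make_inlet(dom, np.array([0, 0, 1.0]), bc.Waveform.constant(1.0))
        f = lat.FluidField.uniform(dom.dims).f
        with pytest.raises(ValueError, match="Mach"):
            bc.apply_velocity_inlet(f, inlet, 0.0, velocity_scale=1.0)


class TestPressureOutlet:
    def test_outlet_pressure_matches_density(self):
        dom, solver, _ = _drive_tube(2e-4, n_steps=2000)
        rho, _ = solver.moments()
        out_rho = rho[dom.outlet_mask]
        assert np.allclose(lat.equation_of_state(out_rho), 1.0 * CS2, rtol=1e-6)

    def test_linear_pressure_drop(self):
        dom, solver, u_lat = _drive_tube(4e-4, n_steps=5000, length=40)
        rho, _ = solver.moments()
        nz = dom.dims[2]
        ax = [rho[11, 11, k] for k in range(2, nz - 2)]
        z = np.arange(2, nz - 2, dtype=float)
        resid = np.polyfit(z, ax, 1, full=True)[1][0]
        drop = ax[0] - ax[-1]
        assert drop > 0
        # straight-line fit captures the axial profile to within 3%
        assert np.sqrt(resid / len(ax)) < 0.03 * drop

    def test_rejects_non_positive_density(self):
        f = lat.FluidField.uniform((4, 4, 4)).f
        with pytest.raises(ValueError):
            bc.apply_pressure_outlet(f, np.array([[1, 1, 1]]), rho_out=0.0)

    def test_empty_outlet_raises(self):
        f = lat.FluidField.uniform((4, 4, 4)).f
        with pytest.raises(ValueError):
            bc.apply_pressure_outlet(f, np.empty((0, 3)))


class TestBounceBack:
    def test_closed_box_mass_conserved(self, rng):
        box = np.full((8, 8, 8), geo.FLUID, dtype=np.uint8)
        box[0] = box[-1] = geo.SOLID
        box[:, 0] = box[:, -1] = geo.SOLID
        box[:, :, 0] = box[:, :, -1] = geo.SOLID
        dom = geo.VoxelDomain((8, 8, 8), 1.0, np.zeros(3), box)
        geo.compute_wall_links(dom)
        solver = LatticeSolver(dom, 0.8, wall_scheme="bounce_back")
        # random perturbation inside the box
        solver.f[:, dom.flow_mask] *= 1 + 0.05 * rng.random(
            (19, dom.n_fluid)
        )
        m0 = solver.flow_mass()
        solver.run(1000)
        assert solver.flow_mass() == pytest.approx(m0, rel=1e-12)

    def test_rest_state_stays_at_rest(self):
        dom = geo.voxelize_slab(gap=6.0, length=1.0, spacing=1.0)
        geo.compute_wall_links(dom)
        solver = LatticeSolver(dom, 0.9, wall_scheme="bounce_back")
        solver.run(50)
        _, u = solver.moments()
        assert np.max(np.abs(u[:, dom.flow_mask])) < 1e-14

    def test_zero_velocity_plane_halfway(self):
        """Fitted parabola vanishes within dx/10 of the halfway plane."""
        dom = geo.voxelize_slab(gap=10.0, length=1.0, spacing=1.0)
        geo.compute_wall_links(dom)
        G = 1e-5
        solver = LatticeSolver(
            dom, 0.9, "bounce_back", body_force=np.array([0, 0, G])
        )
        solver.run(4000)
        _, u = solver.moments()
        flow = dom.flow_mask
        y = dom.voxel_centers(np.argwhere(flow))[:, 1]
        roots = sorted(np.roots(np.polyfit(y, u[2][flow], 2)))
        # halfway planes: dx/2 beyond the outermost fluid sites
        assert roots[0] == pytest.approx(y.min() - 0.5, abs=0.1)
        assert roots[1] == pytest.approx(y.max() + 0.5, abs=0.1)


class TestBFL:
    def test_reduces_to_bounce_back_at_half(self):
        dom = geo.voxelize_slab(gap=10.0, length=1.0, spacing=1.0)
        geo.compute_wall_links(dom)
        qs = np.concatenate([q for _, q in dom.wall_links.values()])
        assert np.allclose(qs, 0.5)
        G = 1e-5
        s_bfl = LatticeSolver(dom, 0.9, "bfl", body_force=np.array([0, 0, G]))
        s_bb = LatticeSolver(dom, 0.9, "bounce_back", body_force=np.array([0, 0, G]))
        for _ in range(60):
            s_bfl.step()
            s_bb.step()
        assert np.array_equal(s_bfl.f, s_bb.f)

    def test_offset_channel_beats_bounce_back(self):
        """Walls off the halfway plane: BFL error < plain bounce-back error."""
        errs = {}
        for scheme in ("bfl", "bounce_back"):
            dom = geo.voxelize_slab(gap=10.2, length=1.0, spacing=1.0, offset=0.3)
            geo.compute_wall_links(dom)
            nu = CS2 * 0.4
            G = 1e-5
            solver = LatticeSolver(dom, 0.9, scheme, body_force=np.array([0, 0, G]))
            solver.run(4000)
            _, u = solver.moments()
            flow = dom.flow_mask
            y = dom.voxel_centers(np.argwhere(flow))[:, 1]
            lo, hi = dom.surface.lo, dom.surface.hi
            analytic = G / (2 * nu) * (y - lo) * (hi - y)
            errs[scheme] = np.max(np.abs(u[2][flow] - analytic)) / analytic.max()
        assert errs["bfl"] < errs["bounce_back"]

    def test_cylinder_centerline_within_two_percent(self, periodic_cylinder):
        from magnetolb.driver import run_poiseuille_benchmark

        rep = run_poiseuille_benchmark(radius_lat=10.3, tau=0.9, n_steps=5000)
        assert rep["centerline_rel_error"] < 0.02

    def test_missing_q_raises(self):
        dom = geo.voxelize_slab(gap=8.0, length=1.0, spacing=1.0)
        geo.compute_wall_links(dom)
        i = next(iter(dom.wall_links))
        sites, _ = dom.wall_links[i]
        dom.wall_links[i] = (sites, None)
        f = lat.FluidField.uniform(dom.dims).f
        with pytest.raises(ValueError, match="q"):
            bc.apply_bfl(f, f.copy(), dom)


class TestFittedRadius:
    def test_bfl_profile_radius_within_half_spacing(self):
        """Fitted Poiseuille radius lands within dx/2 of the true radius."""
        from magnetolb.driver import run_poiseuille_benchmark

        rep = run_poiseuille_benchmark(radius_lat=10.3, tau=0.9, n_steps=5000)
        r, uz = rep["r"], rep["uz"]
        coef = np.polyfit(r**2, uz, 1)
        R_fit = np.sqrt(-coef[1] / coef[0])
        assert abs(R_fit - 10.3) < 0.5


class TestPulsatile:
    def test_cycle_averaged_flow_matches_waveform_mean(self):
        """Quasi-steady pulsatile tube: mean flux = waveform mean x pi R^2 / 2."""
        dx = 25e-6
        dt = 2.083e-5
        period = 1500 * dt
        wf = bc.two_harmonic_pulse(3e-4, bpm=60 / period, n_samples=32)
        dom = geo.voxelize_cylinder(8 * dx, 16 * dx, axis=2, spacing=dx)
        geo.compute_wall_links(dom)
        inlet = bc.make_inlet(dom, np.array([0, 0, 1.0]), wf)
        solver = LatticeSolver(
            dom, 0.9, "bfl", inlets=(inlet,), velocity_scale=dx / dt
        )
        solver.run(1500, dt_s=dt)  # one warm-up cycle
        fluxes = []
        for k in range(1500):
            solver.step(time_s=(1500 + k) * dt)
            _, u = solver.moments()
            fluxes.append(u[2][:, :, 8][dom.flow_mask[:, :, 8]].sum())
        mean_flux = np.mean(fluxes) * (dx / dt) * dx**2
        R = 8 * dx
        expected = wf.mean * np.pi * R**2 / 2
        assert mean_flux == pytest.approx(expected, rel=0.03)
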