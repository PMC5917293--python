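# Methods

This note records the models implemented in `magnetolb`, their
assumptions, the numerical choices that required a decision, and what the
desk-scale test scenarios do and do not demonstrate.

## Flow model

Blood is treated as an incompressible Newtonian fluid at a characteristic
viscosity μ = 0.004 Pa·s and density ρ = 1000 kg/m³ (viscosity in reality
varies with hematocrit and shear; shear thinning is out of scope). The
D3Q19 LBGK scheme recovers the Navier–Stokes equations at second order in
the low-Mach limit; the model is athermal — the temperature (310.15 K,
body temperature) enters only the Brownian noise amplitude.

Unit scaling: lattice spacing δx, time step δt and lattice mass
δm = ρδx³ non-dimensionalise all quantities (with δm so chosen, lattice
density 1 is the physical blood density, which makes the pressure and
force scales unambiguous). Stability requires τ > ½ and a velocity cap
read as u/c_s < 1/30, i.e. u_max = 1/(30√3) ≈ 0.0192 lattice units
(commonly rounded to 0.02); the literal combination "Ma = u/c_s² < 1/30"
would give 0.011 and is inconsistent with the rounded cap, so the c_s
reading is used. Given a peak physical velocity, the largest admissible
δt follows from the cap; for δx = 25 μm and a 0.63 m/s carotid peak this
gives 7.64×10⁻⁷ s (≈ the commonly quoted 7.8×10⁻⁷ s; no single reading
reproduces that figure exactly). For slow desk-scale flows the time step
is instead chosen from the accuracy bound on τ (we use ν_lat = 0.1333,
τ = 0.9 — a standard accuracy/stability compromise for BGK).

Body forces use the Guo second-order forcing term with the half-force
velocity shift in the moments. This choice is validated by the shear-wave
viscosity recovery (<1% error at τ = 0.9) and the body-force Poiseuille
profiles (planar convergence order ≥ 1.8).

### Boundary conditions

* **Walls** — link-wise reflection after streaming. BFL interpolated
  bounce-back is the default: the sub-grid wall fraction q of each cut
  link comes from exact segment–surface intersection for the analytic
  fixtures (cylinder: quadratic root; torus: vectorised bisection; slab:
  linear). Mask-only geometries read from file fall back to q = ½
  (halfway bounce-back accuracy) and distance-transform wall vectors —
  a documented accuracy downgrade. At q = ½ the BFL branches reduce
  exactly to plain bounce-back (tested bitwise).
* **Inlets** — pulsatile parabolic velocity profile, weight
  max(0, 1 − (r/R)²) per site about the lumen centroid (analytic R when
  the fixture surface is known). The face closure is a moving-wall
  bounce-back: unknown populations are set to the reflected
  post-collision populations plus the wall-velocity momentum term
  2w_iρ(c_i·u)/c_s². A full equilibrium overwrite of the inlet sites was
  evaluated first and rejected: it converges to a flux-deficient steady
  state (downstream mean ≈ 0.40–0.43 of the peak instead of 0.5); the
  moving-wall closure transmits the profile at second order (measured
  mean/peak = 0.497). Waveforms are user-supplied CSV tables
  (time_s, peak_velocity_m_s) with periodic linear interpolation; a
  two-harmonic synthetic pulse parameterised by peak velocity and heart
  rate ships as a fixture. Inlet sites are labelled velocity-prescribed
  (Dirichlet in velocity), whatever the naming conventions elsewhere.
* **Outlets** — fixed-density (Dirichlet) equilibrium closure at the
  site's extrapolated velocity, default ρ_out = 1; a zero-gradient copy
  closure is available behind a config switch.

Out-of-grid neighbours of inlet/outlet sites belong to the face
conditions, not the wall scheme; only genuinely solid neighbours (or
out-of-grid neighbours of interior fluid sites) generate wall links.

## Particle model

Particles are points far below the lattice spacing (largest radius
0.5 μm against δx = 25 μm), so no finite-size radius correction and no
Faxén terms are applied. Inertia is neglected (overdamped limit): drag
balances the other forces instantaneously,

    u_p = v(x_p) + β(F + F_R),  β = 1/(6πμ(a + a_c)).

Forces, each individually switchable:

* gravity/buoyancy (ρ_p − ρ_f)(4/3)π(a+a_c)³ g — negligible for the
  nanometre radii used here, off by default in the demos;
* magnet attraction: dipole field of the permanent magnet, induced moment
  4πa³χ_v H/3 (core radius only — the drug coating is non-magnetic and
  assumed not to shield), point-dipole pair force between the induced
  moment and the magnet;
* inter-particle dipolar forces between induced moments, with a 10a
  neighbour cutoff (the force decays as r⁻⁴);
* wall and pair lubrication, 6πμa²(u·r̂)[1/h − 1/h_e] (pair version
  carries the ¼ prefactor and relative velocity), cut off beyond h_e;
  h_e defaults to one core radius for both — the cutoff is a numerical
  regularisation whose value is not prescribed by the physics, so it is
  exposed in the config;
* Brownian noise: per-component Gaussian of variance 2k_BT/(β·dt)
  (Euler–Maruyama; per-axis displacement variance 2D·dt with the
  Stokes–Einstein D). Moments align instantaneously with the local field
  (rotation is fast compared to hydrodynamic time scales); there are no
  rotational degrees of freedom. The susceptibility range 1.0–5.7 is
  treated as dimensionless; the demos use the top value (pure magnetite,
  the most responsive case).

Velocity interpolation is trilinear over the 8 surrounding site centers;
solid-site weights are zeroed and the rest renormalised. Two-way coupling
(off by default — the suspensions here are dilute, 1–5 particles per
lattice volume at most) deposits the drag reaction
+6πμ(a+a_c)(u_p − v) onto the same 8 sites with trilinear weights,
consumed by the next fluid step; the deposited momentum equals minus the
drag impulse on the particles exactly (bookkeeping is tested to 1e-12).

### Numerical treatment of stiff near-contact dynamics

The lubrication force is linear in the (relative) velocity, and its
explicit evaluation with the previous step's velocity is a scalar
recursion with gain −λ, λ = a(1/h − 1/h_e): divergent for λ > 1 at any
time step. The integrator therefore applies lubrication semi-implicitly —
the wall-normal velocity component is divided by 1 + βc(h), the pair
relative normal velocity by 1 + 2βc_p(h) — which is the exact overdamped
balance for this linear force and guarantees gaps close at most
exponentially. The explicit force functions remain the public model
surface (and are what the validation tables report).

A finite step can still jump across the nanometre-thin lubrication layer
(the layer is ~a, the advective step can be ~δx/2). Two geometric
constraints make the integration robust: positions are clamped to at
least a + h_e/2 from the analytic wall (with the velocity made consistent
with the clamped displacement), and overlapping pairs are separated to a
minimal surface gap of 10⁻³·2a. Sub-stepping caps the per-sub-step
displacement (default δx/2) with a bounded sub-step count (64 per step);
displacement beyond the cap is truncated — such motion ends in the
contact constraints regardless. Strongly aggregating configurations
(e.g. 500 nm particles chained at contact by dipolar attraction) are at
the edge of the model's validity: the dilute-suspension assumptions do
not describe chaining, and the constraints above merely keep the
integration stable there.

Particles whose proposed position falls in an outlet voxel or beyond the
grid are removed and logged as exited; the ledger (injected = in-domain +
exited) is asserted at every output step. A master seed spawns separate
streams for seeding and Brownian noise, so toggling one stochastic
element does not perturb the other's draws; complete runs are
bit-reproducible for a fixed seed.

## Orchestration

The coupled loop per time step: fluid collide/stream/boundaries → particle
communication hook (a no-op in this serial reference implementation;
kept so a distributed variant can slot in without changing the loop
contract) → zero and accumulate particle forces → interpolate fluid
velocity → optional reaction-force spreading → overdamped particle
update. For steady or quasi-steady inflow the driver can converge the
flow first (`converge_flow`, max-norm velocity change < 1e-5 over 200
steps) and then freeze it, advancing only particles — valid for one-way
coupling only, and the default for the demo and sweep scenarios whose
transit times (seconds) far exceed the LB time step (~2×10⁻⁵ s). In the
frozen phase the particle step may be a multiple of the LB step (20×
in the scenarios; displacement per step stays well under the sub-step
cap).

## Desk-scale scenarios: what they show

All scenarios run on synthetic vessels (straight tube R = 0.25 mm,
L = 1.6 mm at δx = 25 μm unless stated). They exercise every model
component at full fidelity, but they are not patient anatomy: no
bifurcations, no MRI-derived lumen, heart-rate waveforms are synthetic,
and particle counts are tens rather than tens of thousands. Conclusions
about *orderings* (which radius targets better, how flow rate shifts
capture) transfer; absolute RoI percentages do not.

* **Five-particle demo.** Pressure gradient 103.9 Pa/m (inlet pressure
  0.01 mmHg = 1.33 Pa over a pressure-consistent 12.8 mm tube; the demo
  default is a 1.6 mm tube so a transit fits in seconds — the length is a
  parameter). The magnet moment is {0, 3000, 0} A·m². A near-centerline
  magnet placement of 0.0022 mm appears in descriptions of this scenario
  but would sit inside the lumen; the demo exposes the offset as a
  parameter and by default stands the magnet off so the magnetic drift is
  ⅛ of the peak flow speed (≈8 cm; the drift scales as d⁻⁷, so absolute
  placements are fragile and the package derives them from the intended
  drift via `magnet_standoff`). Checks: the particle nearest the magnet
  has the longest near-wall residence and lowest streamwise velocity;
  trajectories never approach below half the initial minimum separation;
  with the magnet off, radial drift stays below δx/10 over the transit.
* **Lubrication (driven-wall) validation.** A constant force drives a
  particle through quiescent fluid onto a plane wall; each step solves
  the scalar overdamped balance exactly and the trajectory pairs each
  step's force with the post-move position, as trajectory logging does.
  The measured total resistance is compared with the analytic
  sphere-approaching-a-wall force F₀(9a/8h + 1). The cutoff model's
  near-wall coefficient is a/h against the analytic 9a/8h, an intrinsic
  relative gap x/(8+9x) (x = a/h): 10.2% at h = 0.1a, shrinking to 8.7%
  at h = a (with h_e = 50a). Discretisation of the motion adds a
  deviation that grows with the step size; the validation reports both
  step sizes to show the trend. Radius-independence is exact (the
  normalised curves for 25 nm and 500 nm coincide).
* **Dipolar validation.** Two identical induced dipoles in a uniform
  field, parallel and orthogonal to the connecting line; the implemented
  force matches a symbolic energy-gradient oracle to 1e-12, the
  parallel:orthogonal magnitude ratio is exactly 2 at every separation
  (the point-dipole model is isotropic — it ignores the orientation
  dependence a full Laplace solution would show near contact), and the
  force normalised by its touching-separation value is 1 at h = 2a.
* **Targeting sweeps.** Particles seeded in a sphere at the inlet; a
  spherical RoI hugs the near-magnet wall at the mid-plane. The magnet
  standoff follows the drift rule: for the radius sweep the *largest*
  radius gets drift = ¼ of the inlet peak (deflection of order the tube
  radius per transit; a closer magnet slams large particles into the
  wall upstream of the target and inverts the ordering for reasons that
  have nothing to do with targeting efficiency); the velocity sweep uses
  its single radius the same way. Findings at this scale: the RoI peak
  percentage is non-decreasing in radius over {65, 500} nm (a³ forcing),
  and decreases when the inlet peak velocity is doubled.
* **Coating study.** Coatings {16.25, 32.5, 65} nm on a 65 nm core, noise
  off for a deterministic comparison. With the magnet stood off so the
  drift ratio β|F|/|v| stays ≈ 2×10⁻³, trajectories deviate from the
  uncoated case by < 1% of the path length. The drift ratio threshold
  (reported at 0.01) is necessary but not sufficient for the 1% figure:
  radial drift differences are amplified by the shear gradient
  (δu_z = u'(r)·δr), so the study sits well inside the drag-dominated
  regime rather than at its edge.

## Known limitations

* Newtonian rheology only; no red blood cells (their dispersive effect on
  nanoparticle transport is likely non-negligible in vivo).
* Point-dipole magnet (overestimates field gradients near the magnet) and
  point-dipole pair forces (break down for non-dilute suspensions).
* No absorption, binding, or drug release at the target; particles exit
  or circulate indefinitely.
* Mask-only geometries get first-order wall accuracy (q = ½) and
  distance-transform wall vectors.
* Magnetic aggregation (chaining) of large particles is stabilised, not
  modelled.
* Serial, whole-array implementation: practical up to ~10⁶ lattice sites
  and ~10³ particles; the vessel fixtures here use ~3×10⁴ sites.
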