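# Nanoparticle targeting in a straight vessel segment: a 3000 A m^2 magnet
# beside the tube pulls 65 nm magnetite particles toward a spherical RoI on
# the near wall. Desk-scale run: ~1 minute.
units:
  delta_x_m: 2.5e-5        # lattice spacing
  delta_t_s: 2.083e-5      # time step (tau = 0.9 at blood viscosity)
fluid:
  mu: 0.004                # Pa s
  rho: 1000.0              # kg/m^3
  temperature: 310.15      # K
geometry:
  fixture: cylinder
  radius_m: 2.5e-4
  length_m: 1.6e-3
inlets:
  - direction: [0, 0, 1]
    peak_m_s: 4.06e-4      # Poiseuille peak of a 103.9 Pa/m gradient
    steady: true           # steady inflow (required by the frozen-flow run
                           # below; drop for a two-harmonic pulse at `bpm`)
outlet: {rho: 1.0, mode: dirichlet}
wall_scheme: bfl
magnets:
  - position_m: [2.75e-4, 8.1e-2, 8.0e-4]   # ~8 cm standoff on the +y side
    moment_A_m2: [0.0, 3000.0, 0.0]
particles:
  n: 30
  a_m: 6.5e-8              # magnetite core radius
  coating_m: 0.0
  chi_v: 5.7
  rho_p: 5170.0
  seed_sphere:
    center_m: [2.75e-4, 2.75e-4, 2.0e-4]
    radius_m: 1.25e-4
  min_sep_m: 5.0e-6
forces:
  gravity_on: false
  brownian_on: true
  coupling: one-way
roi:
  shape: sphere
  center_m: [2.75e-4, 4.25e-4, 8.0e-4]
  radius_m: 1.25e-4
run:
  steps: 400000            # ~8 s of physical time: one transit of the tube
  output_every: 4000
  seed: 7
  warmup_steps: 2000       # converge the flow before releasing particles
  freeze_fluid_after: 0    # steady inflow: freeze the converged flow and
  particle_dt_factor: 20   # advance particles at 20x the LB step
  output_dir: scratch/tube_targeting
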