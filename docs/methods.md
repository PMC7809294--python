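# Methods

## Model and staged loop

The simulator couples the quasi-static potential equation
`∇·(σ∇Φ) = 0` with Pennes' bioheat equation on one uniform node-centered
grid. The coupling is one-way per time step (Picard style): before every
potential solve the conductivity is refreshed from the current temperature
through `σ = σ_b (1 + α (T − T₀))`; the resulting Joule power `σ|∇Φ|²`
then drives the heat step. There is no inner σ–Φ iteration: within a pulse
the temperature, and hence σ, changes by a small fraction per step, so the
lag error is far below the discretization error.

Each pulse period is ON then OFF. The ON window is subdivided into
`thermal.dt_on_divisor` steps (default 1000, i.e. dt = t_ON/1000); each
step solves the potential (warm-started from the previous step), derives
E, J, the electrode current and the Joule source, and advances the
temperature implicitly. The OFF remainder of the period is covered by
`thermal.n_off_steps` backward-Euler steps (default one, covering the
whole rest of the period): the applied voltage is zero, so the potential
solve is bypassed and the electric variables are identically zero. For
H-FIRE the same rule applies *within* the energized window: during
inter-phase delays (V = 0) the solve is skipped while the stage remains
ON. Forcing the solve instead of bypassing changes no observable beyond
solver tolerance (this equivalence is a test).

Voltages: the anode carries the applied voltage (V/D ratio times the
electrode gap, or a directly specified voltage), the cathode 0 V. H-FIRE
negative phases put −V on the anode. Bipolar bursts tile complete
(positive, delay, negative, delay) cycles into the energized window; a
remainder shorter than one cycle stays at 0 V inside the ON stage, since
the waveform sources fix only the phase widths and the energized time.
The asymmetric phases use equal voltage magnitude on both polarities
(only the *durations* are asymmetric in the sources); a `neg_scale`
factor exposes the amplitude ratio if needed. The nanosecond rise time of
real generators is idealized as an instantaneous step — it is orders of
magnitude below any time step used. Segment lookups are left-closed /
right-open, so a query at a boundary instant resolves to the later
segment.

## Spatial discretization

Seven-point stencils on the uniform lattice; spacing `h` is a single
scalar and electrodes are rasterized by exact, boundary-inclusive
point-membership tests (a node belongs to an electrode iff its coordinate
lies in the closed solid — deterministic, and checked against a
brute-force oracle in the tests). Arbitrary-axis needles are supported by
exact point-in-cylinder tests; there is no sub-voxel anti-aliasing.

**Potential.** Face conductivities are harmonic means of the adjacent
nodal σ — flux-continuous across material interfaces, which makes the
two-slab series medium exact at the stencil level (field ratio
E₁/E₂ = σ₂/σ₁). The stencil is assembled in finite-volume form with
half-cell control volumes at the domain boundary: every face weight
carries its transverse face area (half in a boundary row, quarter at an
edge). Two consequences: the discrete surface integral of J around an
electrode is exactly conservative (anode and cathode currents agree to
solver tolerance), and in the 1D plate limit the current reproduces
σ·E·A with the *geometric* plate cross-section, not the node-count area.
Zero-flux boundaries are imposed by simply omitting the missing-neighbor
faces (equivalent to mirror nodes). Electrode nodes are Dirichlet — the
electrodes are treated as perfect electric conductors, with no Joule
generation inside them.

**Temperature.** The heat stencil uses harmonic-mean face conductivities
mixing tissue and electrode-metal κ, with uniform h³ node cells (the
thermal energy bookkeeping, `Σ ρC_p T h³`, is exactly conserved on
insulated source-free configurations). Electrode nodes conduct with the
electrode material's κ, ρ, C_p; perfusion and metabolic heat act in
tissue nodes only. Boundary faces are zero-flux except the faces of
electrodes with a positive exposed fraction, which get the convective
Robin condition toward room temperature. Electrodes protruding into the
air are modeled through this exposed-fraction tag rather than explicit
air voxels — the simulated box is tissue plus electrode solids only.

## Solvers and time stepping

Both linear systems go through one red–black SOR kernel (relaxation
factor ω = 1.8 for the potential, 1.5 for the heat step; configurable).
Convergence is declared on the relative L2 residual of the reduced
system, normalized by the effective right-hand side (sources plus
Dirichlet coupling); default tolerances are 1e−6 for the potential
(tightened to 1e−8 in the presets' smoke variants and most tests) and
1e−12 for the heat step. On small grids the relaxation solution matches a
sparse direct solve of the identical stencil to better than 1e−8
relative; the direct solve exists only as an oracle path
(`solve_potential_direct`), never as the production solver.

Time stepping is backward Euler. This is forced by the OFF stage: one
implicit step covers ~0.95 s, which violates any explicit diffusion
stability bound at realistic κ/h² by orders of magnitude. The step is
solved in increment form (unknown δ = T_new − T_old), so the right-hand
side is the per-step forcing rather than the absolute temperature level:
a steady state converges with zero iterations exactly, and the
uniform-Joule closed form ΔT = σ|E|²dt/(ρC_p) is reproduced to ~1e−12
relative — a tolerance relative to the ~310 K temperature level could not
deliver that. The implicit step is unconditionally stable and monotone
(adding a nonnegative source never cools any node), at O(dt) accuracy:
halving dt halves the error against the lumped perfusion exponential.

Charge accumulation in the driver is stage-aware: trapezoids between
samples within an ON stage plus a closing rectangle to the switch-off
instant, and nothing during OFF — Q is therefore *exactly* flat across
OFF samples, matching the physical statement that no current flows then.
(The standalone `accumulate_charge` utility is a plain cumulative
trapezoid for externally supplied series.) The Joule energy total is
accumulated the same way and balances the ρC_p-weighted temperature rise
within 2% on insulated runs.

## Dose model and optimization

A tissue node is reversibly electroporated when `|E| ≥ E_thr(n)`
(boundary-inclusive), with the threshold decaying exponentially in pulse
number: `E_thr(n) = E_inf + (E₀ − E_inf) e^(−n/τ)`. Pulse number is the
decay variable — a proxy for exposure time at fixed frequency. The
parameterization (E₀, E_inf, τ) is the package's own; `fit_threshold_decay`
recovers it from (n, threshold) pairs by least squares
(`scipy.optimize.curve_fit`), flagging constant inputs as unidentifiable.
`threshold_from_area` inverts a measured electroporated area into a field
level by bisection on the level-set area of a slice, returning the
nearest achievable level flagged when the target is not reachable within
one voxel area. Damage is the union of `|E|` above the irreversible
threshold (a second model instance, typically constant at 500 V/cm) and
`T ≥ T_crit`; `T_crit` defaults to 50 °C but is an explicit configuration
choice, not a claimed physiological constant.

`tune_pulse_number` exploits that an n-pulse simulation is exactly the
first n periods of a longer run, so one run at max(n) yields the whole
dose-response table (per-pulse electroporated volume, damage volume, and
running peak temperature). The chosen dose is the smallest n whose
reversible volume is within a configured fraction (default 1%) of the
feasible maximum, subject to damage-volume and peak-temperature
constraints; an empty feasible set returns the full table flagged rather
than raising.

## Presets and defaults

The seven built-in presets transcribe the protocol values their source
case studies print (pulse counts, ON lengths, frequencies, V/D ratios,
0.504 S/m, 19×7×1 mm plates 5 mm apart, 1 mm needles 3 mm edge-to-edge at
900 V, asymmetric 2/1/0.5 µs bursts energized 50 µs, the 500 V/cm
irreversible isoline). Domain sizes, needle lengths/insertion depths and
thermal constants are not printed in those sources; the presets use
documented soft-tissue physiology defaults (ρ = 1050 kg/m³,
C_p = 3600 J/(kg·K), κ = 0.5 W/(m·K), ω_b = 1e−3 1/s, q_m = 420 W/m³,
h = 10 W/(m²·K), stainless-steel electrode properties; raw-potato values
for the vegetal preset), each tagged `source: default` in the preset
notes so users can override them from a config file. Default grids are
desk-scale (≤ 61³ nodes); production-size grids are a config override.
The default reversible threshold model (800 → 250 V/cm, τ = 8 pulses)
spans the range reported for vegetal tissue experiments and is likewise a
documented default, not a fitted constant.

## Test strategy and problem sizes

Every numerical claim is checked against an independent oracle: linear
and series-slab closed forms and a sparse direct solve for the potential;
uniform-Joule, lumped-perfusion and Fourier-series solutions for the heat
step; brute-force nodewise scans for rasterization, level sets and
segment lookup; analytic level-set areas for the threshold inversion; and
discrete conservation identities (current in = current out, energy in =
energy stored). The suite and the acceptance script run presets in a
"smoke" variant — spacing doubled, one pulse, ON stage in ~20 steps —
chosen so the whole battery exercises every preset end-to-end in seconds
while leaving the physics contracts (conservation, determinism,
staircase) unchanged. Runs are exactly deterministic: no randomness
anywhere in the simulation path, repr-exact CSV floats, LF line endings;
repeated runs are byte-identical (wall-clock stamps live only in the log,
outside the determinism contract).

## Known limitations

- The conductivity law is temperature-only; sigmoidal field-dependent
  σ(|E|) models are out of scope, as are capacitive/transient electric
  formulations and membrane pore dynamics.
- No pH-front damage model and no Arrhenius thermal-damage integral; the
  damage observable is the field/temperature threshold union described
  above.
- Uniform grids only; no image-derived (DICOM) geometry, no adaptive
  meshing, no curved plates.
- Backward Euler is first-order in time; the per-pulse observables are
  insensitive to this, but sub-step temperature transients during a
  single microsecond-scale pulse are smoothed.
- Electrodes are perfect conductors; contact impedance and electrode
  polarization are not modeled.
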