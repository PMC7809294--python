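# epsim — electroporation treatment simulation

`epsim` is a simulator for electroporation (EP)-based tissue treatments —
electrochemotherapy (ECT), irreversible electroporation (IRE), gene
electrotransfer (GET) and high-frequency IRE (H-FIRE). It is aimed at EP
researchers who want to explore how electrode geometry, tissue properties
and pulse protocols shape the electric field, the tissue heating and the
electroporated volume, and to tune the pulse number of a protocol for
maximum electroporated tissue with minimal damage.

## Model

On a uniform 3D grid over a tissue box containing needle or plate
electrodes, each pulse period is simulated in two stages (energized
`t_ON`, rest `t_OFF`):

- **Electric potential** (quasi-static charge conservation):
  `∇·(σ∇Φ) = 0`, with Dirichlet values on electrode nodes and zero normal
  current through tissue–air surfaces; `E = −∇Φ`, `J = σE`.
- **Electrical conductivity** rises linearly with temperature:
  `σ = σ_b (1 + α (T − T₀))`, refreshed from `T` before every solve.
- **Temperature** follows Pennes' bioheat equation:
  `ρC_p ∂T/∂t = ∇·(κ∇T) − ρ_b ω_b C_b (T − T_b) + σ|∇Φ|² + q_m`,
  with convective cooling `−κ∇T·n̂ = h (T − T_r)` on exposed electrode
  surfaces and zero flux on tissue–air surfaces.
- **Observables**: electrode current `I = ∯ J·dS` through a closed surface
  around an electrode, delivered charge `Q = ∫I dt`, probe temperatures,
  and the electroporated volume — tissue where `|E|` exceeds a threshold
  that decays with pulse number `n`:
  `E_thr(n) = E_inf + (E₀ − E_inf) e^(−n/τ)`.
  Damage is the union of irreversible EP (`|E|` above a second threshold,
  e.g. 500 V/cm) and thermal excess (`T ≥ T_crit`).

During `t_OFF` (and zero-voltage instants inside an H-FIRE burst) the
potential solve is bypassed and `E ≡ 0`; only temperature and conductivity
evolve. The discretization is finite differences / finite volumes with
harmonic-mean face conductivities, red–black SOR relaxation for the
potential, and backward-Euler time stepping for the heat equation.
Monopolar trains and bipolar H-FIRE bursts (symmetric and asymmetric
positive–delay–negative phases) are supported, specified by pulse count,
ON length, frequency and voltage-to-distance ratio (V/cm) or voltage.

## Worked example

Eight 50 ms pulses at 250 V/cm and 1 Hz between two plate electrodes 4 mm
apart (conductivity 0.504 S/m), from a YAML config:

```sh
epsim run demo.yaml --out runs
```

```
run directory: runs/simulation-000001
final charge: 0.0598603 C
peak temperature: 76.799 C
electroporated volume after pulse 8: 42.875 mm^3
```

The run directory contains `config/` (the echoed configuration), `data/`
(`current.csv`, `charge.csv`, `probes.csv`, `ep_volume.csv` and legacy-VTK
field snapshots readable in Paraview) and `log/` (per-solve iteration
counts). The charge trace is a staircase: it ramps during each ON stage
and is exactly flat while no current flows. The electroporated volume
grows with pulse number because the threshold decays; here it jumps to the
whole 42.875 mm³ tissue block once the threshold falls through the uniform
250 V/cm field level.

Tuning the pulse number under the damage constraints:

```sh
epsim tune demo.yaml --n-min 1 --n-max 6
```

```
n,ep_volume_mm3,damage_volume_mm3,peak_T_C,feasible
1,0.0000,0.0000,41.284,True
2,42.8750,0.0000,45.765,True
3,42.8750,18.3750,50.418,True
...
chosen n = 2
```

Two pulses already electroporate the full block; from the third pulse
onward heating pushes tissue past `T_crit`, so n = 2 is the critical pulse
dosage — maximum electroporated volume with no damage.

Built-in case-study presets (`epsim scenario --list`) cover the classic
protocols: IRE (80 × 0.1 ms, 1 Hz, 1800 V/cm), ECT (8 × 0.1 ms, 10 Hz,
600 V/cm), GET (10 × 20 ms, 1 Hz, 300 V/cm), a two-needle GET run at
0.504 S/m, a four-needle vegetal-tissue ECT run, an H-FIRE well (900 V,
asymmetric 2/1/0.5 µs bursts energized for 50 µs) and a plate-electrode
run (19 × 7 × 1 mm plates, 5 mm apart). `epsim waveform <config>` exports
the applied-voltage waveform as CSV.

As a library, `epsim.run_simulation(epsim.scenario("IRE-plates"))` returns
a result bundle with the full time series and final fields.

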