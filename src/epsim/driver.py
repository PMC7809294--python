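"""Staged simulation loop and pulse-number dose optimization.

Each pulse period is two stages.  During the ON (energized) stage the
conductivity is refreshed from the temperature, the potential is solved by
relaxation (warm-started from the previous step), the field, current
density, electrode current and Joule source follow directly, and the
temperature advances implicitly.  During the OFF stage — and during
zero-voltage instants inside an H-FIRE burst — the potential solve is
bypassed, the electric variables are identically zero and only temperature
and conductivity evolve.  The ON stage is subdivided into
``thermal.dt_on_divisor`` implicit steps (default 1000); the OFF remainder
of the period is covered by ``thermal.n_off_steps`` steps (default one).

Everything is deterministic: identical configurations produce bit-identical
output files.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .bioheat import BioheatStepper, initialize_temperature
from .config import SimulationConfig
from .electrostatics import (conductivity_from_temperature, electric_field,
                             solve_potential)
from .errors import ConfigurationError, SolverError
from .mesh import Grid, NodeLabels, classify_boundaries, rasterize_electrodes
from .observables import (TimeSeries, damage_region, electrode_current,
                          electroporated_region, threshold_at)
from .pulses import build_waveform, voltage_at


@dataclass
class ResultBundle:
    """Everything a run produces."""

    config: SimulationConfig
    grid: Grid
    labels: NodeLabels
    series: TimeSeries
    convergence: list[tuple[float, int, int]]   # (t, laplace iters, heat iters)
    phi: np.ndarray
    T: np.ndarray
    sigma: np.ndarray
    E: np.ndarray
    J: np.ndarray
    total_joule_energy: float = 0.0             # J, deposited in tissue
    snapshots: list[Path] = field(default_factory=list)
    run_dir: Path | None = None


def _probe_indices(grid: Grid, probes: dict) -> dict[str, tuple[int, int, int]]:
    out = {}
    for name, p in probes.items():
        idx = tuple(int(round(c / grid.spacing)) for c in p)
        idx = tuple(min(max(i, 0), n - 1) for i, n in zip(idx, grid.shape))
        out[name] = idx
    return out


def run_simulation(config: SimulationConfig, outdir=None,
                   force_off_solve: bool = False) -> ResultBundle:
    """Run the staged loop over all pulses; returns a :class:`ResultBundle`.

    ``outdir``: if given, a sequentially numbered ``simulation-NNNNNN`` run
    directory is created beneath it with ``config/``, ``data/`` (CSV + VTK)
    and ``log/``.  ``force_off_solve`` keeps the Laplace solve active during
    zero-voltage instants (a debugging path; observationally equivalent to
    the bypass within solver tolerance).
    """
    config.validate()
    grid = config.build_grid()
    labels = classify_boundaries(
        grid, rasterize_electrodes(grid, config.electrodes), config.electrodes)
    wave = build_waveform(config.protocol)
    params = config.params
    stepper = BioheatStepper(grid, labels, config.electrodes, params,
                             tol=config.thermal.implicit_tol)
    probes_idx = _probe_indices(grid, config.output.probes)
    tissue = labels.tissue_mask
    h3 = grid.node_volume

    run_dir = None
    log_lines: list[str] = []
    if outdir is not None:
        run_dir = io_formats.next_run_dir(outdir)
        io_formats.save_config(config, run_dir / "config" / "config.yaml")
        for d in config.defaults_used:
            log_lines.append(f"default: {d}")

    T = initialize_temperature(grid, params)
    sigma = conductivity_from_temperature(T, params.sigma_b, params.alpha,
                                          params.t_ref)
    phi = np.zeros(grid.shape)
    e_vec = np.zeros((3,) + grid.shape)
    j_vec = np.zeros((3,) + grid.shape)
    e_mag_pulse = np.zeros(grid.shape)   # field of the last energized solve

    proto = config.protocol
    dt_on = proto.t_on / config.thermal.dt_on_divisor
    t_off_total = proto.period - proto.t_on
    dt_off = t_off_total / config.thermal.n_off_steps

    samples: dict[str, list] = {k: [] for k in
                                ("t", "I", "Ic", "Q", "P", "on", "pulse")}
    probe_samples: dict[str, list] = {n: [] for n in probes_idx}
    convergence: list[tuple[float, int, int]] = []
    pulses, ep_vol, ep_thr, dmg_vol, peak_t = [], [], [], [], []
    snapshots: list[Path] = []
    charge = 0.0
    energy = 0.0

    def record(t, cur_a, cur_c, power, on, pulse_k):
        samples["t"].append(t)
        samples["I"].append(cur_a)
        samples["Ic"].append(cur_c)
        samples["Q"].append(charge)
        samples["P"].append(power)
        samples["on"].append(on)
        samples["pulse"].append(pulse_k)
        for name, idx in probes_idx.items():
            probe_samples[name].append(float(T[idx]))

    def snapshot(tag):
        if run_dir is None or not config.output.snapshots:
            return
        data_dir = run_dir / "data"
        for fname, arr in (("phi", phi), ("T", T), ("sigma", sigma),
                           ("E", e_vec)):
            path = data_dir / f"{fname}_{tag}.vtk"
            io_formats.write_vtk(path, grid, fname, arr)
            snapshots.append(path)

    t_wall0 = _time.time()
    try:
        for k in range(1, proto.n_pulses + 1):
            t0 = (k - 1) * proto.period
            pulse_peak = float(T.max())
            prev_i = 0.0
            # ---- ON (energized) stage ------------------------------------
            for j in range(config.thermal.dt_on_divisor):
                t_left = t0 + j * dt_on
                v = voltage_at(wave, t_left)
                if v != 0.0 or force_off_solve:
                    sigma = conductivity_from_temperature(
                        T, params.sigma_b, params.alpha, params.t_ref)
                    phi, it_lap = solve_potential(
                        grid, labels, sigma, v, 0.0, config.solver, phi0=phi)
                    e_vec = electric_field(phi, grid)
                    j_vec = sigma * e_vec
                    cur_a = electrode_current(phi, sigma, grid, labels,
                                              "anode")
                    cur_c = electrode_current(phi, sigma, grid, labels,
                                              "cathode")
                    e_sq = np.sum(e_vec ** 2, axis=0)
                    joule = sigma * e_sq
                    power = float(np.sum(joule[tissue])) * h3
                    if v != 0.0:
                        e_mag_pulse = np.sqrt(e_sq)
                else:
                    phi.fill(0.0)
                    e_vec.fill(0.0)
                    j_vec.fill(0.0)
                    cur_a = cur_c = 0.0
                    joule = 0.0
                    power = 0.0
                    it_lap = 0
                if j > 0:
                    charge += 0.5 * (prev_i + cur_a) * dt_on
                    energy += 0.5 * (prev_p + power) * dt_on
                record(t_left, cur_a, cur_c, power, True, k)
                prev_i, prev_p = cur_a, power
                T, it_heat = stepper.step(T, dt_on, joule)
                convergence.append((t_left, it_lap, it_heat))
                pulse_peak = max(pulse_peak, float(T.max()))
            # trailing rectangle up to the switch-off instant
            charge += prev_i * dt_on
            energy += prev_p * dt_on

            # ---- per-pulse dose observables ------------------------------
            thr = threshold_at(config.reversible, k)
            region = electroporated_region(e_mag_pulse, thr, grid, tissue)
            dmg = damage_region(e_mag_pulse,
                                threshold_at(config.irreversible, k), T,
                                config.t_crit, grid, tissue)
            pulses.append(k)
            ep_vol.append(region.volume)
            ep_thr.append(thr)
            dmg_vol.append(dmg.volume)
            snapshot(f"pulse{k:04d}_on")

            # ---- OFF stage ----------------------------------------------
            for j in range(config.thermal.n_off_steps):
                t_left = t0 + proto.t_on + j * dt_off
                if force_off_solve:
                    sigma = conductivity_from_temperature(
                        T, params.sigma_b, params.alpha, params.t_ref)
                    phi, it_lap = solve_potential(
                        grid, labels, sigma, 0.0, 0.0, config.solver,
                        phi0=phi)
                    e_vec = electric_field(phi, grid)
                    j_vec = sigma * e_vec
                    cur_a = electrode_current(phi, sigma, grid, labels,
                                              "anode")
                    cur_c = electrode_current(phi, sigma, grid, labels,
                                              "cathode")
                else:
                    phi.fill(0.0)
                    e_vec.fill(0.0)
                    j_vec.fill(0.0)
                    cur_a = cur_c = 0.0
                    it_lap = 0
                record(t_left, cur_a, cur_c, 0.0, False, k)
                T, it_heat = stepper.step(T, dt_off, 0.0)
                convergence.append((t_left, it_lap, it_heat))
                pulse_peak = max(pulse_peak, float(T.max()))
            peak_t.append(pulse_peak)
            snapshot(f"pulse{k:04d}_off")
            sigma = conductivity_from_temperature(T, params.sigma_b,
                                                  params.alpha, params.t_ref)
    except SolverError as exc:
        raise SolverError(
            f"{exc} (at simulation time t = "
            f"{samples['t'][-1] if samples['t'] else 0.0:.6g} s)",
            residual=exc.residual, iterations=exc.iterations) from exc

    record(proto.duration, 0.0, 0.0, 0.0, False, proto.n_pulses)

    series = TimeSeries(
        t=np.asarray(samples["t"]), current=np.asarray(samples["I"]),
        current_cathode=np.asarray(samples["Ic"]),
        charge=np.asarray(samples["Q"]), power=np.asarray(samples["P"]),
        on=np.asarray(samples["on"], bool),
        pulse=np.asarray(samples["pulse"], int),
        probes={n: np.asarray(v) for n, v in probe_samples.items()},
        pulses=np.asarray(pulses, int), ep_volume=np.asarray(ep_vol),
        ep_threshold=np.asarray(ep_thr), damage_volume=np.asarray(dmg_vol),
        peak_temperature=np.asarray(peak_t))

    bundle = ResultBundle(config=config, grid=grid, labels=labels,
                          series=series, convergence=convergence, phi=phi,
                          T=T, sigma=sigma, E=e_vec, J=j_vec,
                          total_joule_energy=energy, snapshots=snapshots,
                          run_dir=run_dir)

    if run_dir is not None:
        io_formats.write_timeseries_csvs(series, run_dir / "data")
        log_lines.append(f"wall_clock_s: {_time.time() - t_wall0:.3f}")
        log_lines.append(f"solves: {len(convergence)}")
        log_lines.append("t_s,laplace_iters,heat_iters")
        log_lines += [f"{t:.9g},{a},{b}" for t, a, b in convergence]
        (run_dir / "log" / "run.log").write_text("\n".join(log_lines) + "\n",
                                                 encoding="utf-8")
    return bundle


@dataclass
class DoseResponse:
    """Dose-response table over pulse number and the chosen dose."""

    n: np.ndarray
    ep_volume: np.ndarray
    damage_volume: np.ndarray
    peak_temperature: np.ndarray
    chosen_n: int | None
    feasible: np.ndarray
    flagged: bool = False


def select_pulse_number(n, ep_volume, damage_volume, peak_temperature,
                        max_damage_volume=None, max_temperature=None,
                        within: float = 0.01) -> DoseResponse:
    """Pick the critical pulse dosage from a dose-response table.

    Feasible rows respect the damage-volume and peak-temperature
    constraints; among them the chosen n is the smallest whose
    electroporated volume is within ``within`` (fraction) of the feasible
    maximum.  An empty feasible set returns a flagged result with the full
    table, not an exception.
    """
    n = np.asarray(n, int)
    ep = np.asarray(ep_volume, float)
    dmg = np.asarray(damage_volume, float)
    pt = np.asarray(peak_temperature, float)
    feasible = np.ones(len(n), dtype=bool)
    if max_damage_volume is not None:
        feasible &= dmg <= max_damage_volume
    if max_temperature is not None:
        feasible &= pt <= max_temperature
    if not feasible.any():
        return DoseResponse(n=n, ep_volume=ep, damage_volume=dmg,
                            peak_temperature=pt, chosen_n=None,
                            feasible=feasible, flagged=True)
    best = float(ep[feasible].max())
    ok = feasible & (ep >= (1.0 - within) * best)
    chosen = int(n[ok][0])
    return DoseResponse(n=n, ep_volume=ep, damage_volume=dmg,
                        peak_temperature=pt, chosen_n=chosen,
                        feasible=feasible)


def tune_pulse_number(config: SimulationConfig, n_range,
                      max_damage_volume=None, max_temperature=None,
                      within: float = 0.01) -> DoseResponse:
    """Dose-response sweep over pulse number.

    A run with n pulses is exactly the first n periods of a longer run
    (the loop is deterministic and history-independent beyond its state), so
    one simulation at max(n_range) yields every row of the table; peak
    temperature up to pulse n is the running maximum.
    """
    n_range = sorted(int(n) for n in n_range)
    if not n_range or n_range[0] < 1:
        raise ConfigurationError("n_range must contain pulse counts >= 1")
    n_max = n_range[-1]
    from dataclasses import replace
    cfg = replace(config, protocol=replace(config.protocol, n_pulses=n_max))
    bundle = run_simulation(cfg)
    s = bundle.series
    running_peak = np.maximum.accumulate(s.peak_temperature)
    rows = [list(s.pulses).index(nv) for nv in n_range]
    return select_pulse_number(
        np.asarray(n_range), s.ep_volume[rows], s.damage_volume[rows],
        running_peak[rows], max_damage_volume=max_damage_volume,
        max_temperature=max_temperature, within=within)
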