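"""Simulation configuration: schema, validation and unit conversion.

Configurations are plain YAML/dict trees in the field's customary units
(millimeters, V/cm, microseconds); ``from_dict`` converts everything to SI,
rejects unknown keys and reports *all* schema violations at once.  The
``to_dict`` echo reproduces the configuration units so a config round-trips
through load/save.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .bioheat import PhysicalParameters
from .electrostatics import SolverSettings
from .errors import ConfigurationError
from .mesh import (ElectrodeGeometry, ElectrodeMaterial, Grid, build_grid)
from .observables import ThresholdModel
from .pulses import HFireSpec, MONOPOLAR, PulseProtocol


@dataclass
class OutputOptions:
    snapshots: bool = True
    probes: dict[str, tuple[float, float, float]] = field(default_factory=dict)


@dataclass
class ThermalOptions:
    dt_on_divisor: int = 1000   # ON stage substeps (paper-style default)
    n_off_steps: int = 1        # OFF stage covered by one implicit step
    implicit_tol: float = 1e-12

    def __post_init__(self):
        if self.dt_on_divisor < 1 or self.n_off_steps < 1:
            raise ConfigurationError("thermal step counts must be >= 1")
        if self.implicit_tol <= 0:
            raise ConfigurationError("implicit_tol must be positive")


@dataclass
class SimulationConfig:
    """Validated, SI-unit simulation setup."""

    extent: tuple[float, float, float]       # m
    spacing: float                           # m
    electrodes: list[ElectrodeGeometry]
    protocol: PulseProtocol
    params: PhysicalParameters = field(default_factory=PhysicalParameters)
    solver: SolverSettings = field(default_factory=SolverSettings)
    thermal: ThermalOptions = field(default_factory=ThermalOptions)
    reversible: ThresholdModel = field(
        default_factory=lambda: ThresholdModel(e0=8e4, e_inf=2.5e4, tau=8.0))
    irreversible: ThresholdModel = field(
        default_factory=lambda: ThresholdModel.constant(5e4))
    t_crit: float = 50.0                     # degC, thermal-damage cutoff
    output: OutputOptions = field(default_factory=OutputOptions)
    name: str = "simulation"
    notes: dict = field(default_factory=dict)
    defaults_used: list[str] = field(default_factory=list)

    def build_grid(self) -> Grid:
        return build_grid(self.extent, self.spacing)

    def validate(self) -> None:
        """Cross-field validation; raises one aggregated error."""
        errors: list[str] = []
        grid = None
        try:
            grid = self.build_grid()
        except ConfigurationError as exc:
            errors.append(str(exc))
        if not any(e.polarity == "anode" for e in self.electrodes):
            errors.append("no anode electrode configured")
        if not any(e.polarity == "cathode" for e in self.electrodes):
            errors.append("no cathode electrode configured")
        if grid is not None:
            hi = np.asarray(grid.extent)
            for i, el in enumerate(self.electrodes):
                lo_b, hi_b = el.bounds()
                if np.any(hi_b < 0) or np.any(lo_b > hi):
                    errors.append(f"electrode {i} lies outside the domain")
            for pname, p in self.output.probes.items():
                if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > hi):
                    errors.append(f"probe {pname!r} lies outside the domain")
        if errors:
            raise ConfigurationError(
                "invalid configuration: " + "; ".join(errors))


class _DictReader:
    """Tracks consumed keys, collected errors and defaulted values."""

    def __init__(self, data: dict, path: str, errors: list[str],
                 defaults: list[str]):
        self.data = data or {}
        self.path = path
        self.errors = errors
        self.defaults = defaults
        self.seen: set[str] = set()

    def get(self, key, default=..., required=False):
        self.seen.add(key)
        if key in self.data:
            return self.data[key]
        if required:
            self.errors.append(f"missing required key {self.path}{key}")
            return None
        if default is not ...:
            self.defaults.append(f"{self.path}{key} = {default!r}")
            return default
        return None

    def sub(self, key) -> "_DictReader":
        self.seen.add(key)
        val = self.data.get(key, {})
        if val is not None and not isinstance(val, dict):
            self.errors.append(f"{self.path}{key} must be a mapping")
            val = {}
        return _DictReader(val, f"{self.path}{key}.", self.errors,
                           self.defaults)

    def finish(self):
        unknown = set(self.data) - self.seen
        for key in sorted(unknown):
            self.errors.append(f"unknown key {self.path}{key}")


def _electrode_from_dict(d: dict, idx: int, errors, defaults
                         ) -> ElectrodeGeometry | None:
    r = _DictReader(d, f"electrodes[{idx}].", errors, defaults)
    kind = r.get("kind", required=True)
    center = r.get("center_mm", required=True)
    polarity = r.get("polarity", required=True)
    exposed = r.get("exposed_fraction", 0.0)
    mat = r.sub("material")
    material = ElectrodeMaterial(kappa=mat.get("kappa", 15.0),
                                 rho=mat.get("rho", 7900.0),
                                 cp=mat.get("cp", 500.0))
    mat.finish()
    kwargs = {}
    if kind == "needle":
        kwargs["radius"] = r.get("radius_mm", required=True)
        kwargs["length"] = r.get("length_mm", required=True)
        kwargs["axis"] = tuple(r.get("axis", [0, 0, 1]))
        if kwargs["radius"] is not None:
            kwargs["radius"] = units.mm_to_m(kwargs["radius"])
        if kwargs["length"] is not None:
            kwargs["length"] = units.mm_to_m(kwargs["length"])
    elif kind == "plate":
        dims = r.get("dims_mm", required=True)
        if dims is not None:
            kwargs["dims"] = tuple(units.mm_to_m(v) for v in dims)
    r.finish()
    if errors or center is None:
        return None
    try:
        return ElectrodeGeometry(
            kind=kind, center=tuple(units.mm_to_m(v) for v in center),
            polarity=polarity, exposed_fraction=exposed, material=material,
            **kwargs)
    except ConfigurationError as exc:
        errors.append(f"electrodes[{idx}]: {exc}")
        return None


def _threshold_from_dict(r: _DictReader, default: ThresholdModel
                         ) -> ThresholdModel:
    e0 = r.get("e0_v_per_cm", units.v_per_m_to_v_per_cm(default.e0))
    e_inf = r.get("einf_v_per_cm", units.v_per_m_to_v_per_cm(default.e_inf))
    tau = r.get("tau_pulses", default.tau)
    r.finish()
    try:
        return ThresholdModel(e0=units.v_per_cm_to_v_per_m(e0),
                              e_inf=units.v_per_cm_to_v_per_m(e_inf), tau=tau)
    except ConfigurationError as exc:
        r.errors.append(f"{r.path[:-1]}: {exc}")
        return default


def from_dict(data: dict) -> SimulationConfig:
    """Parse a configuration dict (config units) into an SI config.

    Raises one :class:`ConfigurationError` listing every offending key.
    """
    errors: list[str] = []
    defaults: list[str] = []
    root = _DictReader(data, "", errors, defaults)

    name = root.get("name", "simulation")

    dom = root.sub("domain")
    extent_mm = dom.get("extent_mm", required=True)
    spacing_mm = dom.get("spacing_mm", required=True)
    dom.finish()

    root.seen.add("electrodes")
    el_list = data.get("electrodes") or []
    electrodes = []
    for i, ed in enumerate(el_list):
        el = _electrode_from_dict(ed, i, errors, defaults)
        if el is not None:
            electrodes.append(el)

    pr = root.sub("protocol")
    n_pulses = pr.get("n_pulses", required=True)
    t_on = pr.get("t_on_s", required=True)
    freq = pr.get("freq_hz", required=True)
    v_per_cm = pr.get("v_per_cm")
    gap_mm = pr.get("gap_mm")
    voltage = pr.get("voltage_v")
    waveform = pr.get("waveform", MONOPOLAR)
    hf = pr.sub("hfire")
    hfire = None
    if waveform != MONOPOLAR:
        pos = hf.get("pos_us", required=True)
        delay = hf.get("delay_us", required=True)
        neg = hf.get("neg_us", required=True)
        energized = hf.get("energized_us", required=True)
        neg_scale = hf.get("neg_scale", 1.0)
        if None not in (pos, delay, neg, energized):
            try:
                hfire = HFireSpec(pos=pos * units.US, delay=delay * units.US,
                                  neg=neg * units.US,
                                  energized=energized * units.US,
                                  neg_scale=neg_scale)
            except ConfigurationError as exc:
                errors.append(f"protocol.hfire: {exc}")
    hf.finish()
    pr.finish()

    pp = root.sub("params")
    try:
        params = PhysicalParameters(
            sigma_b=pp.get("sigma_b", 0.2),
            alpha=pp.get("alpha", 0.02),
            t_ref=pp.get("t_ref_c", 37.0),
            rho=pp.get("rho", 1050.0),
            cp=pp.get("cp", 3600.0),
            kappa=pp.get("kappa", 0.5),
            q_m=pp.get("q_m", 420.0),
            rho_b=pp.get("rho_b", 1060.0),
            omega_b=pp.get("omega_b", 1e-3),
            c_b=pp.get("c_b", 3600.0),
            t_b=pp.get("t_b_c", 37.0),
            h_conv=pp.get("h_conv", 10.0),
            t_room=pp.get("t_room_c", 25.0),
            t_init=pp.get("t_init_c", 37.0))
    except ConfigurationError as exc:
        errors.append(f"params: {exc}")
        params = PhysicalParameters()
    pp.finish()

    so = root.sub("solver")
    try:
        solver = SolverSettings(tol=so.get("tol", 1e-6),
                                max_iter=so.get("max_iter", 50000),
                                omega=so.get("omega", 1.8))
    except ConfigurationError as exc:
        errors.append(f"solver: {exc}")
        solver = SolverSettings()
    so.finish()

    th = root.sub("thermal")
    try:
        thermal = ThermalOptions(
            dt_on_divisor=th.get("dt_on_divisor", 1000),
            n_off_steps=th.get("n_off_steps", 1),
            implicit_tol=th.get("implicit_tol", 1e-12))
    except ConfigurationError as exc:
        errors.append(f"thermal: {exc}")
        thermal = ThermalOptions()
    th.finish()

    tr = root.sub("thresholds")
    reversible = _threshold_from_dict(
        tr.sub("reversible"), ThresholdModel(e0=8e4, e_inf=2.5e4, tau=8.0))
    irreversible = _threshold_from_dict(
        tr.sub("irreversible"), ThresholdModel.constant(5e4))
    t_crit = tr.get("t_crit_c", 50.0)
    tr.finish()

    out = root.sub("output")
    snapshots = out.get("snapshots", True)
    root_probes = out.get("probes_mm", {}) or {}
    probes = {str(k): tuple(units.mm_to_m(v) for v in p)
              for k, p in root_probes.items()}
    out.finish()
    root.seen.add("notes")
    notes = data.get("notes", {}) or {}
    root.finish()

    protocol = None
    if None not in (n_pulses, t_on, freq):
        try:
            protocol = PulseProtocol(
                n_pulses=n_pulses, t_on=t_on, frequency=freq,
                voltage_to_distance=(units.v_per_cm_to_v_per_m(v_per_cm)
                                     if v_per_cm is not None else None),
                gap=(units.mm_to_m(gap_mm) if gap_mm is not None else None),
                voltage=voltage, waveform=waveform, hfire=hfire)
        except ConfigurationError as exc:
            errors.append(f"protocol: {exc}")

    if errors:
        raise ConfigurationError(
            "invalid configuration: " + "; ".join(errors))

    cfg = SimulationConfig(
        extent=tuple(units.mm_to_m(v) for v in extent_mm),
        spacing=units.mm_to_m(spacing_mm),
        electrodes=electrodes, protocol=protocol, params=params,
        solver=solver, thermal=thermal, reversible=reversible,
        irreversible=irreversible, t_crit=t_crit,
        output=OutputOptions(snapshots=snapshots, probes=probes),
        name=name, notes=notes, defaults_used=defaults)
    cfg.validate()
    return cfg


def to_dict(cfg: SimulationConfig) -> dict:
    """Echo the configuration back in config units (mm, V/cm, us)."""
    p = cfg.protocol
    proto: dict = {"n_pulses": p.n_pulses, "t_on_s": p.t_on,
                   "freq_hz": p.frequency, "waveform": p.waveform}
    if p.voltage is not None:
        proto["voltage_v"] = p.voltage
    if p.voltage_to_distance is not None:
        proto["v_per_cm"] = units.v_per_m_to_v_per_cm(p.voltage_to_distance)
    if p.gap is not None:
        proto["gap_mm"] = units.m_to_mm(p.gap)
    if p.hfire is not None:
        proto["hfire"] = {"pos_us": p.hfire.pos / units.US,
                          "delay_us": p.hfire.delay / units.US,
                          "neg_us": p.hfire.neg / units.US,
                          "energized_us": p.hfire.energized / units.US,
                          "neg_scale": p.hfire.neg_scale}
    electrodes = []
    for el in cfg.electrodes:
        ed: dict = {"kind": el.kind,
                    "center_mm": [units.m_to_mm(v) for v in el.center],
                    "polarity": el.polarity,
                    "exposed_fraction": el.exposed_fraction,
                    "material": {"kappa": el.material.kappa,
                                 "rho": el.material.rho,
                                 "cp": el.material.cp}}
        if el.kind == "needle":
            ed["radius_mm"] = units.m_to_mm(el.radius)
            ed["length_mm"] = units.m_to_mm(el.length)
            ed["axis"] = list(el.axis)
        else:
            ed["dims_mm"] = [units.m_to_mm(v) for v in el.dims]
        electrodes.append(ed)
    pa = cfg.params

    def thr(model: ThresholdModel) -> dict:
        return {"e0_v_per_cm": units.v_per_m_to_v_per_cm(model.e0),
                "einf_v_per_cm": units.v_per_m_to_v_per_cm(model.e_inf),
                "tau_pulses": model.tau}

    return {
        "name": cfg.name,
        "domain": {"extent_mm": [units.m_to_mm(v) for v in cfg.extent],
                   "spacing_mm": units.m_to_mm(cfg.spacing)},
        "electrodes": electrodes,
        "protocol": proto,
        "params": {"sigma_b": pa.sigma_b, "alpha": pa.alpha,
                   "t_ref_c": pa.t_ref, "rho": pa.rho, "cp": pa.cp,
                   "kappa": pa.kappa, "q_m": pa.q_m, "rho_b": pa.rho_b,
                   "omega_b": pa.omega_b, "c_b": pa.c_b, "t_b_c": pa.t_b,
                   "h_conv": pa.h_conv, "t_room_c": pa.t_room,
                   "t_init_c": pa.t_init},
        "solver": {"tol": cfg.solver.tol, "max_iter": cfg.solver.max_iter,
                   "omega": cfg.solver.omega},
        "thermal": {"dt_on_divisor": cfg.thermal.dt_on_divisor,
                    "n_off_steps": cfg.thermal.n_off_steps,
                    "implicit_tol": cfg.thermal.implicit_tol},
        "thresholds": {"reversible": thr(cfg.reversible),
                       "irreversible": thr(cfg.irreversible),
                       "t_crit_c": cfg.t_crit},
        "output": {"snapshots": cfg.output.snapshots,
                   "probes_mm": {k: [units.m_to_mm(v) for v in pt]
                                 for k, pt in cfg.output.probes.items()}},
        "notes": dict(cfg.notes),
    }
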