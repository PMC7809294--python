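"""Ready-to-run case-study presets and synthetic test fixtures.

Seven presets cover the classic electroporation protocols: the Table-style
IRE / ECT / GET pulse trains, a gene-electrotransfer run with two needle
electrodes, a vegetal-tissue (potato) multi-needle ECT run, an H-FIRE well
with bipolar asymmetric bursts, and a plate-electrode run.  Protocol
numbers that the source case studies print (pulse counts, widths,
frequencies, V/D ratios, the 0.504 S/m conductivity, plate and needle
dimensions, the 900 V H-FIRE amplitude and 500 V/cm irreversible isoline)
are transcribed exactly; domain sizes and thermal constants are documented
physiology defaults, tagged ``source: default`` in each preset's notes so
they can be overridden from a config file.

All presets are desk-scale (at most ~61^3 nodes) so a workstation can sweep
them; production-size grids are a config override away.
"""

from __future__ import annotations

import numpy as np

from . import config as config_mod
from .config import from_dict
from .errors import ConfigurationError
from .mesh import Grid

_TABLE_PROTOCOLS = {
    # protocol: (n_pulses, t_on s, frequency Hz, V/D ratio V/cm)
    "IRE": (80, 0.0001, 1.0, 1800.0),
    "ECT": (8, 0.0001, 10.0, 600.0),
    "GET": (10, 0.02, 1.0, 300.0),
}

_DEFAULT_NOTES = {
    "domain": "source: default (desk-scale box)",
    "thermal_params": "source: default (soft-tissue physiology)",
    "thresholds": "source: default (reversible decay); irreversible 500 V/cm",
}


def _two_needle_electrodes(gap_mm: float, radius_mm: float = 0.5,
                           length_mm: float = 8.0, center=(10.0, 10.0, 5.0),
                           exposed: float = 0.2):
    cx, cy, cz = center
    half = gap_mm / 2.0
    return [
        {"kind": "needle", "center_mm": [cx - half, cy, cz],
         "radius_mm": radius_mm, "length_mm": length_mm, "axis": [0, 0, 1],
         "polarity": "anode", "exposed_fraction": exposed},
        {"kind": "needle", "center_mm": [cx + half, cy, cz],
         "radius_mm": radius_mm, "length_mm": length_mm, "axis": [0, 0, 1],
         "polarity": "cathode", "exposed_fraction": exposed},
    ]


def _table_preset(protocol: str):
    n, t_on, freq, vd = _TABLE_PROTOCOLS[protocol]
    gap = 8.0
    return {
        "name": f"{protocol}-table1",
        "domain": {"extent_mm": [20.0, 20.0, 10.0], "spacing_mm": 0.5},
        "electrodes": _two_needle_electrodes(gap),
        "protocol": {"n_pulses": n, "t_on_s": t_on, "freq_hz": freq,
                     "v_per_cm": vd, "gap_mm": gap},
        "output": {"probes_mm": {"mid": [10.0, 10.0, 5.0]}},
        "notes": dict(_DEFAULT_NOTES,
                      protocol=f"{protocol} train: source: printed table"),
    }


def _get_needles_lackovic():
    gap = 6.0
    d = {
        "name": "GET-needles-lackovic",
        "domain": {"extent_mm": [16.0, 12.0, 10.0], "spacing_mm": 0.5},
        "electrodes": _two_needle_electrodes(gap, radius_mm=0.5,
                                             length_mm=8.0,
                                             center=(8.0, 6.0, 5.0)),
        "protocol": {"n_pulses": 8, "t_on_s": 0.05, "freq_hz": 1.0,
                     "v_per_cm": 250.0, "gap_mm": gap},
        "params": {"sigma_b": 0.504},
        # probe line between the electrodes: at the electrode surface,
        # quarter gap and mid gap
        "output": {"probes_mm": {"T1": [6.0, 6.0, 5.0],
                                 "T2": [6.75, 6.0, 5.0],
                                 "T3": [8.0, 6.0, 5.0]}},
        "notes": dict(_DEFAULT_NOTES,
                      protocol="250 V/cm, 8 x 50 ms, 1 Hz, sigma 0.504 S/m: "
                               "source: printed",
                      needle_length="source: default (supplement-only)"),
    }
    return d


def _ect_potato_4needle():
    # four needles on a 6 mm square, opposite-side polarities
    side = 6.0
    c = (10.0, 10.0, 2.5)
    els = []
    for sx, sy, pol in ((-1, -1, "anode"), (-1, 1, "anode"),
                        (1, -1, "cathode"), (1, 1, "cathode")):
        els.append({"kind": "needle",
                    "center_mm": [c[0] + sx * side / 2,
                                  c[1] + sy * side / 2, c[2]],
                    "radius_mm": 0.5, "length_mm": 4.0, "axis": [0, 0, 1],
                    "polarity": pol, "exposed_fraction": 0.2})
    return {
        "name": "ECT-potato-4needle",
        "domain": {"extent_mm": [20.0, 20.0, 5.0], "spacing_mm": 0.5},
        "electrodes": els,
        "protocol": {"n_pulses": 32, "t_on_s": 1e-4, "freq_hz": 1.0,
                     "v_per_cm": 1500.0, "gap_mm": side},
        "params": {"sigma_b": 0.05, "alpha": 0.015, "t_ref_c": 22.0,
                   "t_init_c": 22.0, "t_b_c": 22.0, "omega_b": 0.0,
                   "q_m": 0.0, "rho": 1090.0, "cp": 3500.0, "kappa": 0.55},
        "output": {"probes_mm": {"center": [10.0, 10.0, 2.5]}},
        "notes": dict(_DEFAULT_NOTES,
                      protocol="100 us pulses at 1 Hz, 1500 V/cm, up to 32 "
                               "pulses: source: printed",
                      params="raw-potato values: source: default"),
    }


def _hfire_well():
    # two 1 mm needles, 3 mm edge-to-edge (4 mm center-to-center), 900 V,
    # asymmetric 2/1/0.5 us bursts energized for 50 us
    gap_centers = 4.0
    return {
        "name": "HFIRE-well",
        "domain": {"extent_mm": [10.0, 10.0, 10.0], "spacing_mm": 0.25},
        "electrodes": _two_needle_electrodes(gap_centers, radius_mm=0.5,
                                             length_mm=8.0,
                                             center=(5.0, 5.0, 5.0),
                                             exposed=0.2),
        "protocol": {"n_pulses": 100, "t_on_s": 50e-6, "freq_hz": 1.0,
                     "voltage_v": 900.0, "waveform": "hfire-asymmetric",
                     "hfire": {"pos_us": 2.0, "delay_us": 1.0,
                               "neg_us": 0.5, "energized_us": 50.0}},
        "thresholds": {"irreversible": {"e0_v_per_cm": 500.0,
                                        "einf_v_per_cm": 500.0,
                                        "tau_pulses": 1.0}},
        "output": {"probes_mm": {"mid": [5.0, 5.0, 5.0]}},
        "notes": dict(_DEFAULT_NOTES,
                      protocol="900 V asymmetric 2/1/0.5 us bursts, "
                               "energized 50 us, 1 mm electrodes 3 mm "
                               "edge-to-edge: source: printed"),
    }


def _ire_plates():
    # two 19 x 7 x 1 mm plates separated by 5 mm; the tissue box fills the
    # inter-plate volume with a margin around the plates
    return {
        "name": "IRE-plates",
        "domain": {"extent_mm": [7.0, 25.0, 13.0], "spacing_mm": 0.5},
        "electrodes": [
            {"kind": "plate", "center_mm": [0.5, 12.5, 6.5],
             "dims_mm": [1.0, 19.0, 7.0], "polarity": "anode",
             "exposed_fraction": 0.5},
            {"kind": "plate", "center_mm": [6.5, 12.5, 6.5],
             "dims_mm": [1.0, 19.0, 7.0], "polarity": "cathode",
             "exposed_fraction": 0.5},
        ],
        "protocol": {"n_pulses": 8, "t_on_s": 0.05, "freq_hz": 1.0,
                     "v_per_cm": 250.0, "gap_mm": 5.0},
        "params": {"sigma_b": 0.504},
        "output": {"probes_mm": {"mid": [3.5, 12.5, 6.5]}},
        "notes": dict(_DEFAULT_NOTES,
                      protocol="250 V/cm, 8 x 50 ms, 1 Hz; 19x7x1 mm plates "
                               "5 mm apart: source: printed"),
    }


_BUILDERS = {
    "IRE-table1": lambda: _table_preset("IRE"),
    "ECT-table1": lambda: _table_preset("ECT"),
    "GET-table1": lambda: _table_preset("GET"),
    "GET-needles-lackovic": _get_needles_lackovic,
    "ECT-potato-4needle": _ect_potato_4needle,
    "HFIRE-well": _hfire_well,
    "IRE-plates": _ire_plates,
}

SCENARIO_NAMES = tuple(sorted(_BUILDERS))


def scenario_dict(name: str) -> dict:
    """Raw configuration dict of a preset (config units, overridable)."""
    if name not in _BUILDERS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid names: "
            f"{', '.join(SCENARIO_NAMES)}")
    return _BUILDERS[name]()


def scenario(name: str) -> config_mod.SimulationConfig:
    """Validated configuration of a named preset."""
    return from_dict(scenario_dict(name))


def hfire_well_preset() -> config_mod.SimulationConfig:
    """The H-FIRE well case: bipolar asymmetric bursts between two needles."""
    return scenario("HFIRE-well")


def smoke_config(name: str, coarsen: int = 2, n_pulses: int = 1,
                 dt_on_divisor: int = 20,
                 tol: float = 1e-8) -> config_mod.SimulationConfig:
    """Coarsened short variant of a preset for smoke runs.

    Doubles (by default) the grid spacing, truncates the train to one pulse
    and reduces the ON-stage subdivision; used by the test suite to exercise
    every preset end-to-end in seconds.
    """
    d = scenario_dict(name)
    d["domain"]["spacing_mm"] *= coarsen
    d["protocol"]["n_pulses"] = n_pulses
    d.setdefault("thermal", {})["dt_on_divisor"] = dt_on_divisor
    d.setdefault("solver", {})["tol"] = tol
    d.setdefault("output", {})["snapshots"] = False
    return from_dict(d)


def make_synthetic_field(kind: str, grid: Grid, **params) -> np.ndarray:
    """Analytic fields with known gradients/level sets, for oracle tests.

    kinds: ``uniform`` (value), ``linear`` (slope a along x: Phi = a x),
    ``radial`` (|E| = c / r around an in-plane axis at center, clipped at
    r_min), ``two-slab`` (sigma1 for x below the midplane, sigma2 above).
    """
    x, y, z = grid.node_coords()
    if kind == "uniform":
        return np.full(grid.shape, float(params.get("value", 1.0)))
    if kind == "linear":
        return float(params.get("a", 1.0)) * x
    if kind == "radial":
        c = float(params.get("c", 1.0))
        cx = params.get("center", tuple(e / 2 for e in grid.extent))
        r = np.sqrt((x - cx[0]) ** 2 + (y - cx[1]) ** 2)
        r_min = float(params.get("r_min", grid.spacing / 2))
        return c / np.maximum(r, r_min)
    if kind == "two-slab":
        s1 = float(params.get("sigma1", 0.2))
        s2 = float(params.get("sigma2", 0.6))
        mid = grid.extent[0] / 2.0
        return np.where(x < mid - 1e-12, s1, s2)
    raise ConfigurationError(f"unknown synthetic field kind {kind!r}")
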