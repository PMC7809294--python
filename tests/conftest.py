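import numpy as np
import pytest

import epsim


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    """11^3 grid, 0.5 mm spacing."""
    return epsim.build_grid((5e-3, 5e-3, 5e-3), 0.5e-3)


def plate_capacitor(extent, spacing):
    """Full-cross-section plate pair at the x faces (1D closed-form limit)."""
    grid = epsim.build_grid(extent, spacing)
    _, ey, ez = grid.extent
    els = [
        epsim.ElectrodeGeometry(kind="plate", center=(0.0, ey / 2, ez / 2),
                                dims=(0.0, ey, ez), polarity="anode"),
        epsim.ElectrodeGeometry(kind="plate",
                                center=(extent[0], ey / 2, ez / 2),
                                dims=(0.0, ey, ez), polarity="cathode"),
    ]
    labels = epsim.classify_boundaries(
        grid, epsim.rasterize_electrodes(grid, els), els)
    return grid, labels, els


def needle_pair(extent=(6e-3, 6e-3, 6e-3), spacing=0.5e-3,
                radius=0.3e-3, length=4e-3):
    """Two parallel needles along z, quarter/three-quarter x positions."""
    grid = epsim.build_grid(extent, spacing)
    ex, ey, ez = grid.extent
    els = [
        epsim.ElectrodeGeometry(kind="needle", center=(ex / 3, ey / 2, ez / 2),
                                radius=radius, length=length,
                                polarity="anode", exposed_fraction=0.2),
        epsim.ElectrodeGeometry(kind="needle",
                                center=(2 * ex / 3, ey / 2, ez / 2),
                                radius=radius, length=length,
                                polarity="cathode", exposed_fraction=0.2),
    ]
    labels = epsim.classify_boundaries(
        grid, epsim.rasterize_electrodes(grid, els), els)
    return grid, labels, els


def tiny_run_config(n_pulses=2, dt_on_divisor=8, v_per_cm=250.0,
                    alpha=0.02, **overrides):
    """Small plate-electrode run finishing in well under a second."""
    d = {
        "name": "tiny",
        "domain": {"extent_mm": [4.0, 3.0, 3.0], "spacing_mm": 0.5},
        "electrodes": [
            {"kind": "plate", "center_mm": [0.0, 1.5, 1.5],
             "dims_mm": [0.0, 3.0, 3.0], "polarity": "anode"},
            {"kind": "plate", "center_mm": [4.0, 1.5, 1.5],
             "dims_mm": [0.0, 3.0, 3.0], "polarity": "cathode"},
        ],
        "protocol": {"n_pulses": n_pulses, "t_on_s": 0.05, "freq_hz": 1.0,
                     "v_per_cm": v_per_cm, "gap_mm": 4.0},
        "params": {"sigma_b": 0.504, "alpha": alpha, "q_m": 0.0},
        "solver": {"tol": 1e-8},
        "thermal": {"dt_on_divisor": dt_on_divisor},
        "output": {"snapshots": False,
                   "probes_mm": {"mid": [2.0, 1.5, 1.5]}},
    }
    for key, val in overrides.items():
        d.setdefault(key, {}).update(val) if isinstance(val, dict) \
            else d.__setitem__(key, val)
    return epsim.from_dict(d)
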