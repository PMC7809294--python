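"""File I/O: legacy-VTK field snapshots, CSV time series, YAML configs.

Snapshots are legacy ASCII VTK ``STRUCTURED_POINTS`` (x varies fastest),
readable by Paraview and most scientific viewers.  CSV output is
deterministic byte-for-byte: shortest round-trip float repr, comma
separator, LF line endings, UTF-8.
"""

from __future__ import annotations

import io
import re
from pathlib import Path

import numpy as np
import yaml

from . import config as config_mod
from .errors import ConfigurationError
from .mesh import Grid

VECTOR_FIELDS = {"E", "J"}


def _fmt(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def write_vtk(path, grid: Grid, name: str, data: np.ndarray,
              title: str | None = None) -> Path:
    """Write one scalar or vector field as legacy ASCII VTK.

    Scalars have shape ``grid.shape``; vectors ``(3,) + grid.shape``.
    """
    path = Path(path)
    vector = data.ndim == 4
    if vector and data.shape != (3,) + grid.shape:
        raise ConfigurationError(
            f"vector field shape {data.shape} does not match grid "
            f"{grid.shape}")
    if not vector and data.shape != grid.shape:
        raise ConfigurationError(
            f"scalar field shape {data.shape} does not match grid "
            f"{grid.shape}")
    nx, ny, nz = grid.shape
    h = grid.spacing
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(f"{title or name}\n")
    buf.write("ASCII\n")
    buf.write("DATASET STRUCTURED_POINTS\n")
    buf.write(f"DIMENSIONS {nx} {ny} {nz}\n")
    buf.write("ORIGIN 0 0 0\n")
    buf.write(f"SPACING {_fmt(h)} {_fmt(h)} {_fmt(h)}\n")
    buf.write(f"POINT_DATA {nx * ny * nz}\n")
    if vector:
        buf.write(f"VECTORS {name} double\n")
        flat = np.stack([c.ravel(order="F") for c in data], axis=1)
        for row in flat:
            buf.write(f"{_fmt(row[0])} {_fmt(row[1])} {_fmt(row[2])}\n")
    else:
        buf.write(f"SCALARS {name} double 1\n")
        buf.write("LOOKUP_TABLE default\n")
        for v in data.ravel(order="F"):
            buf.write(f"{_fmt(v)}\n")
    try:
        path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")
    except OSError as exc:
        raise OSError(f"cannot write VTK file {path}: {exc}") from exc
    return path


def read_vtk(path):
    """Read a legacy ASCII STRUCTURED_POINTS file back.

    Returns (name, array, spacing); vectors come back as (3, nx, ny, nz).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    dims = spacing = None
    name = None
    vector = False
    data_start = None
    for i, ln in enumerate(lines):
        if ln.startswith("DIMENSIONS"):
            dims = tuple(int(v) for v in ln.split()[1:4])
        elif ln.startswith("SPACING"):
            spacing = float(ln.split()[1])
        elif ln.startswith("SCALARS"):
            name = ln.split()[1]
            data_start = i + 2          # skip LOOKUP_TABLE line
        elif ln.startswith("VECTORS"):
            name = ln.split()[1]
            vector = True
            data_start = i + 1
    if dims is None or data_start is None:
        raise ConfigurationError(f"{path} is not a structured-points VTK file")
    raw = np.array([float(v) for ln in lines[data_start:]
                    for v in ln.split()])
    n = dims[0] * dims[1] * dims[2]
    if vector:
        comp = raw.reshape(n, 3)
        arr = np.stack([comp[:, c].reshape(dims, order="F") for c in range(3)])
    else:
        arr = raw.reshape(dims, order="F")
    return name, arr, spacing


def write_csv(path, header: list[str], columns: list[np.ndarray]) -> Path:
    """Deterministic CSV: header row + repr-formatted float columns."""
    path = Path(path)
    ncols = len(header)
    if len(columns) != ncols:
        raise ConfigurationError("CSV header/column count mismatch")
    rows = len(columns[0]) if columns else 0
    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    for i in range(rows):
        buf.write(",".join(_fmt(col[i]) for col in columns) + "\n")
    try:
        path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")
    except OSError as exc:
        raise OSError(f"cannot write CSV file {path}: {exc}") from exc
    return path


def read_csv(path):
    """Read a CSV written by :func:`write_csv`; returns (header, columns)."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    header = text[0].split(",")
    if len(text) == 1:
        return header, [np.zeros(0) for _ in header]
    data = np.array([[float(v) for v in ln.split(",")] for ln in text[1:]])
    return header, [data[:, i] for i in range(len(header))]


def write_timeseries_csvs(series, outdir) -> list[Path]:
    """Write the standard run CSVs: current, charge, probes, dose table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = [
        write_csv(outdir / "current.csv",
                  ["time_s", "current_A", "current_cathode_A"],
                  [series.t, series.current, series.current_cathode]),
        write_csv(outdir / "charge.csv", ["time_s", "charge_C"],
                  [series.t, series.charge]),
        write_csv(outdir / "ep_volume.csv",
                  ["pulse", "volume_mm3", "threshold_V_per_cm",
                   "damage_volume_mm3", "peak_temperature_C"],
                  [series.pulses, series.ep_volume * 1e9,
                   series.ep_threshold / 100.0, series.damage_volume * 1e9,
                   series.peak_temperature]),
    ]
    if series.probes:
        names = sorted(series.probes)
        written.append(write_csv(
            outdir / "probes.csv", ["time_s"] + [f"T_{n}_C" for n in names],
            [series.t] + [series.probes[n] for n in names]))
    return written


def load_config(path) -> "config_mod.SimulationConfig":
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file {path} does not exist")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return config_mod.from_dict(data)


def save_config(cfg, path) -> Path:
    """Echo a configuration back to YAML (config units)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config_mod.to_dict(cfg), sort_keys=False),
                    encoding="utf-8", newline="\n")
    return path


_RUN_RE = re.compile(r"^simulation-(\d{6})$")


def next_run_dir(base) -> Path:
    """Create the next sequentially numbered run directory.

    Layout: ``simulation-NNNNNN/{config,data,log}``.
    """
    base = Path(base)
    base.mkdir(parents=True, exist_ok=True)
    nums = [int(m.group(1)) for p in base.iterdir()
            if (m := _RUN_RE.match(p.name))]
    run = base / f"simulation-{(max(nums, default=0) + 1):06d}"
    for sub in ("config", "data", "log"):
        (run / sub).mkdir(parents=True)
    return run
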