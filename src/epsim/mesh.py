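"""Uniform 3D grid, electrode rasterization and boundary classification.

The computational domain is a box discretized by a node-centered uniform
lattice: node (i, j, k) sits at (i*h, j*h, k*h).  Electrodes (needle
cylinders or plate boxes) are rasterized onto the lattice by exact
point-membership tests against the closed solid, and every domain-boundary
face is classified for the thermal boundary conditions: tissue-air faces are
insulated (zero flux), faces of exposed electrodes lose heat convectively to
the room.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError

TISSUE = 0
ANODE = 1
CATHODE = 2

#: the six domain-boundary faces, keyed by axis and side
BOUNDARY_FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass(frozen=True)
class Grid:
    """Uniform node-centered lattice.

    ``shape`` is the node count per axis, ``spacing`` the (single) grid step
    in meters; the extent per axis is exactly ``(n - 1) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: float

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple((n - 1) * self.spacing for n in self.shape)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def node_volume(self) -> float:
        return self.spacing ** 3

    @property
    def face_area(self) -> float:
        return self.spacing ** 2

    def axis_coords(self, axis: int) -> np.ndarray:
        return np.arange(self.shape[axis]) * self.spacing

    def node_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of node coordinates in meters."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)),
                           indexing="ij")


@dataclass(frozen=True)
class ElectrodeMaterial:
    """Thermal properties of the electrode metal (SI)."""

    kappa: float = 15.0      # W/(m K), stainless-steel-like
    rho: float = 7900.0      # kg/m^3
    cp: float = 500.0        # J/(kg K)


@dataclass(frozen=True)
class ElectrodeGeometry:
    """A needle (cylinder) or plate (axis-aligned box) electrode.

    ``exposed_fraction`` is the portion of the electrode protruding into the
    air above the tissue; it gates the convective-cooling tag of the
    electrode's domain-boundary faces.
    """

    kind: str                                  # "needle" | "plate"
    center: tuple[float, float, float]         # m
    polarity: str                              # "anode" | "cathode"
    radius: float | None = None                # m (needle)
    length: float | None = None                # m (needle)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dims: tuple[float, float, float] | None = None  # m (plate box side lengths)
    exposed_fraction: float = 0.0
    material: ElectrodeMaterial = field(default_factory=ElectrodeMaterial)

    def __post_init__(self):
        if self.kind not in ("needle", "plate"):
            raise ConfigurationError(f"unknown electrode kind {self.kind!r}")
        if self.polarity not in ("anode", "cathode"):
            raise ConfigurationError(
                f"electrode polarity must be anode/cathode, got {self.polarity!r}")
        if not 0.0 <= self.exposed_fraction <= 1.0:
            raise ConfigurationError(
                f"exposed_fraction must lie in [0, 1], got {self.exposed_fraction}")
        if self.kind == "needle":
            if self.radius is None or self.length is None:
                raise ConfigurationError("needle electrode needs radius and length")
            if self.radius <= 0 or self.length <= 0:
                raise ConfigurationError("needle radius and length must be positive")
            n = float(np.linalg.norm(self.axis))
            if n == 0:
                raise ConfigurationError("needle axis must be a nonzero vector")
        else:
            if self.dims is None:
                raise ConfigurationError("plate electrode needs dims")
            if any(d < 0 for d in self.dims):
                raise ConfigurationError("plate dims must be non-negative")

    @property
    def label(self) -> int:
        return ANODE if self.polarity == "anode" else CATHODE

    def contains(self, x, y, z):
        """Boundary-inclusive membership test of point(s) in the solid."""
        cx, cy, cz = self.center
        dx, dy, dz = x - cx, y - cy, z - cz
        if self.kind == "plate":
            hx, hy, hz = (d / 2.0 for d in self.dims)
            return ((np.abs(dx) <= hx) & (np.abs(dy) <= hy)
                    & (np.abs(dz) <= hz))
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        t = dx * a[0] + dy * a[1] + dz * a[2]
        r2 = (dx - t * a[0]) ** 2 + (dy - t * a[1]) ** 2 + (dz - t * a[2]) ** 2
        return (np.abs(t) <= self.length / 2.0) & (r2 <= self.radius ** 2)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi) of the solid."""
        c = np.asarray(self.center)
        if self.kind == "plate":
            half = np.asarray(self.dims) / 2.0
            return c - half, c + half
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        # AABB of a capped cylinder: |axis| projection plus radial support
        half = np.abs(a) * self.length / 2.0 + self.radius * np.sqrt(
            np.maximum(1.0 - a ** 2, 0.0))
        return c - half, c + half


@dataclass
class NodeLabels:
    """Per-node material label and per-boundary-face air-exposure tags.

    ``material`` holds TISSUE/ANODE/CATHODE per node; ``electrode_id`` maps
    each electrode node back to its electrode (-1 for tissue).
    ``electrode_air`` has, for each of the six domain faces, a 2D boolean
    array marking faces under convective cooling; all remaining boundary
    faces are tissue-air (insulated).
    """

    material: np.ndarray
    electrode_id: np.ndarray
    electrode_air: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def anode_mask(self) -> np.ndarray:
        return self.material == ANODE

    @property
    def cathode_mask(self) -> np.ndarray:
        return self.material == CATHODE

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.material == TISSUE

    def face_counts(self) -> dict[str, int]:
        """Number of electrode-air and tissue-air boundary faces."""
        if not self.electrode_air:
            return {"electrode_air": 0, "tissue_air": 0}
        n_el = sum(int(m.sum()) for m in self.electrode_air.values())
        n_total = sum(m.size for m in self.electrode_air.values())
        return {"electrode_air": n_el, "tissue_air": n_total - n_el}


def build_grid(extent: tuple[float, float, float], spacing: float,
               rtol: float = 1e-9) -> Grid:
    """Build a uniform grid; the spacing must divide every extent.

    ``extent`` per axis in meters; node count per axis is
    ``round(extent/h) + 1``.
    """
    if spacing <= 0:
        raise ConfigurationError(f"grid spacing must be positive, got {spacing}")
    shape = []
    for ax, (name, ext) in enumerate(zip("xyz", extent)):
        if ext <= 0:
            raise ConfigurationError(f"domain extent along {name} must be positive")
        n = round(ext / spacing)
        if abs(n * spacing - ext) > rtol * ext:
            raise ConfigurationError(
                f"spacing {spacing} does not divide the extent {ext} along axis "
                f"{name}")
        shape.append(n + 1)
    if any(n < 3 for n in shape):
        raise ConfigurationError(
            f"grid needs at least 3 nodes per axis, got {tuple(shape)}")
    return Grid(shape=tuple(shape), spacing=float(spacing))


def rasterize_electrodes(grid: Grid,
                         electrodes: list[ElectrodeGeometry]) -> NodeLabels:
    """Label every node anode/cathode/tissue by exact point membership.

    Deterministic: a node is labeled iff its coordinate lies inside the
    closed electrode solid.  Overlapping electrodes and electrodes that claim
    no node (fully outside the domain, or falling between node columns) are
    errors.
    """
    x, y, z = grid.node_coords()
    material = np.full(grid.shape, TISSUE, dtype=np.int8)
    electrode_id = np.full(grid.shape, -1, dtype=np.int32)
    lo_dom = np.zeros(3)
    hi_dom = np.asarray(grid.extent)
    for idx, el in enumerate(electrodes):
        lo, hi = el.bounds()
        if np.any(hi < lo_dom) or np.any(lo > hi_dom):
            raise GeometryError(
                f"electrode {idx} ({el.kind}, {el.polarity}) lies entirely "
                f"outside the domain")
        mask = el.contains(x, y, z)
        if not mask.any():
            raise GeometryError(
                f"electrode {idx} ({el.kind}, {el.polarity}) claims no grid "
                f"node; refine the grid or enlarge the electrode")
        clash = mask & (electrode_id >= 0)
        if clash.any():
            other = int(electrode_id[clash][0])
            raise GeometryError(
                f"electrodes {other} and {idx} overlap on {int(clash.sum())} "
                f"node(s)")
        material[mask] = el.label
        electrode_id[mask] = idx
    return NodeLabels(material=material, electrode_id=electrode_id)


def _boundary_slice(face: str, shape):
    ax = "xyz".index(face[0])
    idx = 0 if face[1] == "-" else shape[ax] - 1
    sl = [slice(None)] * 3
    sl[ax] = idx
    return tuple(sl)


def classify_boundaries(grid: Grid, labels: NodeLabels,
                        electrodes: list[ElectrodeGeometry]) -> NodeLabels:
    """Tag every domain-boundary face as tissue-air or electrode-air.

    A boundary face is electrode-air iff the node behind it belongs to an
    electrode with a positive exposed fraction; those faces get the
    convective (Robin) thermal condition, everything else is zero-flux.
    """
    exposed = np.array([el.exposed_fraction > 0 for el in electrodes],
                       dtype=bool)
    tags: dict[str, np.ndarray] = {}
    for face in BOUNDARY_FACES:
        sl = _boundary_slice(face, grid.shape)
        eid = labels.electrode_id[sl]
        tag = np.zeros(eid.shape, dtype=bool)
        if len(electrodes):
            on_el = eid >= 0
            tag[on_el] = exposed[eid[on_el]]
        tags[face] = tag
    return NodeLabels(material=labels.material,
                      electrode_id=labels.electrode_id,
                      electrode_air=tags)
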