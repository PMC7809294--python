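"""Treatment observables: current, charge, thresholds, electroporated volume.

The dose model is the field-threshold one: a tissue node is (reversibly)
electroporated when |E| reaches a threshold that *decays with pulse number*,

    E_thr(n) = E_inf + (E_0 - E_inf) exp(-n / tau),

so the electroporated region grows pulse by pulse even under a steady field.
Damage combines irreversible electroporation (|E| above a second, fixed or
slowly-decaying threshold) with thermal excess (T above T_crit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, ndimage, optimize

from .errors import ConfigurationError
from .mesh import ANODE, CATHODE, Grid, NodeLabels


@dataclass(frozen=True)
class ThresholdModel:
    """Exponential pulse-number decay of the electroporation threshold.

    ``e0`` is the threshold before the first pulse, ``e_inf`` the asymptote,
    ``tau`` the decay constant in pulses; all field values in V/m.
    """

    e0: float
    e_inf: float
    tau: float

    def __post_init__(self):
        if not self.e0 >= self.e_inf > 0:
            raise ConfigurationError(
                f"threshold model needs e0 >= e_inf > 0, got "
                f"e0={self.e0}, e_inf={self.e_inf}")
        if self.tau <= 0:
            raise ConfigurationError(f"threshold tau must be positive, got "
                                     f"{self.tau}")

    @classmethod
    def constant(cls, level: float) -> "ThresholdModel":
        return cls(e0=level, e_inf=level, tau=1.0)


def threshold_at(model: ThresholdModel, n) -> float | np.ndarray:
    """Threshold after n pulses (n = 0 gives E_0)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ConfigurationError("pulse index must be >= 0")
    out = model.e_inf + (model.e0 - model.e_inf) * np.exp(-n / model.tau)
    return float(out) if out.ndim == 0 else out


def current_density(sigma: np.ndarray, e_field: np.ndarray) -> np.ndarray:
    """J = sigma E, nodewise (Ohm's law)."""
    return sigma * e_field


def electrode_current(phi: np.ndarray, sigma: np.ndarray, grid: Grid,
                      labels: NodeLabels, which: str = "anode") -> float:
    """Current through a closed surface one node layer outside an electrode.

    The surface is the face set between the 6-connected dilation of the
    electrode's nodes and the rest of the grid; per-face flux uses exactly
    the potential stencil's face conductances (harmonic mean times the
    half-cell face area), so the discrete divergence theorem makes anode
    and cathode currents agree to solver tolerance, and the
    full-cross-section plate limit reproduces I = sigma E A with the
    geometric plate area.

    Returns the current delivered by the anode (positive out of the anode)
    or collected by the cathode (positive into the cathode).
    """
    from .electrostatics import face_conductivities

    if which not in ("anode", "cathode"):
        raise ConfigurationError(f"which must be anode or cathode, got {which!r}")
    target = ANODE if which == "anode" else CATHODE
    mask = labels.material == target
    if not mask.any():
        raise ConfigurationError(f"no {which} nodes present")
    struct = ndimage.generate_binary_structure(3, 1)
    box = ndimage.binary_dilation(mask, structure=struct)

    h3 = grid.node_volume
    weights = face_conductivities(sigma, grid.spacing)
    total = 0.0
    for axis, w_face in enumerate(weights):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        dphi = phi[sl_a] - phi[sl_b]
        # faces crossed going +axis out of the box, and -axis out of the box
        out_pos = box[sl_a] & ~box[sl_b]
        out_neg = ~box[sl_a] & box[sl_b]
        total += float(np.sum((w_face * dphi)[out_pos])) * h3
        total -= float(np.sum((w_face * dphi)[out_neg])) * h3
    return total if which == "anode" else -total


def accumulate_charge(current: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral of I(t); Q(0) = 0."""
    current = np.asarray(current, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(current) == 0:
        return np.zeros(0)
    return integrate.cumulative_trapezoid(current, t, initial=0.0)


@dataclass
class RegionResult:
    """Mask, volume (m^3) and optional slice area (m^2) of a level set."""

    mask: np.ndarray
    volume: float
    area: float | None = None


def electroporated_region(e_field: np.ndarray, e_thr: float, grid: Grid,
                          tissue_mask: np.ndarray | None = None,
                          plane: tuple[int, int] | None = None
                          ) -> RegionResult:
    """Tissue nodes with |E| >= threshold (boundary-inclusive).

    ``e_field`` may be the (3, ...) vector field or its magnitude.
    ``plane=(axis, index)`` additionally reports the area on that slice.
    """
    e_mag = (np.linalg.norm(e_field, axis=0) if e_field.ndim == 4
             else np.asarray(e_field))
    mask = e_mag >= e_thr
    if tissue_mask is not None:
        mask = mask & tissue_mask
    volume = float(mask.sum()) * grid.node_volume
    area = None
    if plane is not None:
        axis, index = plane
        sl = [slice(None)] * 3
        sl[axis] = index
        area = float(mask[tuple(sl)].sum()) * grid.face_area
    return RegionResult(mask=mask, volume=volume, area=area)


@dataclass
class LevelResult:
    """Field level recovered from a target area, with the achieved area."""

    level: float
    area: float
    flagged: bool = False


def threshold_from_area(e_slice: np.ndarray, target_area: float,
                        face_area: float, max_iter: int = 200) -> LevelResult:
    """Invert the level-set area on a slice: find E_thr with
    count(|E| >= E_thr) * h^2 matching the target area.

    Bisection on the (non-increasing) area-vs-level curve; if the target is
    not reachable within one face area the nearest achievable level is
    returned flagged rather than raising.
    """
    vals = np.asarray(e_slice, dtype=float).ravel()

    def area_of(level: float) -> float:
        return float(np.count_nonzero(vals >= level)) * face_area

    lo, hi = float(vals.min()), float(vals.max())
    if target_area >= area_of(lo):
        flag = target_area > area_of(lo) + face_area
        return LevelResult(level=lo, area=area_of(lo), flagged=flag)
    if target_area <= area_of(hi):
        return LevelResult(level=hi, area=area_of(hi),
                           flagged=target_area < area_of(hi) - face_area)
    best = (lo, area_of(lo))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = area_of(mid)
        if abs(a - target_area) <= abs(best[1] - target_area):
            best = (mid, a)
        if abs(a - target_area) <= face_area:
            return LevelResult(level=mid, area=a, flagged=False)
        if a > target_area:
            lo = mid
        else:
            hi = mid
    return LevelResult(level=best[0], area=best[1],
                       flagged=abs(best[1] - target_area) > face_area)


@dataclass
class ThresholdFit:
    """fit_threshold_decay output: model, RMS residual, identifiability."""

    model: ThresholdModel
    rms: float
    identifiable: bool = True


def fit_threshold_decay(n: np.ndarray, e_thr: np.ndarray) -> ThresholdFit:
    """Least-squares fit of E_inf + (E_0 - E_inf) exp(-n/tau).

    Needs at least 3 distinct pulse numbers.  Constant input is returned as
    E_0 = E_inf with tau flagged unidentifiable.
    """
    n = np.asarray(n, dtype=float)
    y = np.asarray(e_thr, dtype=float)
    if len(n) < 3 or len(np.unique(n)) < 3:
        raise ConfigurationError("threshold fit needs >= 3 distinct pulse "
                                 "numbers")
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        level = float(y.mean())
        return ThresholdFit(model=ThresholdModel.constant(level), rms=0.0,
                            identifiable=False)

    def f(x, e0, e_inf, tau):
        return e_inf + (e0 - e_inf) * np.exp(-x / tau)

    span = float(n.max() - n.min())
    p0 = [float(y[np.argmin(n)]), float(y[np.argmax(n)]), max(span / 3.0, 1.0)]
    popt, _ = optimize.curve_fit(f, n, y, p0=p0, maxfev=20000)
    e0, e_inf, tau = (float(v) for v in popt)
    resid = y - f(n, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if e0 < e_inf:      # decay fitted "backwards"; reparametrize
        e0, e_inf = max(e0, e_inf), min(e0, e_inf)
    return ThresholdFit(model=ThresholdModel(e0=e0, e_inf=max(e_inf, 1e-300),
                                             tau=abs(tau)), rms=rms)


def damage_region(e_field: np.ndarray, irreversible_thr: float,
                  T: np.ndarray, t_crit: float, grid: Grid,
                  tissue_mask: np.ndarray | None = None) -> RegionResult:
    """Union of IRE damage (|E| >= irreversible threshold) and thermal
    excess (T >= T_crit)."""
    e_mag = (np.linalg.norm(e_field, axis=0) if e_field.ndim == 4
             else np.asarray(e_field))
    mask = (e_mag >= irreversible_thr) | (T >= t_crit)
    if tissue_mask is not None:
        mask = mask & tissue_mask
    return RegionResult(mask=mask, volume=float(mask.sum()) * grid.node_volume)


@dataclass
class TimeSeries:
    """Sampled treatment observables.

    Per-sample arrays: time, anode/cathode current, cumulative charge,
    instantaneous Joule power, ON flag, pulse index and named probe
    temperatures.  Per-pulse arrays: electroporated volume, the threshold
    used, damage volume and peak temperature after each pulse.
    """

    t: np.ndarray
    current: np.ndarray
    current_cathode: np.ndarray
    charge: np.ndarray
    power: np.ndarray
    on: np.ndarray
    pulse: np.ndarray
    probes: dict[str, np.ndarray] = field(default_factory=dict)
    # per-pulse dose table
    pulses: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    ep_volume: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ep_threshold: np.ndarray = field(default_factory=lambda: np.zeros(0))
    damage_volume: np.ndarray = field(default_factory=lambda: np.zeros(0))
    peak_temperature: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ConfigurationError("time samples must be strictly increasing")
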