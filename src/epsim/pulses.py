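"""Pulse protocols and piecewise-constant applied-voltage waveforms.

A protocol is a train of ``n_pulses`` periods at a given frequency.  During
the ON (energized) window of each period the electrodes carry the applied
voltage; the rest of the period is OFF at 0 V.  Monopolar trains hold a
constant +V during the whole ON window; H-FIRE protocols fill the energized
window with bipolar (positive, delay, negative, delay) cycles.  The
nanosecond rise time of real generators is idealized as an instantaneous
step, which is far below any time step used here.

Segment convention: left-closed, right-open intervals; a query exactly at a
segment boundary resolves to the later segment.  Inter-phase delays inside
an H-FIRE burst count as ON for stage logic (the burst is energized even
while the voltage crosses zero); the Laplace solve is skipped whenever the
instantaneous voltage is zero regardless of stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

MONOPOLAR = "monopolar"
HFIRE_SYMMETRIC = "hfire-symmetric"
HFIRE_ASYMMETRIC = "hfire-asymmetric"
WAVEFORM_KINDS = (MONOPOLAR, HFIRE_SYMMETRIC, HFIRE_ASYMMETRIC)


@dataclass(frozen=True)
class HFireSpec:
    """Phase widths of one bipolar cycle and the energized time per burst.

    Widths in seconds: positive phase, inter-phase delay, negative phase.
    Cycles of (pos, delay, neg, delay) are tiled into ``energized`` seconds;
    a remainder shorter than one full cycle stays at 0 V.  Both polarities
    use the same magnitude scaled by ``neg_scale`` on the negative phase
    (the literature fixes asymmetric *durations*, not amplitudes).
    """

    pos: float
    delay: float
    neg: float
    energized: float
    neg_scale: float = 1.0

    def __post_init__(self):
        if min(self.pos, self.neg) <= 0 or self.delay < 0:
            raise ConfigurationError("H-FIRE phase widths must be positive "
                                     "(delay may be zero)")
        if self.pos + self.delay + self.neg > self.energized:
            raise ConfigurationError(
                "H-FIRE cycle (pos + delay + neg) exceeds the energized time")

    @property
    def cycle(self) -> float:
        return self.pos + self.delay + self.neg + self.delay


@dataclass(frozen=True)
class PulseProtocol:
    """Pulse-train description.

    ``t_on`` is the energized window per period (for H-FIRE this is the
    burst's energized time).  The applied voltage is either given directly
    (``voltage``) or as a voltage-to-distance ratio in V/m times the
    electrode gap ``gap`` in m.
    """

    n_pulses: int
    t_on: float                      # s
    frequency: float                 # Hz
    voltage_to_distance: float | None = None   # V/m
    gap: float | None = None                   # m
    voltage: float | None = None               # V, overrides V/D * gap
    waveform: str = MONOPOLAR
    hfire: HFireSpec | None = None

    def __post_init__(self):
        if self.n_pulses < 1:
            raise ConfigurationError("n_pulses must be >= 1")
        if self.t_on <= 0 or self.frequency <= 0:
            raise ConfigurationError("t_on and frequency must be positive")
        if self.t_on >= self.period:
            raise ConfigurationError(
                f"t_on = {self.t_on} s must be shorter than the pulse period "
                f"{self.period} s")
        if self.waveform not in WAVEFORM_KINDS:
            raise ConfigurationError(f"unknown waveform kind {self.waveform!r}")
        if self.waveform != MONOPOLAR and self.hfire is None:
            raise ConfigurationError("H-FIRE waveform needs an HFireSpec")
        if self.voltage is None and (self.voltage_to_distance is None
                                     or self.gap is None):
            raise ConfigurationError(
                "protocol needs either voltage or voltage_to_distance + gap")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def amplitude(self) -> float:
        """Applied voltage V (anode minus cathode) during positive phases."""
        if self.voltage is not None:
            return float(self.voltage)
        return float(self.voltage_to_distance * self.gap)

    @property
    def duration(self) -> float:
        return self.n_pulses * self.period


@dataclass(frozen=True)
class Waveform:
    """Piecewise-constant applied voltage over [0, duration].

    Stored as contiguous segments [starts[i], ends[i]) with constant voltage
    ``volts[i]``; ``on[i]`` marks segments inside an energized window.
    """

    starts: np.ndarray
    ends: np.ndarray
    volts: np.ndarray
    on: np.ndarray
    duration: float = field(default=0.0)
    #: nominal segment lengths (bitwise-exact per-phase widths; the
    #: starts/ends carry cumulative rounding, the widths do not)
    widths: np.ndarray | None = None

    def __post_init__(self):
        if not (np.all(self.starts[1:] == self.ends[:-1])
                and self.starts[0] == 0.0
                and self.ends[-1] == self.duration):
            raise ConfigurationError("waveform segments must tile [0, duration]")
        if self.widths is None:
            object.__setattr__(self, "widths", self.ends - self.starts)

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    def segment_index(self, t: float) -> int:
        if not 0.0 <= t <= self.duration:
            raise ConfigurationError(
                f"time {t} s outside the waveform span [0, {self.duration}] s")
        if t == self.duration:
            return self.n_segments - 1
        return int(np.searchsorted(self.starts, t, side="right") - 1)

    @property
    def net_volt_seconds(self) -> float:
        return float(np.sum(self.volts * self.widths))

    @property
    def total_on_time(self) -> float:
        """Summed length of nonzero-voltage segments."""
        nz = self.volts != 0.0
        return float(np.sum(self.widths[nz]))


def _assemble(protocol: PulseProtocol, seg_per_pulse):
    """Tile per-period segments (t0, t1, V, on) over all pulses."""
    starts, ends, volts, on, widths = [], [], [], [], []
    period = protocol.period
    for k in range(protocol.n_pulses):
        t0 = k * period
        for (a, b, v, s, w) in seg_per_pulse:
            starts.append(t0 + a)
            ends.append(t0 + b)
            volts.append(v)
            on.append(s)
            widths.append(w)
    # make the tiling exact against float drift
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    starts[1:] = ends[:-1]
    starts[0] = 0.0
    duration = float(ends[-1])
    return Waveform(starts=starts, ends=ends, volts=np.asarray(volts, float),
                    on=np.asarray(on, bool), duration=duration,
                    widths=np.asarray(widths))


def build_monopolar(protocol: PulseProtocol) -> Waveform:
    """Constant +V during each ON window, 0 V during OFF."""
    if protocol.waveform != MONOPOLAR:
        raise ConfigurationError("protocol waveform kind is not monopolar")
    v = protocol.amplitude
    seg = [(0.0, protocol.t_on, v, True, protocol.t_on),
           (protocol.t_on, protocol.period, 0.0, False,
            protocol.period - protocol.t_on)]
    return _assemble(protocol, seg)


def build_hfire(protocol: PulseProtocol) -> Waveform:
    """Bipolar bursts: (pos, delay, neg, delay) cycles fill each ON window."""
    if protocol.waveform not in (HFIRE_SYMMETRIC, HFIRE_ASYMMETRIC):
        raise ConfigurationError("protocol waveform kind is not H-FIRE")
    spec = protocol.hfire
    if protocol.waveform == HFIRE_SYMMETRIC and spec.neg != spec.pos:
        raise ConfigurationError(
            "symmetric H-FIRE requires equal positive and negative widths")
    v = protocol.amplitude
    seg = []
    t = 0.0
    while t + spec.cycle <= protocol.t_on + 1e-15 * protocol.t_on:
        seg.append((t, t + spec.pos, v, True, spec.pos))
        t += spec.pos
        if spec.delay > 0:
            seg.append((t, t + spec.delay, 0.0, True, spec.delay))
            t += spec.delay
        seg.append((t, t + spec.neg, -v * spec.neg_scale, True, spec.neg))
        t += spec.neg
        if spec.delay > 0:
            seg.append((t, t + spec.delay, 0.0, True, spec.delay))
            t += spec.delay
    if not seg:
        raise ConfigurationError("no complete H-FIRE cycle fits the ON window")
    if t < protocol.t_on:           # un-energizable remainder of the burst
        seg.append((t, protocol.t_on, 0.0, True, protocol.t_on - t))
    seg.append((protocol.t_on, protocol.period, 0.0, False,
                protocol.period - protocol.t_on))
    return _assemble(protocol, seg)


def build_waveform(protocol: PulseProtocol) -> Waveform:
    if protocol.waveform == MONOPOLAR:
        return build_monopolar(protocol)
    return build_hfire(protocol)


def voltage_at(waveform: Waveform, t: float) -> float:
    """Applied voltage at time t (left-closed, right-open segments)."""
    return float(waveform.volts[waveform.segment_index(t)])


def stage_at(waveform: Waveform, t: float) -> str:
    """"ON" iff t lies in an energized window (incl. intra-burst delays)."""
    return "ON" if waveform.on[waveform.segment_index(t)] else "OFF"


def waveform_table(waveform: Waveform):
    """(time_s, voltage_V) rows at every segment start, for CSV export."""
    return list(zip(waveform.starts.tolist(), waveform.volts.tolist()))
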