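"""Time-gridded stimulus protocols for aversive odor conditioning.

Every conditioning experiment is described by a :class:`StimulusProtocol`: a
uniform time grid carrying a binary CS+ odor indicator ``o(t)`` and a shock
voltage ``S(t)`` in volts.  Builders construct the four experiment families
(temporal-sequence packaging of 100 V, repeated training blocks, continuous
odor-shock pairing, trace conditioning) plus the odor-free minimal-shock
avoidance test, and :func:`enumerate_experiment_battery` returns the full
28-condition battery the model is fitted to.

Conventions
-----------
* Discrete shock pulses last 1.5 s (trace-conditioning pulses 1.25 s) and
  occupy half-open intervals ``[onset, onset + duration)`` on the grid.
* The CS- odor presentation is part of each protocol's timeline but carries
  no voltage and is not flagged in ``odor`` (the single-weight model tracks
  the CS+ pathway only).
* ``train_end`` marks the end of conditioning; the behavioral readout uses
  the synaptic weight at that time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StimulusProtocol",
    "PULSE_DURATION",
    "TRACE_PULSE_DURATION",
    "build_sequence_protocol",
    "build_repeated_protocol",
    "build_continuous_protocol",
    "build_trace_protocol",
    "build_minimal_shock_protocol",
    "enumerate_experiment_battery",
    "save_protocol",
    "load_protocol",
]

#: duration (s) of one discrete electroshock pulse
PULSE_DURATION = 1.5
#: duration (s) of one trace-conditioning pulse
TRACE_PULSE_DURATION = 1.25

DEFAULT_DT = 0.01

_BUILDERS: dict[str, Any] = {}  # populated at module end, used by (de)serialization


@dataclass
class StimulusProtocol:
    """One conditioning condition on a uniform time grid.

    Attributes
    ----------
    name : str
        Human-readable condition label, also used as condition id.
    dt : float
        Grid spacing in seconds.
    t : ndarray
        Time grid, starts at 0, uniform spacing ``dt``.
    odor : ndarray
        Binary CS+ odor indicator per grid point.
    voltage : ndarray
        Shock strength in volts per grid point, >= 0.
    train_end : float
        Time (s) at which conditioning ends and the test readout is taken.
    meta : dict
        Free-form condition descriptors (family, alignment, n_pulses, ...).
    """

    name: str
    dt: float
    t: np.ndarray
    odor: np.ndarray
    voltage: np.ndarray
    train_end: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.odor = np.asarray(self.odor, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` if any grid invariant is violated."""
        n = len(self.t)
        if not (len(self.odor) == n and len(self.voltage) == n):
            raise ValueError("t, odor and voltage must share one grid")
        if n < 2:
            raise ValueError("grid needs at least two points")
        steps = np.diff(self.t)
        if not np.allclose(steps, self.dt, rtol=0, atol=1e-9):
            raise ValueError("time grid is not uniform with spacing dt")
        if self.t[0] != 0.0:
            raise ValueError("time grid must start at 0")
        if not np.all(np.isin(self.odor, (0.0, 1.0))):
            raise ValueError("odor indicator must be binary")
        if np.any(self.voltage < 0):
            raise ValueError("voltage must be non-negative")
        if self.train_end > self.t[-1] + 1e-9:
            raise ValueError("train_end exceeds the grid")

    # -- derived quantities ---------------------------------------------

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    @property
    def train_end_index(self) -> int:
        return int(round(self.train_end / self.dt))

    def shock_energy(self) -> float:
        """Time integral of the voltage trace, in V*s."""
        return float(np.sum(self.voltage) * self.dt)

    def odor_shock_overlap(self) -> float:
        """Total time (s) during which odor and shock coincide."""
        return float(np.sum((self.odor > 0) & (self.voltage > 0)) * self.dt)

    # -- export ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "odor": self.odor, "voltage": self.voltage})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------


def _make_grid(total: float, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    return t, np.zeros(n), np.zeros(n)


def _idx(time: float, dt: float) -> int:
    return int(round(time / dt))


def _paint(arr: np.ndarray, start: float, stop: float, value: float, dt: float) -> None:
    """Set ``arr`` to ``value`` on the half-open interval [start, stop)."""
    arr[_idx(start, dt): _idx(stop, dt)] = value


def _paint_pulses(voltage: np.ndarray, onsets: list[float], duration: float,
                  value: float, dt: float) -> None:
    prev_end = -np.inf
    for onset in onsets:
        if onset < prev_end - 1e-9:
            raise ValueError("shock pulses overlap")
        _paint(voltage, onset, onset + duration, value, dt)
        prev_end = onset + duration


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _sequence_onsets(n_pulses: int, alignment: str, window: float = 60.0) -> list[float]:
    """Pulse onsets (odor-relative, s) for the sequence-packaging protocols.

    For up to 4 pulses the onsets are 15 s apart (the spacing printed for the
    repeated-training blocks); 8 pulses are compressed to 60/8 = 7.5 s spacing
    so that all fit the 60 s odor window.  With ``alignment='end'`` the last
    pulse ends exactly at odor offset; with ``'beginning'`` the first pulse
    starts at odor onset.
    """
    spacing = 15.0 if n_pulses <= 4 else window / n_pulses
    if alignment == "end":
        ends = [window - k * spacing for k in range(n_pulses)]
        onsets = sorted(e - PULSE_DURATION for e in ends)
    elif alignment == "beginning":
        onsets = [k * spacing for k in range(n_pulses)]
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    if onsets[0] < -1e-9 or onsets[-1] + PULSE_DURATION > window + 1e-9:
        raise ValueError("pulse train does not fit the odor window")
    return onsets


def build_sequence_protocol(n_pulses: int, pulse_voltage: float,
                            alignment: str = "end", dt: float = DEFAULT_DT,
                            enforce_total: bool = True) -> StimulusProtocol:
    """Temporal-sequence packaging of a fixed 100 V total into 1-8 pulses.

    Timeline: 90 s initial air, 60 s CS+ odor carrying the pulse train,
    30 s air, 60 s CS- odor with zero voltage.

    Parameters
    ----------
    n_pulses : {1, 2, 4, 8}
        Number of 1.5 s shock pulses.
    pulse_voltage : float
        Voltage of each pulse; with ``enforce_total`` the product
        ``n_pulses * pulse_voltage`` must equal 100 V.
    alignment : {'end', 'beginning'}
        Whether the train is packed against odor offset or odor onset.
    """
    if n_pulses not in (1, 2, 4, 8):
        raise ValueError("n_pulses must be one of {1, 2, 4, 8}")
    if enforce_total and abs(n_pulses * pulse_voltage - 100.0) > 1e-9:
        raise ValueError("n_pulses * pulse_voltage must equal 100 V "
                         "(pass enforce_total=False to override)")
    t0, odor_on, odor_off = 90.0, 90.0, 150.0
    total = 90.0 + 60.0 + 30.0 + 60.0
    t, odor, voltage = _make_grid(total, dt)
    _paint(odor, odor_on, odor_off, 1.0, dt)
    onsets = [t0 + o for o in _sequence_onsets(n_pulses, alignment)]
    _paint_pulses(voltage, onsets, PULSE_DURATION, pulse_voltage, dt)
    name = f"sequence_{n_pulses}x{pulse_voltage:g}V_{alignment}"
    proto = StimulusProtocol(
        name, dt, t, odor, voltage, train_end=total,
        meta={"family": "sequence", "n_pulses": n_pulses,
              "pulse_voltage": pulse_voltage, "alignment": alignment},
    )
    proto.validate()
    return proto


def build_repeated_protocol(repetitions: float, pulse_voltage: float,
                            dt: float = DEFAULT_DT) -> StimulusProtocol:
    """Repeated training blocks (60 s CS+ / 30 s air / 60 s CS-).

    A full block carries four pulses ending 15, 30, 45 and 60 s into the CS+
    presentation; ``repetitions=0.5`` is a single half block with two pulses
    ending at 45 and 60 s.  Blocks are separated by 90 s of air, and 90 s of
    air follow the last block before ``train_end``.
    """
    if repetitions not in (0.5, 1, 2, 4):
        raise ValueError("repetitions must be one of {0.5, 1, 2, 4}")
    n_blocks = 1 if repetitions == 0.5 else int(repetitions)
    pulse_ends = [45.0, 60.0] if repetitions == 0.5 else [15.0, 30.0, 45.0, 60.0]

    block, gap, init, tail = 150.0, 90.0, 90.0, 90.0
    total = init + n_blocks * block + (n_blocks - 1) * gap + tail
    t, odor, voltage = _make_grid(total, dt)
    for b in range(n_blocks):
        start = init + b * (block + gap)
        _paint(odor, start, start + 60.0, 1.0, dt)
        onsets = [start + e - PULSE_DURATION for e in pulse_ends]
        _paint_pulses(voltage, onsets, PULSE_DURATION, pulse_voltage, dt)
        # CS- odor occupies [start+90, start+150) with zero voltage
    name = f"repeated_{repetitions:g}x4x{pulse_voltage:g}V"
    proto = StimulusProtocol(
        name, dt, t, odor, voltage, train_end=total,
        meta={"family": "repeated", "repetitions": repetitions,
              "pulse_voltage": pulse_voltage,
              "n_pulses": len(pulse_ends) * n_blocks},
    )
    proto.validate()
    return proto


ALLOWED_CONTINUOUS_DURATIONS = (10.0, 15.0, 30.0, 45.0, 90.0, 120.0)


def build_continuous_protocol(duration: float, voltage: float,
                              dt: float = DEFAULT_DT,
                              enforce_allowed: bool = True) -> StimulusProtocol:
    """Ongoing odor-shock pairing: voltage on during the whole CS+ window.

    Timeline: 90 s initial air, ``duration`` of coextensive odor X and shock,
    30 s air, then odor Y (CS-) for the same duration with zero voltage.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if enforce_allowed and (duration not in ALLOWED_CONTINUOUS_DURATIONS
                            or voltage not in (25.0, 50.0)):
        raise ValueError("duration/voltage outside the experimental sets "
                         "(pass enforce_allowed=False to override)")
    init = 90.0
    total = init + duration + 30.0 + duration
    t, odor, volt = _make_grid(total, dt)
    _paint(odor, init, init + duration, 1.0, dt)
    _paint(volt, init, init + duration, voltage, dt)
    name = f"continuous_{duration:g}s_{voltage:g}V"
    proto = StimulusProtocol(
        name, dt, t, odor, volt, train_end=total,
        meta={"family": "continuous", "duration": duration, "voltage": voltage},
    )
    proto.validate()
    return proto


def build_trace_protocol(isi: float, dt: float = DEFAULT_DT) -> StimulusProtocol:
    """Trace conditioning: 10 s odor, then a 4 x 90 V / 0.2 Hz pulse train.

    ``isi`` is the interval from odor onset to the onset of the first shock
    pulse (1.25 s pulses, onsets 5 s apart); the train may start after the
    odor has ended, leaving odor and shock disjoint in time.
    """
    if isi < 0:
        raise ValueError("isi must be non-negative")
    init, odor_dur, tail = 90.0, 10.0, 30.0
    last_off = isi + 3 * 5.0 + TRACE_PULSE_DURATION
    total = init + max(odor_dur, last_off) + tail
    t, odor, voltage = _make_grid(total, dt)
    _paint(odor, init, init + odor_dur, 1.0, dt)
    onsets = [init + isi + k * 5.0 for k in range(4)]
    _paint_pulses(voltage, onsets, TRACE_PULSE_DURATION, 90.0, dt)
    name = f"trace_isi{isi:g}s"
    proto = StimulusProtocol(
        name, dt, t, odor, voltage, train_end=total,
        meta={"family": "trace", "isi": isi, "n_pulses": 4,
              "pulse_voltage": 90.0},
    )
    proto.validate()
    return proto


def build_minimal_shock_protocol(voltage: float,
                                 dt: float = DEFAULT_DT) -> StimulusProtocol:
    """Odor-free 30 s continuous shock used by the unconditioned readout."""
    if voltage < 0:
        raise ValueError("voltage must be non-negative")
    t, odor, volt = _make_grid(30.0, dt)
    volt[:_idx(30.0, dt)] = voltage
    proto = StimulusProtocol(
        f"minimal_shock_{voltage:g}V", dt, t, odor, volt, train_end=30.0,
        meta={"family": "minimal_shock", "voltage": voltage},
    )
    proto.validate()
    return proto


def enumerate_experiment_battery(dt: float = DEFAULT_DT) -> list[StimulusProtocol]:
    """The fixed 28-condition battery the models are fitted to.

    Ordering (fixed): 8 sequence conditions (packagings 1x100, 2x50, 4x25,
    8x12.5 V, end-aligned then beginning-aligned), 8 repeated conditions
    (0.5, 1, 2, 4 repetitions at 25 V then 50 V), 12 continuous conditions
    (durations 10-120 s at 25 V then 50 V).
    """
    battery: list[StimulusProtocol] = []
    for alignment in ("end", "beginning"):
        for n in (1, 2, 4, 8):
            battery.append(build_sequence_protocol(n, 100.0 / n, alignment, dt))
    for v in (25.0, 50.0):
        for reps in (0.5, 1, 2, 4):
            battery.append(build_repeated_protocol(reps, v, dt))
    for v in (25.0, 50.0):
        for dur in ALLOWED_CONTINUOUS_DURATIONS:
            battery.append(build_continuous_protocol(dur, v, dt))
    assert len(battery) == 28
    return battery


# ---------------------------------------------------------------------------
# plain-text serialization: store the builder and its arguments, rebuild on load
# ---------------------------------------------------------------------------

_BUILDERS.update({
    "sequence": build_sequence_protocol,
    "repeated": build_repeated_protocol,
    "continuous": build_continuous_protocol,
    "trace": build_trace_protocol,
    "minimal_shock": build_minimal_shock_protocol,
})

_BUILDER_ARGS = {
    "sequence": ("n_pulses", "pulse_voltage", "alignment"),
    "repeated": ("repetitions", "pulse_voltage"),
    "continuous": ("duration", "voltage"),
    "trace": ("isi",),
    "minimal_shock": ("voltage",),
}


def save_protocol(protocol: StimulusProtocol, path) -> None:
    """Write a YAML description (family + builder arguments) of a protocol."""
    family = protocol.meta.get("family")
    if family not in _BUILDER_ARGS:
        raise ValueError(f"cannot serialize protocol family {family!r}")
    spec = {"family": family, "dt": protocol.dt,
            **{k: protocol.meta[k] for k in _BUILDER_ARGS[family]}}
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh)


def load_protocol(path) -> StimulusProtocol:
    """Rebuild a protocol from a YAML description written by :func:`save_protocol`."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    family = spec.pop("family")
    dt = spec.pop("dt", DEFAULT_DT)
    return _BUILDERS[family](dt=dt, **spec)
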