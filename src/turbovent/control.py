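"""Motor-speed controllers: proportional update, general PID, feed-forward.

The turbine speed is commanded as an 8-bit value.  Volume-targeted breaths
use the firmware's accumulating proportional rule

    motorSpeed <- motorSpeed + volumeError * Kp

applied once per breath with volumeError = target - delivered (positive error
raises the speed).  Pressure-targeted breaths run a per-sample PID whose
output trims a feed-forward base speed.  Feed-forward tables map an operator
setting (tidal volume, target pressure, PEEP) to a starting speed so the
loop begins near its target; the packaged defaults are computed once from
the static circuit/lung relations for the default synthetic lung.

The speed floor during exhalation is non-zero so the blower never has to
spin up from standstill at the next breath.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "ControllerState",
    "FeedForwardTable",
    "p_update",
    "pid_update",
    "feed_forward_lookup",
    "default_volume_table",
    "default_pressure_table",
    "default_peep_table",
]

#: speed command range
SPEED_MAX = 255.0
#: default non-zero floor so the turbine keeps spinning through exhalation
MIN_SPEED = 10.0


@dataclass(frozen=True)
class ControllerState:
    """State of one controller instance (pure-functional updates)."""

    motor_speed: float = MIN_SPEED  # command counts
    last_error: float = 0.0
    integral_accum: float = 0.0  # target units * s
    kp: float = 0.1
    ki: float = 0.0
    kd: float = 0.0
    min_speed: float = MIN_SPEED
    max_speed: float = SPEED_MAX
    integral_limit: float = 1000.0  # anti-windup clamp on the accumulator

    def __post_init__(self) -> None:
        for g in (self.kp, self.ki, self.kd):
            if not math.isfinite(g):
                raise ValueError("controller gains must be finite")
        if not (self.min_speed <= self.motor_speed <= self.max_speed):
            raise ValueError(
                f"motor_speed {self.motor_speed} outside "
                f"[{self.min_speed}, {self.max_speed}]"
            )


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def p_update(state: ControllerState, error: float) -> ControllerState:
    """Accumulating proportional step: speed += error * kp, clamped."""
    speed = _clamp(
        state.motor_speed + error * state.kp, state.min_speed, state.max_speed
    )
    return replace(state, motor_speed=speed, last_error=error)


def pid_update(
    state: ControllerState, error: float, dt: float
) -> Tuple[ControllerState, float]:
    """One PID step: output = kp*e + ki*int(e) + kd*de/dt.

    Trapezoidal integral with anti-windup clamping, backward-difference
    derivative.  Returns the new state and the raw controller output (the
    caller decides how the output maps onto a speed command).
    """
    if not (dt > 0):
        raise ValueError("dt must be > 0")
    integral = state.integral_accum + 0.5 * (error + state.last_error) * dt
    integral = _clamp(integral, -state.integral_limit, state.integral_limit)
    derivative = (error - state.last_error) / dt
    output = state.kp * error + state.ki * integral + state.kd * derivative
    new_state = replace(state, last_error=error, integral_accum=integral)
    return new_state, output


@dataclass(frozen=True)
class FeedForwardTable:
    """Ordered (target setting -> initial motor speed) interpolation knots."""

    targets: Tuple[float, ...]
    speeds: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.targets) == 0:
            raise ValueError("feed-forward table must be non-empty")
        if len(self.targets) != len(self.speeds):
            raise ValueError("targets and speeds must have equal length")
        if any(b <= a for a, b in zip(self.targets, self.targets[1:])):
            raise ValueError("targets must be strictly increasing")
        if any(not (0.0 <= s <= SPEED_MAX) for s in self.speeds):
            raise ValueError("speeds must lie within the command range")


def feed_forward_lookup(target: float, table: FeedForwardTable) -> float:
    """Initial speed for a target: linear interpolation, clamped at the ends."""
    return float(np.interp(target, table.targets, table.speeds))


# ---------------------------------------------------------------------------
# packaged default tables, computed from the static circuit relations
# ---------------------------------------------------------------------------

def _speed_for_p1(p1: float, max_pressure: float = 70.0) -> float:
    """Speed command whose unloaded stall pressure equals p1 (quadratic law)."""
    frac = math.sqrt(_clamp(p1 / max_pressure, 0.0, 1.0))
    return _clamp(SPEED_MAX * frac, MIN_SPEED, SPEED_MAX)


def default_volume_table(
    compliance: float = 50.0,
    cracking: float = 5.0,
    pilot_bias: float = 3.0,
    targets: Sequence[float] = (100, 200, 300, 400, 500, 600, 700, 800, 999),
) -> FeedForwardTable:
    """Volume-targeted starting speeds for the default lung.

    End-inspiratory statics with the servo gap shut: the plateau reached in
    one inspiratory time approaches P2 - cracking = V/C, and the patient
    branch carries P2 = (P1 + bias)/2, so P1 = 2*(V/C + cracking) - bias.
    """
    speeds = tuple(
        _speed_for_p1(2.0 * (tv / compliance + cracking) - pilot_bias)
        for tv in targets
    )
    return FeedForwardTable(targets=tuple(float(t) for t in targets), speeds=speeds)


def default_pressure_table(
    cracking: float = 5.0,
    pilot_bias: float = 3.0,
    targets: Sequence[float] = (5, 10, 15, 20, 25, 30, 35),
) -> FeedForwardTable:
    """Pressure-targeted starting speeds: P1 = 2*(PIP + cracking) - bias."""
    speeds = tuple(
        _speed_for_p1(2.0 * (pip + cracking) - pilot_bias) for pip in targets
    )
    return FeedForwardTable(targets=tuple(float(t) for t in targets), speeds=speeds)


def default_peep_table(
    vent_split_open: float = 0.5,
    pilot_bias: float = 3.0,
    targets: Sequence[float] = (0, 2, 4, 6, 8, 10, 12),
) -> FeedForwardTable:
    """Exhalation starting speeds holding the pilot at the set PEEP.

    With the servo gap fully open a fraction ``vent_split_open`` of P1 vents
    as P3; the pilot then carries P4 = ((1 - f3)*P1 - bias)/2 = PEEP, so
    P1 = (2*PEEP + bias)/(1 - f3).
    """
    speeds = tuple(
        _speed_for_p1((2.0 * peep + pilot_bias) / (1.0 - vent_split_open))
        for peep in targets
    )
    return FeedForwardTable(targets=tuple(float(t) for t in targets), speeds=speeds)
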