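"""Synthetic test lung.

A linear single-compartment model of the respiratory system standing in for a
physical test lung.  The airway-opening pressure applied by the ventilator
circuit drives flow against a series resistance into an elastic compartment:

    P_applied = R * Q + V / C + P_baseline + P_effort

with volume ``V`` (ml above functional residual capacity), flow ``Q`` (ml/s,
positive into the lung), compliance ``C`` (ml/cmH2O) and resistance ``R``
(cmH2O per L/s).  ``P_effort`` is the (non-positive) muscle pressure of a
spontaneously breathing patient; pulling it negative sucks gas in, which is
how patient triggering is exercised.

Scenarios describe the test conditions every other module is run against:
quiet passive ventilation, spontaneous inspiratory efforts, and opening or
closing of a leak path that emulates patient-circuit disconnection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LungParams",
    "LungState",
    "Scenario",
    "step_lung",
    "make_scenario",
    "SCENARIO_KINDS",
]

#: recognised scenario kinds
SCENARIO_KINDS = ("normal", "spontaneous", "disconnect", "reconnect")

#: resistance below this is treated as the instantaneous-equilibration limit
_R_EPS = 1e-9


class InvalidStateError(ValueError):
    """Raised when a lung update is fed non-finite or inconsistent values."""


@dataclass(frozen=True)
class LungParams:
    """Mechanical parameters of the one-compartment lung.

    Defaults are typical adult values: C = 50 ml/cmH2O, R = 5 cmH2O/(L/s),
    giving a mechanical time constant tau = R*C = 0.25 s.
    """

    compliance: float = 50.0  # ml per cmH2O
    resistance: float = 5.0  # cmH2O per (L/s)
    baseline_pressure: float = 0.0  # cmH2O (atmospheric reference)
    #: optional muscle-pressure waveform, cmH2O as a function of time (s);
    #: values must be <= 0 (inspiratory effort lowers alveolar pressure)
    effort_profile: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if not (self.compliance > 0):
            raise ValueError(f"compliance must be > 0, got {self.compliance}")
        if self.resistance < 0:
            raise ValueError(f"resistance must be >= 0, got {self.resistance}")

    def effort_at(self, t: float) -> float:
        """Muscle pressure (cmH2O, <= 0) at time ``t``."""
        if self.effort_profile is None:
            return 0.0
        e = float(self.effort_profile(t))
        if e > 1e-12:
            raise InvalidStateError(f"effort must be <= 0, got {e} at t={t}")
        return min(e, 0.0)


@dataclass(frozen=True)
class LungState:
    """Instantaneous state of the lung."""

    time: float = 0.0  # s
    volume_above_frc: float = 0.0  # ml
    flow: float = 0.0  # ml/s, positive into the lung
    alveolar_pressure: float = 0.0  # cmH2O
    airway_pressure: float = 0.0  # cmH2O (pressure applied at the opening)

    def __post_init__(self) -> None:
        if self.volume_above_frc < 0:
            raise InvalidStateError(
                f"volume_above_frc must be >= 0, got {self.volume_above_frc}"
            )


def step_lung(
    state: LungState,
    params: LungParams,
    applied_pressure: float,
    dt: float,
) -> LungState:
    """Advance the lung by ``dt`` under a given airway-opening pressure.

    Explicit fixed-step Euler, mirroring a firmware loop.  For a resistive
    lung the caller must keep ``dt <= 0.1 * R * C`` (stability contract);
    the default lung at dt = 1 ms satisfies this with a wide margin.

    Parameters
    ----------
    applied_pressure : cmH2O applied at the airway opening.
    dt : time step in seconds.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be > 0, got {dt}")
    if not (math.isfinite(applied_pressure) and math.isfinite(state.volume_above_frc)):
        raise InvalidStateError("non-finite lung inputs")

    tau = params.resistance * params.compliance / 1000.0  # s (R in cmH2O/(L/s))
    if params.resistance > _R_EPS and dt > 0.1 * tau:
        raise ValueError(
            f"dt={dt} violates stability contract dt <= 0.1*R*C = {0.1 * tau:.4g} s"
        )

    effort = params.effort_at(state.time)
    p_elastic = state.volume_above_frc / params.compliance
    driving = applied_pressure - params.baseline_pressure - p_elastic - effort

    if params.resistance > _R_EPS:
        flow = 1000.0 * driving / params.resistance  # ml/s
        volume = state.volume_above_frc + flow * dt
        if volume < 0.0:
            # the compartment cannot empty below FRC
            flow = -state.volume_above_frc / dt
            volume = 0.0
    else:
        # zero-resistance limit: instantaneous elastic equilibrium
        volume = max(
            0.0,
            params.compliance
            * (applied_pressure - params.baseline_pressure - effort),
        )
        flow = (volume - state.volume_above_frc) / dt

    t_new = state.time + dt
    alveolar = params.baseline_pressure + volume / params.compliance + params.effort_at(t_new)
    return LungState(
        time=t_new,
        volume_above_frc=volume,
        flow=flow,
        alveolar_pressure=alveolar,
        airway_pressure=applied_pressure,
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Test-condition script applied on top of the lung.

    ``event_times`` alternate the leak path on/off for disconnect/reconnect
    scenarios (odd index = leak opens, even index closes again... the first
    time opens it).  ``effort_times`` are the onsets of half-sine inspiratory
    efforts for spontaneous scenarios.
    """

    kind: str = "normal"
    event_times: Tuple[float, ...] = ()
    leak_conductance: float = 0.0  # ml/s per cmH2O when the leak is open
    effort_times: Tuple[float, ...] = ()
    effort_amplitude: float = 0.0  # cmH2O, <= 0
    effort_duration: float = 0.6  # s

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}"
            )
        if self.leak_conductance < 0:
            raise ValueError("leak_conductance must be >= 0")
        if any(b <= a for a, b in zip(self.event_times, self.event_times[1:])):
            raise ValueError("event_times must be strictly increasing")
        if any(b <= a for a, b in zip(self.effort_times, self.effort_times[1:])):
            raise ValueError("effort_times must be strictly increasing")
        if self.effort_amplitude > 0:
            raise ValueError("effort_amplitude must be <= 0")

    def leak_at(self, t: float) -> float:
        """Leak-path conductance active at time ``t`` (ml/s per cmH2O)."""
        n_past = sum(1 for et in self.event_times if t >= et)
        return self.leak_conductance if n_past % 2 == 1 else 0.0

    def effort_at(self, t: float) -> float:
        """Muscle pressure (cmH2O, <= 0) of the scripted efforts at ``t``."""
        p = 0.0
        for t0 in self.effort_times:
            if t0 <= t <= t0 + self.effort_duration:
                p += self.effort_amplitude * math.sin(
                    math.pi * (t - t0) / self.effort_duration
                )
        return p


def make_scenario(
    kind: str,
    *,
    seed: int = 42,
    duration: float = 120.0,
    event_times: Optional[Sequence[float]] = None,
    leak_conductance: float = 500.0,
    effort_times: Optional[Sequence[float]] = None,
    n_efforts: Optional[int] = None,
    effort_amplitude: float = -3.0,
    effort_duration: float = 0.6,
) -> Scenario:
    """Build a deterministic scenario of the given kind.

    ``normal``       — no events, no leak, no effort.
    ``spontaneous``  — half-sine inspiratory efforts (default amplitude
                       -3 cmH2O, 0.6 s) at ``effort_times``; if not given,
                       ``n_efforts`` onsets are drawn uniformly over
                       ``duration`` from a generator seeded with ``seed``.
    ``disconnect``   — leak path opens at event_times[0] (default 30 s).
    ``reconnect``    — leak opens then closes (default 30 s and 60 s).
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(
            f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}"
        )
    if kind == "normal":
        return Scenario(kind=kind)
    if kind == "spontaneous":
        if effort_times is None:
            n = n_efforts if n_efforts is not None else max(1, int(duration / 6.0))
            rng = np.random.default_rng(seed)
            times = np.sort(rng.uniform(0.0, duration, size=n))
            # enforce strict increase and pulse separation
            keep = [times[0]]
            for t in times[1:]:
                if t - keep[-1] > effort_duration:
                    keep.append(t)
            effort_times = keep
        return Scenario(
            kind=kind,
            effort_times=tuple(float(t) for t in effort_times),
            effort_amplitude=effort_amplitude,
            effort_duration=effort_duration,
        )
    # disconnect / reconnect
    if event_times is None:
        event_times = (30.0,) if kind == "disconnect" else (30.0, 60.0)
    return Scenario(
        kind=kind,
        event_times=tuple(float(t) for t in event_times),
        leak_conductance=leak_conductance,
    )
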