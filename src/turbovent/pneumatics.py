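"""Behavioral pneumatic models: turbine, pressure release mechanism (PRM),
one-way valve, passive PEEP valve, and the combined circuit update.

The gas path is: turbine -> PRM -> one-way (check) valve -> patient wye ->
lung, with the PEEP valve hanging off the wye and piloted by the PRM's P4
line.  The PRM divides the turbine pressure P1 into a patient component P2,
a vented component P3 (through the servo-actuated gap) and a PEEP-pilot
component P4, with the additive balance

    P1 = P2 + P3 + P4

enforced exactly at every update.  During inhalation the servo gap is shut
(P3 = 0) and P1 splits between patient and pilot; opening the gap during
exhalation raises P3 and pulls both P2 and P4 down, letting the patient
exhale through the PEEP valve while the pilot pressure P4 sets the
end-expiratory floor.

The patient/pilot split carries a fixed bias just below the one-way valve's
cracking pressure: P2 = P4 + bias whenever there is headroom.  The
end-inspiratory plateau (P2 - cracking) then sits slightly below the pilot
pressure, so the PEEP valve stays sealed for the whole inhalation with a
small margin, while during exhalation an inspiratory effort pulling the wye
pressure more than (cracking - bias) below the pilot still cracks the check
valve and draws measurable trigger flow — the gap acts as the trigger
deadband.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

from .patient_sim import LungParams, LungState, Scenario, step_lung

__all__ = [
    "TurbineParams",
    "PRMParams",
    "CircuitParams",
    "PneumaticState",
    "turbine_pressure",
    "prm_balance",
    "one_way_flow",
    "peep_valve_flow",
    "step_circuit",
]

log = logging.getLogger(__name__)

#: conservation tolerance for P1 = P2 + P3 + P4
EQ_BALANCE_TOL = 1e-9

#: floor on lung resistance used in the node solve, cmH2O/(L/s)
_R_FLOOR = 0.01


class InvalidStateError(ValueError):
    """Raised on non-finite or physically impossible pneumatic inputs."""


@dataclass(frozen=True)
class TurbineParams:
    """Centrifugal blower ratings: 70 cmH2O stall pressure, 240 L/min free flow.

    The fan laws adopted are stall pressure proportional to speed squared and
    free flow proportional to speed; the instantaneous operating point is the
    linear intersection of the fan curve with the circuit load.
    """

    max_pressure: float = 70.0  # cmH2O at full speed, zero flow
    max_flow: float = 240_000.0 / 60.0  # ml/s at full speed, zero pressure
    speed_command_max: int = 255

    def __post_init__(self) -> None:
        if not (self.max_pressure > 0 and self.max_flow > 0):
            raise ValueError("turbine ratings must be positive")


@dataclass(frozen=True)
class PRMParams:
    """Servo-actuated pressure release mechanism.

    spring_preload is the normalized servo travel the actuator must exceed
    before the spring-loaded gap cracks open.  vent_conductance_open sets the
    fully-open gap conductance relative to the through path (dimensionless
    split weight); vent_flow_conductance converts the vented pressure P3 into
    an actual vent flow (ml/s per cmH2O) loading the turbine.
    pilot_bias (cmH2O) is the fixed P2 - P4 offset; it defaults to 2 cmH2O
    below the one-way-valve cracking pressure so the check valve carries a
    deadband during exhalation — without it, controller jitter and the
    natural refill-to-PEEP flow would produce spurious trigger flow at the
    flow sensor.
    """

    spring_preload: float = 0.05  # normalized servo travel
    vent_conductance_open: float = 1.0  # split weight of the gap, fully open
    through_conductance: float = 1.0  # split weight of the through path
    vent_flow_conductance: float = 50.0  # ml/s per cmH2O of P3
    pilot_bias: float = 3.0  # cmH2O

    def __post_init__(self) -> None:
        if not (0.0 <= self.spring_preload < 1.0):
            raise ValueError("spring_preload must be in [0, 1)")
        for name in ("vent_conductance_open", "through_conductance",
                     "vent_flow_conductance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pilot_bias < 0:
            raise ValueError("pilot_bias must be >= 0")

    def gap_fraction(self, servo_open_fraction: float) -> float:
        """Effective gap opening after the spring preload is overcome."""
        if not (0.0 <= servo_open_fraction <= 1.0):
            raise ValueError("servo_open_fraction must be in [0, 1]")
        if self.spring_preload >= 1.0:
            return 0.0
        return max(0.0, servo_open_fraction - self.spring_preload) / (
            1.0 - self.spring_preload
        )

    def vent_split(self, servo_open_fraction: float) -> float:
        """Fraction of P1 diverted to P3 at the given servo opening."""
        g_gap = self.vent_conductance_open * self.gap_fraction(servo_open_fraction)
        denom = g_gap + self.through_conductance
        return g_gap / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class CircuitParams:
    """Everything between the turbine outlet and the lung."""

    turbine: TurbineParams = field(default_factory=TurbineParams)
    prm: PRMParams = field(default_factory=PRMParams)
    cv_cracking: float = 5.0  # one-way valve cracking pressure, cmH2O
    cv_conductance: float = 100.0  # ml/s per cmH2O above cracking
    peep_conductance: float = 100.0  # PEEP valve, ml/s per cmH2O


@dataclass(frozen=True)
class PneumaticState:
    """Node pressures and branch flows at one time step.

    p_wye is the patient-wye (proximal airway) pressure, the quantity the
    pressure sensor reads.  Flows are ml/s: flow_patient through the one-way
    valve toward the patient, flow_vent through the PRM gap, flow_peep out of
    the PEEP valve, flow_leak through any disconnection leak.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p_wye: float = 0.0
    flow_patient: float = 0.0
    flow_vent: float = 0.0
    flow_pilot: float = 0.0
    flow_peep: float = 0.0
    flow_leak: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.p1, self.p2, self.p3, self.p4):
            if not math.isfinite(v):
                raise InvalidStateError("non-finite node pressure")
        if abs(self.p1 - (self.p2 + self.p3 + self.p4)) > EQ_BALANCE_TOL:
            raise InvalidStateError(
                f"pressure balance violated: p1={self.p1} vs "
                f"p2+p3+p4={self.p2 + self.p3 + self.p4}"
            )

    @property
    def balance_residual(self) -> float:
        return self.p1 - (self.p2 + self.p3 + self.p4)


def turbine_pressure(
    speed_command: float, params: TurbineParams = TurbineParams()
) -> Tuple[float, float]:
    """Stall pressure (cmH2O) and free-flow limit (ml/s) at a speed command.

    Out-of-range commands are clamped with a logged warning.
    """
    s = speed_command
    if s < 0 or s > params.speed_command_max:
        log.warning("speed command %s out of range, clamping", s)
        s = min(max(s, 0.0), float(params.speed_command_max))
    frac = s / params.speed_command_max
    return params.max_pressure * frac * frac, params.max_flow * frac


def _split_nodes(p1: float, f3: float, bias: float) -> Tuple[float, float, float]:
    """Divide p1 into (p2, p3, p4) for a given vent split fraction.

    Computed so that p2 + p3 + p4 reproduces p1 to floating-point cancellation
    (well inside the 1e-9 balance tolerance).
    """
    p3 = f3 * p1
    p_rem = p1 - p3
    p4 = max(0.0, 0.5 * (p_rem - bias))
    p2 = p_rem - p4
    return p2, p3, p4


def prm_balance(
    p1: float,
    servo_open_fraction: float,
    params: PRMParams = PRMParams(),
    downstream_load: Optional[float] = None,
) -> PneumaticState:
    """Split the inlet pressure across the PRM's three outputs.

    Increasing the servo opening weakly increases P3 and weakly decreases P2
    and P4.  ``downstream_load`` (ml/s per cmH2O), if given, is used to
    estimate the patient-branch flow at this split; it does not affect the
    pressure division.
    """
    if not math.isfinite(p1):
        raise InvalidStateError("p1 must be finite")
    if p1 < 0:
        raise InvalidStateError(f"p1 must be >= 0, got {p1}")
    f3 = params.vent_split(servo_open_fraction)
    p2, p3, p4 = _split_nodes(p1, f3, params.pilot_bias)
    g_gap = params.vent_flow_conductance * params.gap_fraction(servo_open_fraction)
    q_vent = g_gap * p3
    q_patient = 0.0 if downstream_load is None else downstream_load * p2
    return PneumaticState(
        p1=p1, p2=p2, p3=p3, p4=p4, flow_vent=q_vent, flow_patient=q_patient
    )


def one_way_flow(
    delta_p: float, cracking: float = 5.0, conductance: float = 100.0
) -> float:
    """Flow (ml/s) through the check valve for a pressure difference delta_p.

    Zero at or below the cracking pressure (default 5 cmH2O), linear above,
    never negative — the rubber membrane blocks backflow entirely.
    """
    return conductance * max(0.0, delta_p - cracking)


def peep_valve_flow(
    p_patient: float, p_pilot: float, conductance: float = 100.0
) -> float:
    """Flow (ml/s) out of the passive PEEP valve.

    The pilot pressure presses the diaphragm film onto the seat: sealed while
    p_patient <= p_pilot, linear conductance above.
    """
    return conductance * max(0.0, p_patient - p_pilot)


def _solve_operating_point(
    stall: float,
    q_max: float,
    f3: float,
    g_vent: float,
    bias: float,
    crack: float,
    g_cv: float,
    g_pp: float,
    g_lung: float,
    g_leak: float,
    p_alv_eff: float,
) -> Tuple[float, float, float, float]:
    """Solve the loaded turbine pressure p1 and the wye pressure.

    The fan curve p1 = stall*(1 - q_total/q_max) is intersected with the
    piecewise-linear circuit load.  For each combination of element states
    (check valve conducting or not, PEEP valve open or not, pilot branch
    above or below the bias headroom) the system is linear in p1 and solved
    in closed form; the combination whose assumptions are consistent with its
    own solution is returned.

    Returns (p1, p_wye, q_cv, q_peep).
    """
    if stall <= 0.0 or q_max <= 0.0:
        # turbine off: wye settles between lung, pilot(0) and leak
        denom = g_lung + g_leak + g_pp
        p_w = g_lung * p_alv_eff / denom if denom > 0 else 0.0
        if p_w < 0.0:
            p_w = g_lung * p_alv_eff / (g_lung + g_leak) if (g_lung + g_leak) else 0.0
            p_w = min(p_w, 0.0)
            return 0.0, p_w, 0.0, 0.0
        return 0.0, p_w, 0.0, g_pp * p_w

    k_vent = g_vent * f3  # vent flow = k_vent * p1

    best = None
    best_viol = math.inf
    for a_cv in (1, 0):
        for b_pp in (1, 0):
            for c_split in (1, 0):
                # node pressures as linear functions of p1: p2 = u2*p1 + v2 ...
                if c_split:
                    u4, v4 = 0.5 * (1.0 - f3), -0.5 * bias
                else:
                    u4, v4 = 0.0, 0.0
                u2, v2 = (1.0 - f3) - u4, -v4

                d = a_cv * g_cv + b_pp * g_pp + g_lung + g_leak
                # p_wye = (a*g_cv*(p2-crack) + b*g_pp*p4 + g_lung*p_alv)/d
                uw = (a_cv * g_cv * u2 + b_pp * g_pp * u4) / d
                vw = (
                    a_cv * g_cv * (v2 - crack)
                    + b_pp * g_pp * v4
                    + g_lung * p_alv_eff
                ) / d
                # q_cv = a*g_cv*(p2 - crack - p_wye) = A*p1 + B
                A = a_cv * g_cv * (u2 - uw)
                B = a_cv * g_cv * (v2 - crack - vw)
                # fan curve: p1 = stall*(1 - (q_cv + k_vent*p1)/q_max)
                denom = 1.0 + stall * (A + k_vent) / q_max
                p1 = stall * (1.0 - B / q_max) / denom
                if p1 < 0.0:
                    p1 = 0.0
                p2, p3, p4 = _split_nodes(p1, f3, bias)
                p_w = uw * p1 + vw
                # consistency of the assumed element states
                viol = 0.0
                margin_cv = p2 - crack - p_w
                viol += max(0.0, -margin_cv) if a_cv else max(0.0, margin_cv)
                margin_pp = p_w - p4
                viol += max(0.0, -margin_pp) if b_pp else max(0.0, margin_pp)
                rem = (1.0 - f3) * p1 - bias
                viol += max(0.0, -rem) if c_split else max(0.0, rem)
                if viol <= 1e-9:
                    q_cv = a_cv * g_cv * max(0.0, margin_cv)
                    q_peep = b_pp * g_pp * max(0.0, margin_pp)
                    return p1, p_w, q_cv, q_peep
                if viol < best_viol:
                    best_viol = viol
                    q_cv = a_cv * g_cv * max(0.0, margin_cv)
                    q_peep = b_pp * g_pp * max(0.0, margin_pp)
                    best = (p1, p_w, q_cv, q_peep)
    # fall back to the least-inconsistent combination (boundary cases)
    assert best is not None
    return best


def step_circuit(
    speed_command: float,
    servo_open_fraction: float,
    lung: LungState,
    lung_params: LungParams,
    scenario: Scenario,
    dt: float,
    circuit: CircuitParams = CircuitParams(),
) -> Tuple[PneumaticState, LungState]:
    """One synchronized update of turbine -> PRM -> valves -> lung.

    Solves the quasi-static pneumatic network at the current lung state,
    honoring the additive P1 = P2 + P3 + P4 balance and any active leak path,
    then advances the lung one Euler step under the resulting wye pressure.
    """
    stall, q_max = turbine_pressure(speed_command, circuit.turbine)
    prm = circuit.prm
    f3 = prm.vent_split(servo_open_fraction)
    g_vent = prm.vent_flow_conductance * prm.gap_fraction(servo_open_fraction)

    r_eff = max(lung_params.resistance, _R_FLOOR)
    g_lung = 1000.0 / r_eff
    g_leak = scenario.leak_at(lung.time)
    effort = lung_params.effort_at(lung.time) + scenario.effort_at(lung.time)
    p_alv_eff = (
        lung_params.baseline_pressure
        + lung.volume_above_frc / lung_params.compliance
        + effort
    )

    p1, p_w, q_cv, q_peep = _solve_operating_point(
        stall,
        q_max,
        f3,
        g_vent,
        prm.pilot_bias,
        circuit.cv_cracking,
        circuit.cv_conductance,
        circuit.peep_conductance,
        g_lung,
        g_leak,
        p_alv_eff,
    )
    p2, p3, p4 = _split_nodes(p1, f3, prm.pilot_bias)

    pneumo = PneumaticState(
        p1=p1,
        p2=p2,
        p3=p3,
        p4=p4,
        p_wye=p_w,
        flow_patient=q_cv,
        flow_vent=g_vent * p3,
        flow_peep=q_peep,
        flow_leak=g_leak * p_w,
    )

    # advance the lung under the wye pressure; combine scripted scenario
    # effort with any effort profile on the lung itself
    if scenario.effort_times:
        params = LungParams(
            compliance=lung_params.compliance,
            resistance=lung_params.resistance,
            baseline_pressure=lung_params.baseline_pressure,
            effort_profile=_combined_effort(lung_params, scenario),
        )
    else:
        params = lung_params
    new_lung = step_lung(lung, params, p_w, dt)
    return pneumo, new_lung


def _combined_effort(lung_params: LungParams, scenario: Scenario):
    base = lung_params.effort_profile

    def effort(t: float) -> float:
        e = scenario.effort_at(t)
        if base is not None:
            e += base(t)
        return e

    return effort
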