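"""Breath timing, PRVC/PCV mode state machines, SIMV triggering, alarms and
patient-circuit disconnection detection — the firmware's top-level loop.

A breath cycle lasts BCT = 60/BPM seconds and is the sum of the inspiration
and expiration times.  In PRVC (pressure-regulated volume control) each
breath is delivered at a constant turbine speed which the accumulating
proportional rule corrects breath-to-breath from the volume error, starting
from a feed-forward speed.  In PCV (pressure control ventilation) a
per-sample PID holds the set peak inspiratory pressure during inhalation.
In both modes exhalation opens the PRM servo gap and a PID regulates the
turbine so the PEEP-valve pilot holds the set PEEP.

When SIMV is enabled, a patient inspiratory effort sensed as flow at or above
the trigger threshold inside the synchronization window — the final
``sync_window_fraction`` of the cycle, per nonSyncTime = BCT*(1 - fraction)
and syncTime = nonSyncTime - Ti measured from the start of expiration —
starts the next breath early.

Safety logic: the airway pressure is hard-capped at p_max (the inhale speed
collapses to the floor if the cap is hit); a band-filtered end-inspiratory
PIP below 5 cmH2O raises the disconnection alarm and drops the turbine to a
low probe speed until the pressure signal returns; per-breath tidal volume,
PIP and PEEP are checked against operator alarm bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .control import (
    ControllerState,
    FeedForwardTable,
    default_peep_table,
    default_pressure_table,
    default_volume_table,
    feed_forward_lookup,
    p_update,
    pid_update,
    MIN_SPEED,
    SPEED_MAX,
)
from .patient_sim import LungParams, LungState, Scenario, make_scenario
from .pneumatics import CircuitParams, step_circuit
from .sensing import (
    DEFAULT_CALIBRATION,
    FilterConfig,
    SensorCalibration,
    analog_to_cmH2O,
    band_filter,
    simulate_flow_sensor,
    simulate_pressure_sensor,
)

__all__ = [
    "VentSettings",
    "AlarmBounds",
    "BreathTiming",
    "BreathRecord",
    "AlarmState",
    "RunGains",
    "RunResult",
    "compute_timing",
    "simv_should_trigger",
    "detect_disconnection",
    "check_alarms",
    "run_prvc",
    "run_pcv",
    "run_mode",
    "DISCONNECTION_PIP_THRESHOLD",
]

#: end-inspiratory PIP below this (cmH2O) flags a patient-circuit disconnection
DISCONNECTION_PIP_THRESHOLD = 5.0

#: GUI-enforced setting ranges (firmware capacity is higher)
GUI_RANGES = {
    "tidal_volume": (100.0, 999.0),
    "pip_target": (0.0, 35.0),
    "bpm": (6.0, 60.0),
    "peep": (0.0, 12.0),
}


class SettingsError(ValueError):
    """Raised for ventilator settings outside the permitted ranges."""


@dataclass(frozen=True)
class AlarmBounds:
    """Operator low/high alarm bounds per monitored quantity."""

    tv: Tuple[float, float] = (100.0, 990.0)  # ml
    pip: Tuple[float, float] = (0.0, 55.0)  # cmH2O
    peep: Tuple[float, float] = (0.0, 20.0)  # cmH2O

    def __post_init__(self) -> None:
        for name in ("tv", "pip", "peep"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise SettingsError(f"{name} alarm bounds must satisfy low < high")


@dataclass(frozen=True)
class VentSettings:
    """User-facing mode parameters, validated against the GUI ranges."""

    mode: str = "PRVC"  # PRVC or PCV
    simv: bool = False
    tidal_volume: float = 350.0  # ml (PRVC target)
    bpm: float = 12.0  # breaths/min
    ti: float = 2.0  # s inspiration time
    peep: float = 5.0  # cmH2O
    pip_target: float = 20.0  # cmH2O (PCV target)
    p_max: float = 60.0  # cmH2O firmware hard cap
    trigger_flow: float = 20.0  # ml/s SIMV flow threshold
    sync_window_fraction: float = 0.1
    alarms: AlarmBounds = field(default_factory=AlarmBounds)

    def __post_init__(self) -> None:
        if self.mode not in ("PRVC", "PCV"):
            raise SettingsError(f"unknown mode {self.mode!r}")
        for name, (lo, hi) in GUI_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise SettingsError(f"{name}={v} outside GUI range [{lo}, {hi}]")
        bct = 60.0 / self.bpm
        if not (0 < self.ti < bct):
            raise SettingsError(f"ti={self.ti} must be < breath cycle time {bct}")
        if self.p_max < self.pip_target:
            raise SettingsError("p_max must be >= pip_target")
        if not (0.0 < self.sync_window_fraction < 1.0):
            raise SettingsError("sync_window_fraction must be in (0, 1)")
        if self.trigger_flow <= 0:
            raise SettingsError("trigger_flow must be > 0")


@dataclass(frozen=True)
class BreathTiming:
    """Derived cycle times (all seconds)."""

    bct: float
    ti: float
    te: float
    non_sync_time: float
    sync_time: float


def compute_timing(
    bpm: float, ti: float, sync_window_fraction: float = 0.1
) -> BreathTiming:
    """Breath cycle time, expiratory time and the SIMV window boundaries.

    BCT = 60/BPM, Te = BCT - Ti, nonSyncTime = BCT*(1 - window fraction),
    syncTime = nonSyncTime - Ti (measured from the start of expiration, the
    trigger window is the final window-fraction share of the cycle).
    """
    if bpm <= 0:
        raise SettingsError("bpm must be > 0")
    bct = 60.0 / bpm
    if not (0 < ti < bct):
        raise SettingsError(f"ti={ti} must lie in (0, BCT={bct})")
    non_sync = bct * (1.0 - sync_window_fraction)
    sync = non_sync - ti
    if sync <= 0:
        raise SettingsError(
            "sync window configuration leaves no expiratory non-sync time"
        )
    return BreathTiming(bct=bct, ti=ti, te=bct - ti, non_sync_time=non_sync, sync_time=sync)


def simv_should_trigger(
    elapsed_in_cycle: float,
    timing: BreathTiming,
    sensed_flow: float,
    trigger_flow: float,
    phase: str,
) -> bool:
    """Patient-trigger decision.

    True iff the phase is expiratory, the elapsed expiratory time lies inside
    the synchronization window (sync_time < t_exp <= Te — the final
    window-fraction share of the cycle, ending at the next machine breath),
    and the sensed inspiratory flow meets the threshold (>= comparator).
    """
    if phase != "exhale":
        return False
    t_exp = elapsed_in_cycle - timing.ti
    if not (timing.sync_time < t_exp <= timing.te):
        return False
    return sensed_flow >= trigger_flow


def detect_disconnection(pip_estimate: float, phase: str) -> bool:
    """True iff at end-inspiration the filtered PIP is below 5 cmH2O."""
    return phase in ("inhale_end", "inspiratory_end") and (
        pip_estimate < DISCONNECTION_PIP_THRESHOLD
    )


@dataclass(frozen=True)
class BreathRecord:
    """Per-breath summary."""

    breath_index: int
    t_start: float  # s
    delivered_volume: float  # ml, end-inspiratory minus start volume
    pip: float  # cmH2O, band-filtered end-inspiratory pressure
    peep_estimate: float  # cmH2O, band-filtered end-expiratory pressure
    min_pressure: float  # cmH2O, true minimum wye pressure over exhalation
    trigger_type: str = "machine"  # machine | patient
    alarms: frozenset = frozenset()
    motor_speed_insp: float = 0.0
    ti_actual: float = 0.0
    te_actual: float = 0.0
    flow_sensor_ok: bool = True

    def __post_init__(self) -> None:
        if self.delivered_volume < -1e-9:
            raise ValueError("delivered_volume must be >= 0")


@dataclass(frozen=True)
class AlarmState:
    """Alarms active after the most recent evaluation."""

    active: frozenset
    bounds: AlarmBounds
    audible: bool = False


def check_alarms(record: BreathRecord, settings: VentSettings) -> AlarmState:
    """Evaluate TV/PIP/PEEP bound alarms and the flow-sensor-disconnect alarm.

    One alarm per monitored quantity outside its [low, high] bounds; the
    flow-sensor alarm fires when flow readings were absent or non-finite for
    the whole breath.  The circuit-disconnection alarm is raised by the mode
    loop itself (it needs the PIP history) and merged into the breath record.
    """
    b = settings.alarms
    active = set()
    if not (b.tv[0] <= record.delivered_volume <= b.tv[1]):
        active.add("TV")
    if not (b.pip[0] <= record.pip <= b.pip[1]):
        active.add("PIP")
    if not (b.peep[0] <= record.peep_estimate <= b.peep[1]):
        active.add("PEEP")
    if not record.flow_sensor_ok:
        active.add("flow_sensor_disconnect")
    return AlarmState(active=frozenset(active), bounds=b, audible=bool(active))


# ---------------------------------------------------------------------------
# the closed-loop engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunGains:
    """Controller gains and safety speeds used by the mode loops.

    Tuned once on the default synthetic lung; all overridable via config.
    """

    kp_volume: float = 0.1  # counts per ml, per-breath PRVC update
    pressure_kp: float = 3.0  # counts per cmH2O, per-sample PCV PID
    pressure_ki: float = 60.0  # counts per cmH2O*s
    pressure_kd: float = 0.0
    peep_kp: float = 3.0
    peep_ki: float = 60.0
    peep_kd: float = 0.0
    min_speed: float = MIN_SPEED
    #: inhale speed while the disconnection alarm is active; sized to build
    #: >5 cmH2O against the default lung when reconnected, ~0 when open
    probe_speed: float = 140.0
    integral_limit: float = 4.0  # cmH2O*s anti-windup clamp


@dataclass(frozen=True)
class SensorNoise:
    pressure_sd_counts: float = 1.0
    flow_sd_ml_s: float = 5.0


_SAMPLE_KEYS = (
    "time",
    "p1",
    "p2",
    "p3",
    "p4",
    "p_wye",
    "pressure_sensed",
    "flow_sensed",
    "flow_lung",
    "volume",
    "motor_speed",
    "servo_fraction",
    "phase",
    "breath_index",
)


@dataclass
class RunResult:
    """Waveforms and per-breath records from one closed-loop run."""

    settings: VentSettings
    seed: int
    dt: float
    samples: Dict[str, list]
    breaths: List[BreathRecord]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({k: self.samples[k] for k in _SAMPLE_KEYS})

    @property
    def max_balance_residual(self) -> float:
        """Largest |P1 - (P2+P3+P4)| over the whole run."""
        p1 = np.asarray(self.samples["p1"])
        tot = (
            np.asarray(self.samples["p2"])
            + np.asarray(self.samples["p3"])
            + np.asarray(self.samples["p4"])
        )
        return float(np.max(np.abs(p1 - tot))) if p1.size else 0.0


def run_mode(
    settings: VentSettings,
    lung: Optional[LungParams] = None,
    n_breaths: int = 20,
    seed: int = 0,
    scenario: Optional[Scenario] = None,
    gains: Optional[RunGains] = None,
    noise: Optional[SensorNoise] = None,
    circuit: Optional[CircuitParams] = None,
    calibration: SensorCalibration = DEFAULT_CALIBRATION,
    dt: float = 1e-3,
    lung_params_schedule: Optional[Dict[int, LungParams]] = None,
) -> RunResult:
    """Run the selected mode closed-loop against the synthetic lung.

    ``lung_params_schedule`` optionally swaps the lung parameters at given
    breath indices (e.g. halving compliance mid-run to exercise adaptation).
    Identical arguments and seed give bit-identical results.
    """
    lung_params = lung if lung is not None else LungParams()
    scenario = scenario if scenario is not None else make_scenario("normal")
    gains = gains if gains is not None else RunGains()
    noise = noise if noise is not None else SensorNoise()
    circuit = circuit if circuit is not None else CircuitParams()
    rng = np.random.default_rng(seed)

    timing = compute_timing(settings.bpm, settings.ti, settings.sync_window_fraction)
    n_insp = max(1, int(round(timing.ti / dt)))
    n_cycle = max(n_insp + 1, int(round(timing.bct / dt)))

    vol_table = default_volume_table(
        compliance=lung_params.compliance,
        cracking=circuit.cv_cracking,
        pilot_bias=circuit.prm.pilot_bias,
    )
    pres_table = default_pressure_table(
        cracking=circuit.cv_cracking, pilot_bias=circuit.prm.pilot_bias
    )
    peep_table = default_peep_table(
        vent_split_open=circuit.prm.vent_split(1.0),
        pilot_bias=circuit.prm.pilot_bias,
    )

    # persistent controllers
    if settings.mode == "PRVC":
        insp_base = feed_forward_lookup(settings.tidal_volume, vol_table)
    else:
        insp_base = feed_forward_lookup(settings.pip_target, pres_table)
    exh_base = feed_forward_lookup(settings.peep, peep_table)

    vol_ctrl = ControllerState(
        motor_speed=min(max(insp_base, gains.min_speed), SPEED_MAX),
        kp=gains.kp_volume,
        min_speed=gains.min_speed,
    )
    pres_pid = ControllerState(
        motor_speed=gains.min_speed,
        kp=gains.pressure_kp,
        ki=gains.pressure_ki,
        kd=gains.pressure_kd,
        integral_limit=gains.integral_limit,
    )
    peep_pid = ControllerState(
        motor_speed=gains.min_speed,
        kp=gains.peep_kp,
        ki=gains.peep_ki,
        kd=gains.peep_kd,
        integral_limit=gains.integral_limit,
    )

    samples: Dict[str, list] = {k: [] for k in _SAMPLE_KEYS}
    breaths: List[BreathRecord] = []
    state = LungState()
    t = 0.0
    disconnected = False
    trigger_type = "machine"
    pip_filter = FilterConfig(window_size=50, shrink_percent=0.5)

    def _sense(pneumo):
        counts = simulate_pressure_sensor(
            pneumo.p_wye, calibration, noise.pressure_sd_counts, rng
        )
        p = analog_to_cmH2O(counts, calibration)
        q = simulate_flow_sensor(pneumo.flow_patient, noise.flow_sd_ml_s, rng)
        return p, q

    def _record_sample(pneumo, lung_state, p_s, q_s, speed, servo, phase, b):
        samples["time"].append(lung_state.time)
        samples["p1"].append(pneumo.p1)
        samples["p2"].append(pneumo.p2)
        samples["p3"].append(pneumo.p3)
        samples["p4"].append(pneumo.p4)
        samples["p_wye"].append(pneumo.p_wye)
        samples["pressure_sensed"].append(p_s)
        samples["flow_sensed"].append(q_s)
        samples["flow_lung"].append(lung_state.flow)
        samples["volume"].append(lung_state.volume_above_frc)
        samples["motor_speed"].append(speed)
        samples["servo_fraction"].append(servo)
        samples["phase"].append(phase)
        samples["breath_index"].append(b)

    for b in range(n_breaths):
        if lung_params_schedule and b in lung_params_schedule:
            lung_params = lung_params_schedule[b]
        t_breath_start = state.time
        v_start = state.volume_above_frc
        insp_sensed: List[float] = []
        cap_latched = False

        # ---- inhalation -------------------------------------------------
        if settings.mode == "PCV":
            pres_pid = replace(pres_pid, last_error=0.0)
        speed = vol_ctrl.motor_speed if settings.mode == "PRVC" else insp_base
        for i in range(n_insp):
            if disconnected:
                speed_cmd = gains.probe_speed
            elif cap_latched:
                speed_cmd = gains.min_speed
            elif settings.mode == "PRVC":
                speed_cmd = vol_ctrl.motor_speed
            else:
                speed_cmd = speed
            pneumo, state = step_circuit(
                speed_cmd, 0.0, state, lung_params, scenario, dt, circuit
            )
            p_s, q_s = _sense(pneumo)
            insp_sensed.append(p_s)
            if p_s > settings.p_max:
                cap_latched = True
            if settings.mode == "PCV" and not (disconnected or cap_latched):
                pres_pid, out = pid_update(pres_pid, settings.pip_target - p_s, dt)
                speed = min(max(insp_base + out, gains.min_speed), SPEED_MAX)
            _record_sample(pneumo, state, p_s, q_s, speed_cmd, 0.0, "inhale", b)

        # ---- end-inspiration bookkeeping --------------------------------
        v_end_insp = state.volume_above_frc
        delivered = max(0.0, v_end_insp - v_start)
        window = min(pip_filter.window_size, len(insp_sensed))
        pip_est = band_filter(
            insp_sensed[-window:],
            FilterConfig(window_size=window, shrink_percent=pip_filter.shrink_percent),
        ).filtered_mean
        motor_speed_insp = speed_cmd

        newly_disconnected = detect_disconnection(pip_est, "inhale_end")
        reconnected = disconnected and not newly_disconnected
        if reconnected:
            disconnected = False
        elif newly_disconnected:
            disconnected = True
        if settings.mode == "PRVC" and not (disconnected or cap_latched):
            vol_ctrl = p_update(vol_ctrl, settings.tidal_volume - delivered)

        # ---- exhalation --------------------------------------------------
        peep_pid = replace(peep_pid, last_error=0.0)
        exh_sensed: List[float] = []
        min_pressure = math.inf
        trigger_next = "machine"
        speed = exh_base
        i = n_insp
        while i < n_cycle:
            elapsed = (i) * dt
            if disconnected:
                speed_cmd = gains.min_speed
            else:
                speed_cmd = speed
            pneumo, state = step_circuit(
                speed_cmd, 1.0, state, lung_params, scenario, dt, circuit
            )
            p_s, q_s = _sense(pneumo)
            exh_sensed.append(p_s)
            if pneumo.p_wye < min_pressure:
                min_pressure = pneumo.p_wye
            if not disconnected:
                peep_pid, out = pid_update(peep_pid, settings.peep - p_s, dt)
                # one-sided anti-windup: early exhalation legitimately runs
                # above PEEP while the lung empties, so the integral may only
                # trim the feed-forward upward, never wind below it
                if peep_pid.integral_accum < 0.0:
                    peep_pid = replace(peep_pid, integral_accum=0.0)
                    out = peep_pid.kp * peep_pid.last_error
                speed = min(max(exh_base + out, gains.min_speed), SPEED_MAX)
            _record_sample(pneumo, state, p_s, q_s, speed_cmd, 1.0, "exhale", b)
            i += 1
            if settings.simv and simv_should_trigger(
                i * dt, timing, q_s, settings.trigger_flow, "exhale"
            ):
                trigger_next = "patient"
                break

        # ---- breath record ----------------------------------------------
        window = min(pip_filter.window_size, len(exh_sensed))
        peep_est = band_filter(
            exh_sensed[-window:],
            FilterConfig(window_size=window, shrink_percent=pip_filter.shrink_percent),
        ).filtered_mean
        record = BreathRecord(
            breath_index=b,
            t_start=t_breath_start,
            delivered_volume=delivered,
            pip=pip_est,
            peep_estimate=peep_est,
            min_pressure=min_pressure if math.isfinite(min_pressure) else peep_est,
            trigger_type=trigger_type,
            motor_speed_insp=motor_speed_insp,
            ti_actual=n_insp * dt,
            te_actual=(i - n_insp) * dt,
        )
        alarm_state = check_alarms(record, settings)
        active = set(alarm_state.active)
        if disconnected:
            active.add("disconnection")
        record = replace(record, alarms=frozenset(active))
        breaths.append(record)
        trigger_type = trigger_next

    return RunResult(
        settings=settings, seed=seed, dt=dt, samples=samples, breaths=breaths
    )


def run_prvc(
    settings: VentSettings,
    lung: Optional[LungParams] = None,
    n_breaths: int = 20,
    seed: int = 0,
    **kwargs,
) -> RunResult:
    """Pressure-regulated volume control run (see ``run_mode``)."""
    if settings.mode != "PRVC":
        settings = replace(settings, mode="PRVC")
    return run_mode(settings, lung=lung, n_breaths=n_breaths, seed=seed, **kwargs)


def run_pcv(
    settings: VentSettings,
    lung: Optional[LungParams] = None,
    n_breaths: int = 20,
    seed: int = 0,
    **kwargs,
) -> RunResult:
    """Pressure control ventilation run (see ``run_mode``)."""
    if settings.mode != "PCV":
        settings = replace(settings, mode="PCV")
    return run_mode(settings, lung=lung, n_breaths=n_breaths, seed=seed, **kwargs)
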