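"""Telemetry frame codec, waveform writers, run configuration and the CLI.

The GUI and the firmware exchange settings as a fixed 27-character frame: a
single type character followed by zero-padded decimal fields.  The field
order and widths below are this package's documented convention (the wire
format it defines and round-trips); the historical firmware used the same
shape — one leading type character plus fixed-width numeric substrings.

Layout (27 characters total)::

    pos  width  field              encoding
    0    1      frame type         'v' settings, 'd' debug/telemetry
    1    2      mode code          integer (0 PCV, 1 PRVC; +10 = SIMV on)
    3    2      BPM                integer breaths/min
    5    4      Ti                 seconds, fixed 'NN.N'
    9    3      tidal volume       ml / 10
    12   2      PIP target         integer cmH2O
    14   2      PEEP               integer cmH2O
    16   2      trigger flow       integer ml/s
    18   2      TV alarm low       ml / 10
    20   2      TV alarm high      ml / 10
    22   2      PIP alarm high     integer cmH2O
    24   1      PEEP alarm low     integer cmH2O (single digit)
    25   2      PEEP alarm high    integer cmH2O

The PIP low alarm bound is not carried on the wire (fixed at 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Union

import click
import pandas as pd
import yaml

from .control import MIN_SPEED
from .energetics import (
    BatteryPack,
    average_power,
    efficiency_fold,
    pack_energy,
    runtime_hours,
)
from .modes import (
    AlarmBounds,
    BreathRecord,
    RunGains,
    RunResult,
    SensorNoise,
    VentSettings,
    run_mode,
)
from .patient_sim import LungParams, Scenario, make_scenario
from .sensing import CalibrationTable, fit_calibration

__all__ = [
    "FRAME_LENGTH",
    "FrameError",
    "TelemetryFrame",
    "encode_frame",
    "decode_frame",
    "write_waveforms",
    "RunConfig",
    "cli",
]

log = logging.getLogger(__name__)

FRAME_LENGTH = 27
FRAME_TYPES = ("v", "d")

MODE_CODES = {"PCV": 0, "PRVC": 1}
MODE_NAMES = {v: k for k, v in MODE_CODES.items()}
_SIMV_OFFSET = 10


class FrameError(ValueError):
    """Raised when a frame cannot be encoded or decoded; names the field."""


@dataclass(frozen=True)
class TelemetryFrame:
    """Decoded settings frame."""

    frame_type: str
    mode_code: int
    bpm: int
    ti: float
    tidal_volume: int  # ml
    pip_target: int
    peep: int
    trigger_flow: int
    tv_alarm_low: int  # ml
    tv_alarm_high: int
    pip_alarm_high: int
    peep_alarm_low: int
    peep_alarm_high: int

    @property
    def mode(self) -> str:
        base = self.mode_code % _SIMV_OFFSET
        if base not in MODE_NAMES:
            raise FrameError(f"unknown mode code {self.mode_code}")
        return MODE_NAMES[base]

    @property
    def simv(self) -> bool:
        return self.mode_code >= _SIMV_OFFSET

    def to_settings(self) -> VentSettings:
        """Convert to validated settings (range errors propagate)."""
        return VentSettings(
            mode=self.mode,
            simv=self.simv,
            tidal_volume=float(self.tidal_volume),
            bpm=float(self.bpm),
            ti=self.ti,
            peep=float(self.peep),
            pip_target=float(self.pip_target),
            trigger_flow=float(self.trigger_flow),
            alarms=AlarmBounds(
                tv=(float(self.tv_alarm_low), float(self.tv_alarm_high)),
                pip=(0.0, float(self.pip_alarm_high)),
                peep=(float(self.peep_alarm_low), float(self.peep_alarm_high)),
            ),
        )


def _encode_int(value: float, width: int, name: str, scale: float = 1.0) -> str:
    scaled = value / scale
    iv = int(round(scaled))
    if abs(scaled - iv) > 1e-9:
        raise FrameError(
            f"{name}={value} is not representable at resolution {scale:g}"
        )
    if iv < 0 or iv >= 10**width:
        raise FrameError(f"{name}={value} exceeds its {width}-character field")
    return f"{iv:0{width}d}"


def encode_frame(
    settings: Union[VentSettings, TelemetryFrame], frame_type: str = "v"
) -> str:
    """Encode settings into the fixed-width 27-character frame string."""
    if frame_type not in FRAME_TYPES:
        raise FrameError(f"unknown frame type {frame_type!r}")
    if isinstance(settings, VentSettings):
        mode_code = MODE_CODES[settings.mode] + (_SIMV_OFFSET if settings.simv else 0)
        tf = TelemetryFrame(
            frame_type=frame_type,
            mode_code=mode_code,
            bpm=int(round(settings.bpm)),
            ti=settings.ti,
            tidal_volume=int(round(settings.tidal_volume)),
            pip_target=int(round(settings.pip_target)),
            peep=int(round(settings.peep)),
            trigger_flow=int(round(settings.trigger_flow)),
            tv_alarm_low=int(round(settings.alarms.tv[0])),
            tv_alarm_high=int(round(settings.alarms.tv[1])),
            pip_alarm_high=int(round(settings.alarms.pip[1])),
            peep_alarm_low=int(round(settings.alarms.peep[0])),
            peep_alarm_high=int(round(settings.alarms.peep[1])),
        )
    else:
        tf = replace(settings, frame_type=frame_type)

    if not (0 <= tf.ti < 100):
        raise FrameError(f"ti={tf.ti} exceeds its field")
    ti_str = f"{tf.ti:04.1f}"
    if len(ti_str) != 4:
        raise FrameError(f"ti={tf.ti} exceeds its field")

    frame = (
        frame_type
        + _encode_int(tf.mode_code, 2, "mode_code")
        + _encode_int(tf.bpm, 2, "bpm")
        + ti_str
        + _encode_int(tf.tidal_volume, 3, "tidal_volume", scale=10.0)
        + _encode_int(tf.pip_target, 2, "pip_target")
        + _encode_int(tf.peep, 2, "peep")
        + _encode_int(tf.trigger_flow, 2, "trigger_flow")
        + _encode_int(tf.tv_alarm_low, 2, "tv_alarm_low", scale=10.0)
        + _encode_int(tf.tv_alarm_high, 2, "tv_alarm_high", scale=10.0)
        + _encode_int(tf.pip_alarm_high, 2, "pip_alarm_high")
        + _encode_int(tf.peep_alarm_low, 1, "peep_alarm_low")
        + _encode_int(tf.peep_alarm_high, 2, "peep_alarm_high")
    )
    assert len(frame) == FRAME_LENGTH
    return frame


def _decode_int(s: str, name: str, scale: float = 1.0) -> int:
    if not s.isdigit():
        raise FrameError(f"field {name!r} is not numeric: {s!r}")
    return int(int(s) * scale)


def decode_frame(s: str) -> TelemetryFrame:
    """Parse a frame string; raises FrameError naming the offending field.

    Decoding is purely syntactic — every numeric field is extracted but no
    clinical range validation is applied (use ``TelemetryFrame.to_settings``
    for that), so settings are never partially applied.
    """
    if not isinstance(s, str) or len(s) != FRAME_LENGTH:
        raise FrameError(
            f"wrong frame length: expected {FRAME_LENGTH}, got "
            f"{len(s) if isinstance(s, str) else type(s)}"
        )
    if s[0] not in FRAME_TYPES:
        raise FrameError(f"unknown frame type {s[0]!r}")
    ti_str = s[5:9]
    try:
        ti = float(ti_str)
    except ValueError:
        raise FrameError(f"field 'ti' is not numeric: {ti_str!r}") from None
    if ti_str[2] != "." or ti < 0:
        raise FrameError(f"field 'ti' malformed: {ti_str!r}")
    return TelemetryFrame(
        frame_type=s[0],
        mode_code=_decode_int(s[1:3], "mode_code"),
        bpm=_decode_int(s[3:5], "bpm"),
        ti=ti,
        tidal_volume=_decode_int(s[9:12], "tidal_volume", scale=10.0),
        pip_target=_decode_int(s[12:14], "pip_target"),
        peep=_decode_int(s[14:16], "peep"),
        trigger_flow=_decode_int(s[16:18], "trigger_flow"),
        tv_alarm_low=_decode_int(s[18:20], "tv_alarm_low", scale=10.0),
        tv_alarm_high=_decode_int(s[20:22], "tv_alarm_high", scale=10.0),
        pip_alarm_high=_decode_int(s[22:24], "pip_alarm_high"),
        peep_alarm_low=_decode_int(s[24:25], "peep_alarm_low"),
        peep_alarm_high=_decode_int(s[25:27], "peep_alarm_high"),
    )


# ---------------------------------------------------------------------------
# waveform / record writers
# ---------------------------------------------------------------------------

WAVEFORM_COLUMNS = [
    "time_s",
    "pressure_cmH2O",
    "flow_ml_s",
    "volume_ml",
    "motor_speed",
    "servo_fraction",
    "alarms",
]

BREATH_COLUMNS = [
    "breath_index",
    "t_start_s",
    "delivered_volume_ml",
    "pip_cmH2O",
    "peep_cmH2O",
    "min_pressure_cmH2O",
    "trigger_type",
    "alarms",
    "motor_speed_insp",
    "ti_s",
    "te_s",
]


def write_waveforms(result: RunResult, out_dir) -> Dict[str, Path]:
    """Write per-sample and per-breath CSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alarms_by_breath = {r.breath_index: ";".join(sorted(r.alarms)) for r in result.breaths}
    wf = pd.DataFrame(
        {
            "time_s": result.samples["time"],
            "pressure_cmH2O": result.samples["pressure_sensed"],
            "flow_ml_s": result.samples["flow_sensed"],
            "volume_ml": result.samples["volume"],
            "motor_speed": result.samples["motor_speed"],
            "servo_fraction": result.samples["servo_fraction"],
            "alarms": [
                alarms_by_breath.get(b, "") for b in result.samples["breath_index"]
            ],
        },
        columns=WAVEFORM_COLUMNS,
    )
    br = pd.DataFrame(
        [
            {
                "breath_index": r.breath_index,
                "t_start_s": r.t_start,
                "delivered_volume_ml": r.delivered_volume,
                "pip_cmH2O": r.pip,
                "peep_cmH2O": r.peep_estimate,
                "min_pressure_cmH2O": r.min_pressure,
                "trigger_type": r.trigger_type,
                "alarms": ";".join(sorted(r.alarms)),
                "motor_speed_insp": r.motor_speed_insp,
                "ti_s": r.ti_actual,
                "te_s": r.te_actual,
            }
            for r in result.breaths
        ],
        columns=BREATH_COLUMNS,
    )
    wf_path = out / "waveforms.csv"
    br_path = out / "breaths.csv"
    wf.to_csv(wf_path, index=False)
    br.to_csv(br_path, index=False)
    return {"waveforms": wf_path, "breaths": br_path}


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Schema-validated description of one simulation run."""

    settings: VentSettings = field(default_factory=VentSettings)
    lung: LungParams = field(default_factory=LungParams)
    scenario: Scenario = field(default_factory=lambda: make_scenario("normal"))
    gains: RunGains = field(default_factory=RunGains)
    noise: SensorNoise = field(default_factory=SensorNoise)
    n_breaths: int = 20
    seed: int = 0
    dt: float = 1e-3
    out_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {
            "settings",
            "lung",
            "scenario",
            "gains",
            "noise",
            "n_breaths",
            "seed",
            "dt",
            "out_dir",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        if "settings" in d:
            s = dict(d["settings"])
            if "alarms" in s:
                a = dict(s["alarms"])
                s["alarms"] = AlarmBounds(
                    **{k: tuple(v) for k, v in a.items()}
                )
            kw["settings"] = VentSettings(**s)
        if "lung" in d:
            kw["lung"] = LungParams(**d["lung"])
        if "scenario" in d:
            sc = dict(d["scenario"])
            kind = sc.pop("kind", "normal")
            kw["scenario"] = make_scenario(kind, **sc)
        if "gains" in d:
            kw["gains"] = RunGains(**d["gains"])
        if "noise" in d:
            kw["noise"] = SensorNoise(**d["noise"])
        for key in ("n_breaths", "seed", "dt", "out_dir"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        return cls.from_dict(data)

    def run(self) -> RunResult:
        return run_mode(
            self.settings,
            lung=self.lung,
            n_breaths=self.n_breaths,
            seed=self.seed,
            scenario=self.scenario,
            gains=self.gains,
            noise=self.noise,
            dt=self.dt,
        )


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("--verbose", is_flag=True, help="Enable per-cycle DEBUG logging.")
def cli(verbose: bool) -> None:
    """Turbine-ventilator closed-loop simulator."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO)


@cli.command("run")
@click.argument("config", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None, help="Output directory.")
def cli_run(config: str, out: Optional[str]) -> None:
    """Run a mode simulation described by a YAML/JSON config file."""
    cfg = RunConfig.from_file(config)
    result = cfg.run()
    out_dir = out or cfg.out_dir or "turbovent_out"
    paths = write_waveforms(result, out_dir)
    summary = {
        "mode": result.settings.mode,
        "simv": result.settings.simv,
        "n_breaths": len(result.breaths),
        "mean_delivered_ml": float(
            pd.Series([r.delivered_volume for r in result.breaths]).mean()
        ),
        "mean_pip_cmH2O": float(pd.Series([r.pip for r in result.breaths]).mean()),
        "max_balance_residual": result.max_balance_residual,
        "alarms": sorted({a for r in result.breaths for a in r.alarms}),
    }
    (Path(out_dir) / "summary.json").write_text(
        json.dumps(summary, indent=2), encoding="utf-8"
    )
    click.echo(json.dumps(summary, indent=2))
    click.echo(f"waveforms: {paths['waveforms']}")


@cli.command("calibrate")
@click.argument("table", type=click.Path(exists=True))
def cli_calibrate(table: str) -> None:
    """Fit the pressure-sensor constant C from a 2-column calibration CSV."""
    c = fit_calibration(CalibrationTable.from_csv(table))
    click.echo(f"C = {c:.6f} cmH2O per count")


@cli.command("energy")
@click.option("--cell-mah", default=3400.0, show_default=True)
@click.option("--series", default=3, show_default=True)
@click.option("--parallel", default=2, show_default=True)
@click.option("--voltage", default=12.6, show_default=True)
@click.option("--avg-power", default=None, type=float, help="Average draw in W.")
@click.option(
    "--energy-wh", default=None, type=float, help="Measured energy consumed, Wh."
)
@click.option(
    "--duration-h", default=None, type=float, help="Measurement duration, hours."
)
def cli_energy(cell_mah, series, parallel, voltage, avg_power, energy_wh, duration_h):
    """Battery pack energy, average power and runtime calculations."""
    pack = BatteryPack(
        cell_capacity_mah=cell_mah, series=series, parallel=parallel, pack_voltage=voltage
    )
    click.echo(f"pack energy: {pack_energy(pack):.2f} Wh")
    if energy_wh is not None and duration_h is not None:
        avg_power = average_power(energy_wh, duration_h)
        click.echo(f"average power: {avg_power:.3f} W")
    if avg_power is not None:
        click.echo(f"runtime: {runtime_hours(pack, avg_power):.2f} h")


@cli.command("frame")
@click.option("--decode", "frame_str", default=None, help="Frame string to decode.")
@click.option("--encode-defaults", is_flag=True, help="Encode default settings.")
def cli_frame(frame_str: Optional[str], encode_defaults: bool) -> None:
    """Encode or decode a 27-character settings frame."""
    if frame_str is not None:
        tf = decode_frame(frame_str)
        click.echo(json.dumps(asdict(tf), indent=2))
    elif encode_defaults:
        click.echo(encode_frame(VentSettings()))
    else:
        raise click.UsageError("pass --decode FRAME or --encode-defaults")


if __name__ == "__main__":  # pragma: no cover
    cli()
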