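"""Sensor forward models, analog calibration and the band-filtration statistic.

The differential pressure sensor (MPX2010DP behind an op-amp) reports integer
ADC counts; the firmware converts them to cmH2O with

    pressure = (analog - analog_offset) * C

where C is the slope of a bench calibration: known water-column pressures
against offset-subtracted analog counts, fitted by ordinary least squares.
Two historically used values of C ship as named presets; the table-derived
one (0.208879) is the default.  The flow sensor (SFM3300) needs no
calibration and is modeled as additive Gaussian noise with range clipping at
+/-250 slm.

Raw samples are cleaned with a standard-deviation band filter: over a window
of n samples compute the mean, the population standard deviation, shrink the
deviation by ``shrink_percent``, and average only the samples inside
mean +/- shrunk deviation.  Boundary samples are kept; if the band is empty
the unfiltered mean is returned (fail-safe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence, Tuple, Union

import numpy as np
from scipy import stats

__all__ = [
    "C_FROM_TABLE",
    "C_FROM_SYRINGE_TEST",
    "SensorCalibration",
    "CalibrationTable",
    "FilterConfig",
    "FilterResult",
    "analog_to_cmH2O",
    "simulate_pressure_sensor",
    "fit_calibration",
    "band_filter",
    "simulate_flow_sensor",
    "load_reference_table",
    "DEFAULT_CALIBRATION",
]

#: slope fitted to the packaged bench calibration table (the default)
C_FROM_TABLE = 0.208879
#: slope from the earlier single-point syringe/water-column experiment
C_FROM_SYRINGE_TEST = 0.20916

#: SFM3300 measurement range, +/-250 standard liters per minute, in ml/s
FLOW_RANGE_ML_S = 250.0 * 1000.0 / 60.0

RngLike = Union[int, None, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SensorCalibration:
    """Analog-to-pressure conversion constants."""

    analog_offset: float = 102.0  # counts at zero differential pressure
    c_constant: float = C_FROM_TABLE  # cmH2O per count

    def __post_init__(self) -> None:
        if not (self.c_constant > 0):
            raise ValueError("c_constant must be > 0")


DEFAULT_CALIBRATION = SensorCalibration()


@dataclass(frozen=True)
class CalibrationTable:
    """Bench calibration data: pressure (cmH2O) vs offset-subtracted counts."""

    pressures: Tuple[float, ...]
    analogs: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pressures) != len(self.analogs):
            raise ValueError("pressures and analogs must have equal length")
        if len(self.pressures) < 2:
            raise ValueError("calibration table needs at least 2 rows")
        order = np.argsort(self.pressures)
        a = np.asarray(self.analogs)[order]
        if np.any(np.diff(a) < 0):
            raise ValueError("analog values must be non-decreasing with pressure")

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(pressures=tuple(data[:, 0]), analogs=tuple(data[:, 1]))

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pressure_cmH2O,offset_subtracted_analog\n")
            for p, a in zip(self.pressures, self.analogs):
                fh.write(f"{p:g},{a:g}\n")


def load_reference_table() -> CalibrationTable:
    """The packaged MPX2010DP bench calibration table (21 rows, 0-20 cmH2O)."""
    ref = resources.files("turbovent.data").joinpath("mpx2010_calibration.csv")
    with resources.as_file(ref) as path:
        return CalibrationTable.from_csv(path)


def analog_to_cmH2O(analog: float, cal: SensorCalibration = DEFAULT_CALIBRATION) -> float:
    """Convert a raw ADC reading to cmH2O: (analog - offset) * C."""
    return (analog - cal.analog_offset) * cal.c_constant


def simulate_pressure_sensor(
    true_pressure: float,
    cal: SensorCalibration = DEFAULT_CALIBRATION,
    noise_sd: float = 0.0,
    seed: RngLike = None,
) -> int:
    """Forward model of the pressure-sensing chain: quantized noisy counts.

    Returns round(true/C + offset + eps) with eps ~ Normal(0, noise_sd).
    ``seed`` may be an integer or a numpy Generator (for in-loop use).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    counts = true_pressure / cal.c_constant + cal.analog_offset
    if noise_sd > 0:
        counts += _as_rng(seed).normal(0.0, noise_sd)
    return int(round(counts))


def fit_calibration(table: CalibrationTable) -> float:
    """Least-squares slope C (cmH2O per count) of pressure on analog counts.

    Ordinary least squares with intercept; the intercept absorbs any residual
    zero offset and is discarded.
    """
    analogs = np.asarray(table.analogs, dtype=float)
    if np.ptp(analogs) == 0:
        raise ValueError("degenerate calibration table: all analog values equal")
    result = stats.linregress(analogs, np.asarray(table.pressures, dtype=float))
    return float(result.slope)


@dataclass(frozen=True)
class FilterConfig:
    """Band-filter window size and band shrink fraction."""

    window_size: int = 50
    shrink_percent: float = 0.5

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not (0.0 <= self.shrink_percent < 1.0):
            raise ValueError("shrink_percent must be in [0, 1)")


@dataclass(frozen=True)
class FilterResult:
    mean: float
    std_dev: float
    std_shrink: float
    filtered_mean: float
    n_kept: int


def band_filter(samples: Sequence[float], cfg: FilterConfig) -> FilterResult:
    """Outlier-band filtration of a full sensor window.

    mean = sum(x)/n; std_dev is the population form (divide by n);
    std_shrink = std_dev * (1 - shrink_percent); samples inside
    [mean - std_shrink, mean + std_shrink] (inclusive) are averaged.  If no
    sample falls inside the band the plain mean is returned unchanged.
    """
    x = np.asarray(samples, dtype=float)
    if x.size != cfg.window_size:
        raise ValueError(
            f"expected exactly window_size={cfg.window_size} samples, got {x.size}"
        )
    mean = float(x.mean())
    std_dev = float(np.sqrt(np.mean((x - mean) ** 2)))  # population (/n)
    std_shrink = std_dev * (1.0 - cfg.shrink_percent)
    inside = np.abs(x - mean) <= std_shrink
    n_kept = int(inside.sum())
    filtered_mean = float(x[inside].mean()) if n_kept else mean
    return FilterResult(
        mean=mean,
        std_dev=std_dev,
        std_shrink=std_shrink,
        filtered_mean=filtered_mean,
        n_kept=n_kept,
    )


def simulate_flow_sensor(
    true_flow: float, noise_sd: float = 0.0, seed: RngLike = None
) -> float:
    """Forward model of the SFM3300 flow sensor: noisy, range-clipped ml/s."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    reading = float(true_flow)
    if noise_sd > 0:
        reading += float(_as_rng(seed).normal(0.0, noise_sd))
    return float(np.clip(reading, -FLOW_RANGE_ML_S, FLOW_RANGE_ML_S))
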