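"""Electrical power and energy bookkeeping: battery runtime, mean power and
the servo-vs-solenoid efficiency comparison.

The ventilator's backup pack is 18650 cells in a 3S2P arrangement (three in
series for voltage, two strings in parallel for capacity), so pack energy is
capacity * parallel * voltage.  Average power is energy over duration, and
runtime is pack energy over average power.  "x times more efficient" follows
the reference/new - 1 convention (a mechanism using the same energy is 0
times more efficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "EnergyLedger",
    "BatteryPack",
    "integrate_energy",
    "average_power",
    "runtime_hours",
    "efficiency_fold",
    "pack_energy",
    "electrical_power",
]


@dataclass
class EnergyLedger:
    """Sampled electrical power with running energy integration."""

    times: List[float] = field(default_factory=list)  # s
    powers: List[float] = field(default_factory=list)  # W

    def record(self, time: float, power: float) -> None:
        if power < 0:
            raise ValueError("power must be >= 0")
        if self.times and time <= self.times[-1]:
            raise ValueError("times must be strictly increasing")
        self.times.append(float(time))
        self.powers.append(float(power))

    @property
    def integrated_energy(self) -> float:
        """Trapezoidal energy of the samples so far, Wh."""
        if len(self.times) < 2:
            return 0.0
        return float(np.trapezoid(self.powers, self.times)) / 3600.0

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("time_s,power_w\n")
            for t, p in zip(self.times, self.powers):
                fh.write(f"{t:.6g},{p:.6g}\n")


@dataclass(frozen=True)
class BatteryPack:
    """Series/parallel 18650 pack; defaults are the 3S2P backup pack."""

    cell_capacity_mah: float = 3400.0
    series: int = 3
    parallel: int = 2
    pack_voltage: float = 12.6  # V (fully charged 3S)

    def __post_init__(self) -> None:
        if min(self.cell_capacity_mah, self.series, self.parallel, self.pack_voltage) <= 0:
            raise ValueError("battery pack fields must be positive")

    @property
    def capacity_mah(self) -> float:
        return self.cell_capacity_mah * self.parallel

    @property
    def energy_wh(self) -> float:
        return pack_energy(self)


def integrate_energy(power_samples: Sequence[float], dt: float) -> float:
    """Trapezoidal integral of evenly sampled power (W) over dt (s), in Wh."""
    p = np.asarray(power_samples, dtype=float)
    if np.any(p < 0):
        raise ValueError("power samples must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if p.size < 2:
        return 0.0
    return float(np.trapezoid(p, dx=dt)) / 3600.0


def average_power(energy_wh: float, duration_h: float) -> float:
    """Mean power (W) = energy consumed (Wh) / duration (h)."""
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    return energy_wh / duration_h


def runtime_hours(pack: BatteryPack, avg_power_w: float) -> float:
    """Expected runtime (h) of a pack at a given average draw."""
    if avg_power_w <= 0:
        raise ValueError("average power must be > 0")
    return pack.energy_wh / avg_power_w


def efficiency_fold(reference_energy_wh: float, new_energy_wh: float) -> float:
    """How many times more efficient the new mechanism is than the reference.

    reference/new - 1: equal energies give 0 (no improvement).
    """
    if reference_energy_wh <= 0 or new_energy_wh <= 0:
        raise ValueError("energies must be > 0")
    return reference_energy_wh / new_energy_wh - 1.0


def pack_energy(pack: BatteryPack) -> float:
    """Pack energy (Wh) = capacity (Ah, parallel strings summed) * voltage."""
    return pack.cell_capacity_mah * pack.parallel / 1000.0 * pack.pack_voltage


def electrical_power(
    speed_command: float,
    idle_w: float = 5.0,
    turbine_full_w: float = 20.0,
    speed_max: float = 255.0,
) -> float:
    """Simulated electrical draw (W) at a turbine speed command.

    Idle electronics draw plus a cubic fan-power term (aerodynamic power
    scales with the cube of speed), scaled so a typical pressure-control
    operating point sits near the measured ~15.3 W system draw.  Used for
    qualitative run-level ledgers only.
    """
    frac = min(max(speed_command / speed_max, 0.0), 1.0)
    return idle_w + turbine_full_w * frac**3
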