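# turbovent

A closed-loop simulator of a turbine-based emergency ventilator, for
engineers and researchers studying low-cost blower ventilation. It
re-creates the device's computational core as testable software: the
pneumatic pressure balance of the servo-actuated pressure release mechanism
(PRM), sensor calibration and outlier-band filtration, feed-forward plus
proportional/PID turbine control, the PRVC / PCV / SIMV mode state machines
with alarms and patient-circuit disconnection detection, the GUI⇄firmware
settings-frame codec, and battery energy accounting — all exercised against
a synthetic single-compartment test lung instead of physical hardware.

## The models in brief

**Patient lung.** Linear one-compartment equation of motion,
`P_aw = R·Q + V/C + P_0 + P_mus`, integrated by fixed-step Euler at 1 ms
(defaults C = 50 ml/cmH₂O, R = 5 cmH₂O/(L/s)). Spontaneous effort is a
half-sine muscle pressure `P_mus ≤ 0`; disconnection opens a leak
conductance at the patient wye.

**Pneumatics.** The blower obeys fan laws (stall pressure ∝ speed², free
flow ∝ speed; 70 cmH₂O / 240 L/min at full command). The PRM divides the
turbine pressure `P1` into a patient share `P2`, a vented share `P3`
(through the servo gap) and a PEEP-pilot share `P4`, with

```
P1 = P2 + P3 + P4
```

enforced to better than 1e−9 at every time step. Gas reaches the lung
through a one-way valve (5 cmH₂O cracking pressure) and leaves through a
passive PEEP valve that stays sealed while the pilot pressure exceeds the
patient pressure.

**Sensing.** Pressure counts convert as `p = (analog − offset) · C`, with
`C = 0.208879` refitted by ordinary least squares from the packaged 21-row
bench calibration table. Raw windows are cleaned by a standard-deviation
band filter: keep samples inside `mean ± stdDev·(1 − shrinkPercent)` and
re-average (population standard deviation, boundary samples kept).

**Control.** Volume-targeted breaths apply
`motorSpeed ← motorSpeed + volumeError · Kp` once per breath from a
feed-forward starting speed; pressure-targeted breaths run a per-sample PID.
SIMV grants a patient-triggered breath when sensed inspiratory flow reaches
the trigger threshold inside the synchronization window — the final
`sync_window_fraction` of the cycle, via `nonSyncTime = BCT·(1 − f)` and
`syncTime = nonSyncTime − Ti`. A band-filtered end-inspiratory PIP below
5 cmH₂O raises the disconnection alarm.

## Worked example

```python
from turbovent import VentSettings, run_prvc

settings = VentSettings(mode="PRVC", tidal_volume=350, bpm=10, ti=2.0, peep=5)
result = run_prvc(settings, n_breaths=20, seed=1)
for b in result.breaths[:3] + result.breaths[-3:]:
    print(f"breath {b.breath_index:2d}  delivered {b.delivered_volume:6.1f} ml  "
          f"PIP {b.pip:5.2f} cmH2O  PEEP {b.peep_estimate:4.2f} cmH2O  {b.trigger_type}")
print("max |P1-(P2+P3+P4)| =", result.max_balance_residual)
```

prints

```
breath  0  delivered  302.7 ml  PIP  6.27 cmH2O  PEEP 5.01 cmH2O  machine
breath  1  delivered  115.0 ml  PIP  7.52 cmH2O  PEEP 4.80 cmH2O  machine
breath  2  delivered  292.6 ml  PIP 10.86 cmH2O  PEEP 4.95 cmH2O  machine
breath 17  delivered  348.9 ml  PIP 12.11 cmH2O  PEEP 4.80 cmH2O  machine
breath 18  delivered  350.7 ml  PIP 12.11 cmH2O  PEEP 4.80 cmH2O  machine
breath 19  delivered  350.2 ml  PIP 12.11 cmH2O  PEEP 5.01 cmH2O  machine
max |P1-(P2+P3+P4)| = 3.552713678800501e-15
```

The first breaths show the feed-forward start and the one-time fill from
resting lung volume up to the PEEP operating point; the per-breath
proportional rule then holds the delivered tidal volume within a fraction of
a percent of the 350 ml target, at a peak pressure of ~12 cmH₂O and an
end-expiratory pressure at the 5 cmH₂O PEEP setting. The balance residual
confirms the PRM pressure division is conservative to machine precision.

A command-line interface covers the same ground:

```bash
turbovent run config.yaml --out out/        # closed-loop run from a config
turbovent calibrate table.csv               # fit C from a 2-column CSV
turbovent energy --energy-wh 2.544 --duration-h 0.16667
turbovent frame --decode v061502.0042090050025150702
```

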