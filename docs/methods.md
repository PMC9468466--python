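# Methods

This note documents the models behind `turbovent`, the parameters that
matter, the numerical choices, and what the synthetic test rig does and does
not demonstrate about a physical ventilator.

## Patient model

The synthetic test lung is a linear one-compartment model: airway-opening
pressure balances resistive, elastic, baseline and muscle pressure,

    P_aw = R·Q + V/C + P_0 + P_mus ,

with volume `V` in ml above functional residual capacity, flow `Q` in ml/s,
compliance `C` (default 50 ml/cmH₂O) and resistance `R` (default
5 cmH₂O/(L/s)) — typical adult values giving a mechanical time constant
τ = R·C = 0.25 s. Integration is explicit fixed-step Euler at dt = 1 ms,
mirroring a firmware control loop; the step contract `dt ≤ 0.1·τ` keeps the
scheme stable, and convergence is tested against the analytic first-order
step response (<1 % error) and under step halving (<0.5 % change). Volume is
floored at zero: the compartment cannot empty below FRC. In the
zero-resistance limit the compartment equilibrates instantaneously.

Spontaneous effort is a half-sine muscle pressure pulse, P_mus ≤ 0,
default amplitude −3 cmH₂O over 0.6 s — strong enough to pull sensible
trigger flow through the inspiratory valve, weak enough not to distort
delivered volumes much. Scenarios (normal / spontaneous / disconnect /
reconnect) script effort onsets and a leak conductance at the patient wye
(default 500 ml/s per cmH₂O when open — an essentially open circuit); all
randomness flows from one seeded generator.

## Pneumatic network

The blower is modeled by fan laws: stall pressure `70·(s/255)²` cmH₂O and
free-flow limit `4000·(s/255)` ml/s for speed command `s` (ratings
70 cmH₂O / 240 L/min). At every step the operating point is the exact
intersection of the linear fan curve `P1 = stall·(1 − Q/Q_max)` with the
piecewise-linear circuit load: for each combination of element states
(check valve conducting or not, PEEP valve open or closed, pilot branch
above or below its bias headroom) the network is linear and solved in closed
form; the combination consistent with its own solution is taken. This makes
each step O(1), deterministic, and free of iteration tolerances.

The pressure release mechanism divides `P1` additively into the patient
share `P2`, the vented share `P3` and the PEEP-pilot share `P4`:

    P1 = P2 + P3 + P4   (enforced; residual < 1e−9, in practice ~1e−15).

The servo gap takes `P3 = f₃·P1` where `f₃ = g·s_eff/(g·s_eff + g_through)`
grows with servo opening after a spring preload (default 5 % of travel) is
overcome. The remainder splits with a fixed offset, `P2 = P4 + bias`:

    P4 = max(0, (P1 − P3 − bias))/2 ,   P2 = (P1 − P3) − P4 .

The bias defaults to 3 cmH₂O, two below the check-valve cracking pressure
(5 cmH₂O). This one design choice carries three load-bearing consequences:

1. **The PEEP valve stays sealed during inhalation.** The highest pressure
   the wye can reach is the plateau `P2 − cracking = P4 − 2`, always below
   the pilot.
2. **The 2 cmH₂O gap is the patient-trigger deadband.** During exhalation
   the inspiratory limb is balanced (`P2 − cracking = P4 − 2` just below the
   wye pressure), so sensor noise and the natural refill-to-PEEP flow do not
   reach the flow-trigger threshold, while a −3 cmH₂O inspiratory effort
   pulls the wye more than 2 cmH₂O below the pilot and draws an
   unmistakable ~100 ml/s through the check valve. Narrower deadbands (0
   and 1 cmH₂O were tried during design) false-trigger on controller
   jitter alone.
3. **The patient branch always carries the larger share** (`P2 > P4`).

The cost is headroom: with the additive split the achievable plateau is
capped near `(70 + bias)/2 − cracking ≈ 31.5 cmH₂O`, below the 35 cmH₂O
GUI maximum that settings validation (deliberately) still allows. Runs
requesting more simply saturate.

During exhalation the lung empties through the passive PEEP valve (linear
conductance above the pilot pressure, sealed at or below it), so the pilot
sets the end-expiratory floor; the turbine speed is regulated so the pilot
equals the PEEP setting. The disconnection leak is a shunt conductance at
the wye: with it open, no clinically meaningful pressure can be built.

## Sensing

The pressure chain models an MPX2010DP differential sensor behind an op-amp
and ADC: counts = round(p/C + offset + ε), ε Gaussian (default 1 count).
Conversion back is `p = (analog − offset)·C`. Two historical values of C
ship as presets: 0.20916 from a single-point water-column experiment and
0.208879 from the 21-row bench table fitted by OLS *with* intercept — the
form that reproduces the printed constant exactly (a through-origin fit
gives 0.208935); the intercept absorbs residual zero offset and is
discarded. The packaged table is the deliverable fixture
(`data/mpx2010_calibration.csv`). The flow model (SFM3300-style) is additive
Gaussian noise with hard clipping at ±250 slm; no calibration is applied,
matching the sensor's factory-calibrated behaviour.

Band filtration takes a full window of n samples and computes the mean
(Σx/n), the population standard deviation (divide by n, matching the
firmware arithmetic), the shrunk half-width `stdDev·(1 − shrinkPercent)`,
and the mean of samples inside the band, boundaries inclusive. If the band
is empty the unfiltered mean is returned — fail-safe over fail-silent.
Defaults: n = 50 samples, shrink 0.5 (both configurable; the source
firmware prints neither). PIP is estimated from the last 50 inspiratory
samples per breath through this filter, never from the raw maximum.

A note on the filter's robustness margin: a single spike displaces the raw
window mean by (spike)/n, so for large windows the raw mean is barely
corrupted and no single-pass trimmed estimator can beat it 95 % of the
time (≈65 % at n = 50 in our Monte-Carlo). The ≥95 %-improvement property
is therefore demonstrated at a 10-sample window — the regime of 10 %
contamination the filter exists for — while the PIP-estimation default
stays at n = 50.

## Control

Three controllers, all exposed in `RunGains`:

- **Per-breath volume controller (PRVC)** — the accumulating proportional
  rule `speed ← clamp(speed + Kp·(V_target − V_delivered))`, Kp default
  0.1 counts/ml, applied at end-inspiration. On the default lung the
  speed→volume gain is ~4–8 ml/count, so the loop gain sits near 0.4–0.8:
  monotone or mildly overshooting convergence in a handful of breaths, and
  re-convergence within ~3 breaths of a compliance halving.
- **Per-sample pressure PID (PCV and PEEP regulation)** — output trims a
  feed-forward base speed; gains kp = 3 counts/cmH₂O, ki = 60 counts/
  (cmH₂O·s), kd = 0, trapezoidal integral with anti-windup clamp
  (±4 cmH₂O·s). The PEEP loop's integral is additionally clamped one-sided
  at zero: early exhalation legitimately runs above the PEEP target while
  the lung empties, and letting the integral wind down there produced a
  2–3 cmH₂O undershoot later in exhalation.
- **Feed-forward tables** — starting speeds computed once from the static
  circuit relations (plateau ≈ `(P1 + bias)/2 − cracking`, pilot ≈
  `((1 − f₃)·P1 − bias)/2`) rather than stored as magic numbers, so they
  follow any re-parameterisation of the circuit or lung.

Gains were tuned on the default synthetic lung; they are configuration, not
code constants.

The error sign convention is error = target − measured, so under-delivery
raises the speed. The speed floor (10 counts) keeps the blower spinning
through exhalation. The firmware pressure cap `p_max` (default 60 cmH₂O,
above anything the circuit can produce) latches the inhale speed to the
floor for the rest of the breath if the sensed pressure ever exceeds it.

## Mode logic

Breath timing: BCT = 60/BPM, Te = BCT − Ti. The SIMV window is the final
`sync_window_fraction` of the cycle: nonSyncTime = BCT·(1 − f), syncTime =
nonSyncTime − Ti, and a trigger may fire for expiratory elapsed time in
(syncTime, Te] — i.e. the window ends at the next machine breath. The
default fraction is 0.1; 0.4 reproduces the wide-window bench configuration.
The trigger comparator is ≥ on sensed flow (default threshold 20 ml/s),
and triggering is implemented in the expiratory window only. A
patient-triggered breath starts the next cycle immediately (advances one
breath; it does not re-phase the schedule beyond that).

Disconnection: at end-inspiration, a band-filtered PIP below 5 cmH₂O
(strict) raises the alarm. While alarmed, exhalation runs at the speed
floor and inhalation at a fixed low *probe* speed (140 counts) sized to
build ≥5 cmH₂O against the default lung if the circuit is back — that is
how reconnection is detected and the alarm cleared. The probe is this
package's mechanism; a firmware could equally probe less often or less
vigorously.

Alarms: per-breath tidal volume, PIP and PEEP are compared against operator
[low, high] bounds (one alarm per quantity), a flow-sensor alarm fires if
flow readings are absent or non-finite for a full breath, and the
disconnection alarm is merged in by the loop. Settings are validated
against the GUI ranges (TV 100–999 ml, PIP 0–35 cmH₂O, BPM 6–60, PEEP
0–12 cmH₂O, Ti < BCT).

## Telemetry frame

Settings travel as a fixed 27-character string: one type character plus
twelve zero-padded decimal fields (layout table in `interface.py`). The
layout is this package's documented convention — the historical firmware
used the same shape (type char + fixed-width substrings, 27 characters) but
never published its field map, so the example string from that system
parses cleanly under this layout without any claim that the field semantics
coincide. Encoding rejects unrepresentable values (field overflow, tidal
volumes not multiple of 10 ml); decoding is total on the grammar and names
the offending field otherwise, and never partially applies settings.

## Energy accounting

Pack energy = cell capacity × parallel strings × pack voltage (3S2P ×
3400 mAh at 12.6 V → 85.68 Wh). Average power = energy/duration; runtime =
pack energy / average power. "x times more efficient" is reference/new − 1,
the only convention consistent with both published fold values and their
underlying energies. The simulated electrical draw (idle 5 W + 20 W·(s/255)³,
the cubic being the aerodynamic fan-power law, the coefficient chosen so a
high-pressure operating point sits near the measured ~15.3 W) feeds
qualitative run ledgers only; all quantitative energy results come from the
measured inputs.

## Problem sizes and determinism

Closed-loop runs in the test suite and acceptance script use 1 ms steps:
60 s of PCV (12 breaths), 26 breaths of PRVC spanning a mid-run compliance
halving, 6 SIMV breaths with scripted efforts, and a 50 s
disconnect/reconnect cycle — each a few seconds of wall time, chosen as the
shortest horizons on which convergence, re-convergence and alarm latency
are measurable. Identical settings and seed give bit-identical outputs (one
numpy Generator drives all sensor noise; scenario randomness is seeded
separately at construction).

## Limitations

- The lung is linear: no critical-opening-pressure/recruitment behaviour,
  no nonlinear compliance, no gas compressibility (a real circuit's
  compliance smooths the waveforms and would soften the trigger deadband
  analysis).
- The additive pressure balance is a behavioural model of the PRM free-body
  description, not node physics; its conductance ratios and the P2:P4 bias
  are free parameters with defaults chosen for closed-loop plausibility.
- Servo motion is instantaneous between open fractions; motor electrical
  dynamics, filter (HEPA/HME) resistance and oxygen blending are out of
  scope.
- Passing tests demonstrate internal consistency and the specified
  closed-loop behaviours on the synthetic lung; they do not certify
  performance on physical hardware or nonlinear patient mechanics.
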