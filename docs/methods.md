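# Methods

`solvex` is the control logic of a low-cost automated tissue processor for
solvent-exchange protocols (graded ethanol dehydration/rehydration around
staining and clearing steps), re-built as a hardware-agnostic library. This
note records the models it implements, the parameters that matter, the
design choices that were genuinely open, and what the simulator does and
does not capture.

## Device model

The instrument has three peristaltic pumps drawing from stock bottles
(typically distilled water, 70% ethanol, absolute ethanol) into a **premix
container**, a motorized top ball valve that gravity-transfers the premix
into the **tissue container**, and a servo-driven bottom valve that drains
the tissue container into a waste bottle. A protocol step is: blend the
target solution in the premix container, transfer, soak for the programmed
time, drain, repeat. The tissue stays submerged except for the short
drain/refill transition.

## Dosing calibration

Volume delivery is open-loop: pump run time × calibrated flow rate.

- **Estimator.** `estimate_flow_rate` is the mean of per-measurement
  volume/time ratios with their sample SD — exactly the computation used to
  characterize the instrument (24 timed dispenses over 10–80 s run times
  give 1.10 ± 0.02 mL/s). A through-origin least-squares slope
  (`estimate_flow_rate_regression`) is provided for comparison but is not
  the default: the ratio mean weights every dispense equally, matching how
  the calibration session is actually analyzed.
- **Scale factor.** A dimensionless multiplier on delivered volume
  (default 1.0) supports re-scaling for a different pump model without
  re-running a full calibration.
- **Synthetic calibration sessions.** `generate_dispense_measurements`
  draws a realized rate per dispense from N(1.10, 0.02) mL/s and returns
  volume = rate × run time for 8 run times × 3 replicates — the session
  layout and noise level of the instrument's characterization. These are
  its defaults and are not adjusted per test.

## Blending

With stocks at concentrations c_lo < c_hi bracketing a target c_t and an
exchange volume V, the two-stock balance

    v_hi = V (c_t − c_lo) / (c_hi − c_lo),   v_lo = V − v_hi

achieves the target exactly under volume-additive mixing. With three stocks
the problem is underdetermined; the default strategy always uses the two
*adjacent* bracketing stocks (water + 70% below 70%, 70% + 100% above),
which minimizes absolute-ethanol consumption and mirrors graded-series
practice. The strategy is a pluggable function. An exact single-stock match
(within 1e-9) short-circuits to that stock alone. Ethanol/water excess
volume (~3% contraction at mid fractions) is ignored: series concentrations
are nominal labels and the device has no densitometry; the config-driven
concentrations, not hard-coded constants, carry whatever convention the lab
uses.

## Schedule compilation

`compile_routine` expands each step into dose → transfer → soak → drain
phases. Choices:

- **Pumps dose sequentially**, never in parallel, so delivered volumes are
  independent of relay timing (the device runs pumps simultaneously only in
  the Flush utility).
- **Prefetch (default on).** The premix for step k+1 is blended during step
  k's soak, so the refill starts immediately after draining and the tissue
  is out of liquid only for the drain window plus the gravity fill. A
  strictly serial mode exists (`prefetch=False`). If a soak is shorter than
  the next dose time the compiler emits a warning instead of failing.
- **Quantization.** Pump times are real-valued in dose plans; times are
  rounded to the controller tick (default 0.1 s) only at compilation, and
  the per-step residual volume error (at most ~0.1 mL per pump at
  1.10 mL/s) is recorded on the step summary. Simulated soak volumes are
  therefore within ±0.25 mL of the nominal exchange volume.
- **Gravity transfer** is modeled as exchange_volume / transfer_flow_rate
  plus a valve actuation latency. The transfer rate (default 10 mL/s) and
  drain window (default 30 s) are configuration values, not measured
  device constants.
- **No terminal drain.** After the final soak the tissue stays submerged
  for retrieval; a post-stain run therefore ends with the tissue container
  full of absolute ethanol.

## Runtime state machine

The runner executes actions at their scheduled times against any
`HardwareBackend`, logging every action, progress record (step, target
concentration, elapsed, remaining — the device display readout), command,
and fault into an append-only `RunLog` serializable as JSON-lines.

- **Pause** stops pumps and closes both valves immediately and freezes the
  timeline; **resume** restores interrupted actuators and shifts all
  remaining actions by the pause duration, so soak totals and delivered
  volumes are preserved to within one controller tick.
- **Abort** and any actuation fault drive the safe state — valves closed,
  pumps off — chosen because it keeps the tissue submerged in whatever
  liquid is present.
- The `Clock` abstraction separates scheduling from time: `SimulatedClock`
  lets a 10-hour protocol run in milliseconds while the virtual device
  integrates the same flows; `RealTimeClock` sleeps on the wall clock
  (optionally accelerated).
- `replay_log` re-applies a log to a fresh backend; on the deterministic
  simulator this reproduces the final state, making logs self-contained
  run records.

## Virtual device

A mass-balance simulator tracking (volume, ethanol volume) per container
with **perfect instantaneous mixing** in the premix container (no stirrer
is modeled; the gravity pour adds real mixing). Integration is event-driven
with exact piecewise-linear flows: within a constant actuator set, volumes
are linear in time, so the state advances between cutoff events (stock
exhaustion, premix emptying, drain completion, capacity) with no ODE error.
An empty container with its outlet open passes inflow straight through.
Volume and ethanol balances are asserted to 1e-6 mL after every advance.

- **Noise.** Each pump-on event draws a realized rate from
  N(rate, pump_rate_sd); default sd 0 (ideal pump). With sd 0.02 the
  simulated dispense CV reproduces the calibration spread.
- **Faults.** `inject_fault(component, "dead" | "degraded")` makes commands
  raise or scales flow rates, and is surfaced by `self_test`/`sanity_check`
  — this is how safe-state handling is exercised.
- **Stocks are finite** (default 1000 mL per bottle, low-level warning at
  100 mL). Full multi-step protocols need more: the 14-step
  dehydration/rehydration routine alone draws ~1350 mL of 70% ethanol, so
  simulated full runs (and the `simulate` CLI) start bottles at 4000 mL,
  representing the operator filling bottles to the protocol's demand.
- Not modeled: tubing dead volume, siphoning, bubbles, evaporation during
  soaks, partial valve states, thermal effects. Overflow is a fault event,
  never silent clipping.

## Built-in PI routines

The two propidium-iodide staining routines ship as fixtures: routine 1
(dehydration/rehydration) soaks at 50, 70, 85, 95, 100, 100, 95, 85, 70,
50, 30, 15, 0, 0 % ethanol and routine 2 (post-stain) at 0, 0, 15, 30, 50,
70, 85, 95, 100, 100 %, every step 30 min. Together they are the >20
sequential exchanges of the full workflow (24 steps, 12 h of soak; a
20-step × 30 min routine compiles to exactly 10 h of soak).

## Staining QC

Staining quality is summarized from a 1-D confocal line profile as
SNR = mean stained-cell-wall intensity / background intensity, and groups
(e.g. manual vs automated processing, n = 3 samples each) are compared with
a two-sided Welch t-test.

- **Segmentation.** Which points are "wall" and which "background" is a
  choice the SNR definition leaves open; here background points are those
  at or below the 25th percentile and signal points are local maxima above
  3× background, both overridable and both reported in the result.
  Selection runs on a moving-average-smoothed copy (window 5) while the
  means use raw intensities at the selected points: selecting the lowest
  quartile of *raw* noisy samples would bias the background mean low by
  ≈1.27σ and inflate SNR by ~14% at 10% noise, whereas selection on the
  smoothed trace keeps the bias under ~6% there and exactly zero in the
  noiseless limit. If no peak clears the threshold the global maximum is
  used and the result is flagged low-confidence (a flat profile yields
  SNR = 1).
- **Welch, not pooled.** With n = 3 either test is defensible; Welch makes
  no equal-variance assumption and is the safer default. Its true type-I
  error at n = 3 per group is ≈0.034 (slightly conservative); the
  calibration test estimates it over 20 000 vectorized null replicates so
  Monte-Carlo error (SD ≈0.0013) does not blur the check.
- **Generator.** `generate_profile` makes baseline-plus-Gaussian-wall-peak
  traces (peaks truncated at 4σ so the far field equals the background
  exactly) with additive truncated-at-zero Gaussian noise, returning the
  ground-truth ratio. It emulates profile shape and sensor noise, not
  optical artifacts (bleed-through, depth attenuation, out-of-focus haze)
  — so recovery tests validate the estimator's calibration, not
  image-quality claims about real tissue.

## Problem sizes

Simulated protocol runs execute the full 10- and 14-step routines
event-driven (a few hundred events; milliseconds each). Statistical
properties use 24-dispense calibration sessions, 11-seed SNR recovery
grids, and 20 000-replicate null simulations — sizes at which every check
in the suite completes in about a second.

## Known limitations

No closed-loop volume or concentration sensing is modeled (the real device
has none). Physical GPIO/relay drivers are out of scope; `HardwareBackend`
is the extension point. The TIFF line-profile extraction is a convenience
(bilinear sampling along a segment), not a 2-D segmentation pipeline.
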