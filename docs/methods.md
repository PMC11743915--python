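# Methods

This note documents the models implemented in `triggerbench`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
benches do and do not establish.

## Trigger state machine (`trigger_core`)

The channel machine has two phases, `idle` and `in_pulse`, advanced once per
sample instant. Within a tick the order of evaluation is fixed:

1. a supra-threshold sample while `in_pulse` first refreshes the
   last-supra-threshold time (so a still-supra sample at a would-be
   termination tick *extends* the pulse via the increment rather than
   terminating and immediately re-triggering);
2. termination is then evaluated (`t − t_onset ≥ d_min` **and**
   `t − t_supra ≥ d_inc`); a pulse never terminates and re-fires on the
   same tick;
3. only in `idle` can a supra-threshold sample raise the output, gated by
   the refractory period measured onset-to-onset.

Consequences, all asserted by tests:

* emitted durations are quantized upward: a sustained input with increment 0
  gives exactly `T_s·⌈d_min/T_s⌉` (10 ms at 160 µs/sample → 10.080 ms);
* `d_min = d_inc = 0` gives the smallest representable pulse, one sample
  period;
* crossings during the refractory period are silently ignored — they
  neither fire nor extend anything;
* detection latency for an abrupt onset at uniform-random phase is uniform
  on `[0, T_s)`, hence jitter S.D. `T_s/√12`.

Threshold comparison is strict (`sample > θ`) on raw ADC counts (10-bit,
0–1023): the firmware-style parameter menu is unitless, and the strict
comparison makes "threshold at the DC-bias code" mean "any positive
excursion". Whether a real firmware uses `>` or `≥` is unobservable at any
realistic noise level; the choice is documented rather than consequential.

`dc` mode uses the same supra-threshold logic as `oscillatory` — the two
differ only in the character of the input signal — with a `polarity` option
(`rising`/`falling`) so a light sensor whose voltage *drops* at stimulus
onset can trigger on downward crossings. No baseline tracking is attempted;
only threshold crossing is implemented.

Switch channels register a closure once the closed state has persisted for
`debounce_time` (default 20 ms — mechanical bounce settles well within
this) and are gated by a 100 ms refractory default; the event timestamp is
the first sample of the stable closed run, i.e. the press itself rather
than the moment de-bouncing confirms it.

Times in the firmware-facing modules are microseconds (the natural scale of
the parameter menu and of the latencies measured); the signal/analysis
modules use seconds and Hz. Reports are microseconds.

## Device model (`device_model`)

Per-channel costs default to 16.5 µs (trigger) and 0.5 µs (switch). These
are calibrated, not measured: they are consistent simultaneously with a
16–17 µs per-channel processing time and with all three documented rate
ceilings (8 triggers → 6.25 kHz; 6 triggers + 1 switch → 10 kHz; 1 trigger
→ 50 kHz). Both are configurable.

The rate menu defaults to 50 kHz divided down to round sample periods:
50, 25, 12.5, 10 and 6.25 kHz (periods 20/40/80/100/160 µs). Divisors
giving fractional or non-round periods (50/3, 50/6, 50/7 kHz) are excluded:
offering 50/7 kHz (140 µs) would make an 8-trigger device at any cost below
17.5 µs "feasible" at a rate the documented ceilings say it cannot reach.
The menu is a constructor argument for devices that differ.

A rate is feasible iff the summed channel costs plus loop overhead fit
*strictly* inside one sample period; the idle fraction is
`max(0, 1 − total_cost/T_s)`. Requesting an infeasible rate raises an error
naming the maximum feasible one.

There is no sample-and-hold: each channel evaluates the live analog source
at its own instant `n·T_s + Σ_{j<i} c_j`, and its output edge is applied
when its processing completes, one further cost later. Edge timestamps are
continuous (unquantized); quantization enters only through the virtual
digitizer. The front ends are idealized: `half_wave` clamps to
[0, 3.3 V] before 10-bit floor quantization (negative excursions read 0),
`dc_biased` first adds V_CC/2 = 1.65 V (0 V reads code 512). Level
converters, LEDs, interrupt latency and clock drift are not modeled.

## Signal bank (`signal_bank`)

The generators produce the bench's study conditions:

* **onset tone** — cosine-phase 100 Hz carrier (first sample at +amplitude,
  the abrupt edge the trigger should catch), flat for 50 ms, then a
  raised-cosine decay reaching zero at 100 ms. Only "abrupt onset, silent
  by 100 ms" is essential; the taper shape is a package choice and none of
  the timing results depend on it.
* **noise bursts** — zero-mean white Gaussian, rectangular 25 ms envelope,
  one independent realization per event.
* **stimulus trains** — onset-to-onset gaps i.i.d. uniform on [0.25, 1] s;
  187 events for the latency bench, 200 for the pulse bench. Uniform gaps
  also guarantee stimulus onsets at uniform-random phase relative to the
  device's sample grid, which is what makes the T_s/√12 law apply.
* **oddball sequences** — 270 standard / 80 target / 60 distractor events
  on a 1 s onset grid; standards and targets are 340 ms square waves at
  400/575 Hz, distractors unique band-passed noise realizations.
* **virtual digitizer** — uniform resampling at 100 kHz (10 µs cells)
  through linear interpolation of the source.

Every stochastic generator requires an explicit seed and reruns
bit-identically. Amplitudes are stated relative to the trigger threshold
(default tone amplitude 1 V ≈ 6× the 50-count ≈ 0.16 V threshold); absolute
playback levels are irrelevant to the timing questions.

Not emulated: soundcard output latency/jitter beyond a configurable
constant (the ERP demo injects these explicitly), analog noise floors,
device/digitizer clock drift. The last omission has one visible effect: an
exact 10.080 ms pulse is a whole number of 10 µs digitizer cells, so the
digitized duration always reads 10.080 ms, whereas real equipment with
slightly drifting clocks reads 10.080 or 10.090 ms. The emulator's value
set is a subset of the hardware's.

## Timing analysis (`timing_analysis`)

* `detect_onsets`: first sample with `|Δv|` above the threshold per event;
  detections within `min_separation` (default 100 ms — shorter than the
  shortest 250 ms gap, longer than any stimulus feature) are suppressed.
* `group_correct` (Woody-style): epochs in a (−1 ms, +5 ms) window, shifts
  up to ±2 ms, at most 10 sweeps. Each epoch's Pearson correlation with the
  full mean epoch (not leave-one-out) is maximized over integer-sample lags;
  ties break toward the smallest |shift|. The epoch matrix is re-extracted
  each sweep; iteration stops at an all-zero shift vector. The window,
  bound and threshold are package decisions — the measured jitter is
  insensitive to them over wide ranges because the corrected onsets only
  enter through their dispersion.
* `edge_times`: logic threshold defaults to 50 % of the observed high
  level; crossings are linearly interpolated between bracketing samples
  (sub-sample precision); an unterminated final pulse is flagged
  open-ended.
* `latency_stats`: each input onset pairs with the nearest following
  output onset within 50 ms; unpaired inputs are counted and excluded;
  S.D. uses ddof = 1.

## ERP jitter (`erp_jitter`)

Components are Gaussian bells (signed amplitude, latency, width = Gaussian
σ). The defaults — MMN −3 µV at 175 ms σ 40 ms, P3a +5 µV at 300 ms σ
60 ms, 300 Hz grid over (−100, 800) ms, 10 µV trial noise — are demo
values of realistic order, not measurements. Latency jitter is normal with
demo S.D. 30.7 ms on top of a 227 ms constant audio latency.

Epochs evaluate the analytic template at `t − shift`, so non-integer shifts
are exact. The expected time-locked average is the template convolved with
the latency density; `smear_oracle` evaluates that convolution by
trapezoid quadrature, and for Gaussian components it reduces to the closed
form: widths add in quadrature and the peak shrinks by `w/√(w² + σ²)`.

The latency of a broad noisy peak is a badly behaved statistic — the argmax
of a shallow extremum wanders far more than the mean of the latency
distribution — so `peak_latency_se` estimates its standard error by
bootstrap over epochs (200 resamples), and the demo's latency-shift check
uses that SE rather than the naive `σ/√n`.

## Problem sizes and runtimes

The benches run at full study scale: 187 tones (~117 s of signal, ~7.3·10⁵
device ticks per channel across 8 channels, ~1.2·10⁷ digitizer samples per
line) in roughly 20 s on one core; 200 noise bursts similarly; the ERP
convolution check uses n = 5000 epochs. The state-machine oracle tests use
≥100 short random traces against a deliberately naive history-based
reference.

## Known limitations

* The emulator is idealized firmware: no interrupt latency, no clock drift,
  no analog front-end noise; measured hardware will show these on top.
* `dc` mode is plain threshold crossing; slow baseline drift of a light
  sensor would require re-thresholding, which the model does not automate.
* The ERP module synthesizes difference waves directly; it does not model
  electrodes, head geometry, or real single-trial EEG statistics, so its
  tests demonstrate the averaging mathematics, not biological realism.
* Latency *means* reported by the pipeline depend on the onset-detection
  threshold (an arbitrary criterion for "when the sound begins"); only the
  jitter (S.D.) is threshold-invariant, and the benches treat it as the
  primary figure of merit.
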