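# Methods

This note documents the models, estimators and defaults behind `adbsim`,
the choices made where the design was genuinely open, and what the
simulator does and does not capture about in-vivo adaptive DBS.

## Synthetic LFP generation

Each hemisphere's signal is a sum of independent components, in µV at
250 Hz (configurable; the rate must exceed twice the highest peak
frequency and tile the 100 ms control cadence):

* **Aperiodic background** — Gaussian noise colored in the frequency
  domain to a one-sided PSD of `10^offset / f^exponent` µV²/Hz
  (defaults: offset −1.5, exponent 1.0), plus a white noise floor given
  as an RMS amplitude (default 0.05 µV).
* **Oscillatory peaks** — narrowband Gaussian processes: white noise
  band-pass filtered (4th-order Butterworth) around the peak frequency
  with the configured bandwidth (default 3 Hz). A filtered-noise rhythm
  matches the stochastic, bursty character of basal-ganglia beta better
  than a pure tone while remaining calibratable.
* **Artifacts** — additive ECG (triangular ~80 ms QRS-like template at
  the configured heart rate with ±5% beat-interval jitter) and movement
  transients (Poisson-timed 300 ms Hann-windowed broadband bursts).

### Amplitude calibration

Peak amplitudes are specified in µVp — the value a Welch estimator with
a 1 s Hann window reports at the spectral peak, the convention used by
sensing hardware. For a narrowband process this is not the RMS: the
calibration computes the expected Welch-peak PSD of the unit-variance
band-pass shape analytically (filter response convolved with the Hann
window's spectral kernel) and scales the process variance so the
estimator's expected peak equals the requested amplitude, via
`A = √(2·PSD·ENBW)`. Tests assert recovery within max(0.1 µVp, 10%)
over 60 s of clean synthesis; the residual error is Welch estimator
variance plus a small kernel-approximation bias (~2–4% depending on
bandwidth).

### Modulation

All modulation sources multiply the oscillatory envelope and compose
multiplicatively (an invariant the tests assert exactly):

* **Bursts** — Poisson onsets at `burst_rate` events/s; durations gamma
  distributed with the configured mean and coefficient of variation
  (shape = 1/cv², scale = mean·cv²), so any positive dispersion yields a
  right tail producing bursts beyond 500 ms; gain applied through a
  raised-cosine 10 ms-edged envelope to avoid spectral splatter;
  overlapping bursts merge by pointwise maximum so the gain is bounded.
* **Medication** — each dose contributes a unit-peak bi-exponential
  `exp(−t/τ_washout) − exp(−t/τ_washin)` (defaults 90 / 20 min), doses
  additive and clipped at 1; beta amplitude scales by
  `1 − f_med · effect(t)`. The simplest wash-in/wash-out model with two
  interpretable constants.
* **Stimulation** — amplitude factor `1 − f_stim · σ((A − A₅₀)/s)` with
  logistic σ, slope `s` defaulting to A₅₀/4: a saturating dose-response
  anchored by one parameter. This is the feedback path in closed-loop
  runs. Note σ(−4) ≈ 0.018, so a small residual suppression exists at
  0 mA; it cancels in the threshold-ratio properties the tests check.
* **Circadian** — `1 + c·cos(2π(hour − acrophase)/24)` applied to the
  oscillatory amplitude only (default acrophase 15:00, fraction 0).

No quantitative magnitudes for medication or stimulation beta
suppression are established for this simulator's target population; the
defaults (`f_med`, `f_stim` of 0–0.5 in fixtures, A₅₀ = 1.5 mA) are
**placeholders chosen for plausibility** and should be treated as free
parameters, not measurements.

### Determinism

All randomness derives from one seed through
`numpy.random.SeedSequence.spawn` in a fixed per-purpose order
(background, bursts, artifacts, one stream per peak; per-hemisphere
children in closed-loop runs; programming before closed loop in
sessions). Identical configuration and seed give byte-identical samples
and identical session checksums.

## Sensing chain

* **30 s spectra** — Welch, 1 s Hann windows, 50% overlap, ~1 Hz
  resolution, grid 0–100 Hz, amplitudes `√(2·PSD·ENBW)` µVp. The
  device's internal estimator is not public; this choice is asserted by
  calibration tests (pure-tone peaks within 5%; Parseval within 1%).
* **Signal test** — largest local maximum above the fitted aperiodic
  background with amplitude strictly greater than 1.1 µVp, searched over
  8–100 Hz per channel; the overall best is the largest detected peak.
* **Aperiodic background** — robust straight line in log-frequency /
  log-power over 4–45 Hz (Siegel repeated-median slope), one re-fit with
  above-line points masked. Configurable.
* **Automated offline peak detector** — all local maxima in 8–30 Hz
  whose prominence above the background exceeds 0.3 µVp, ordered by
  frequency. This is a documented variant: the reference device's
  offline detector criteria are unpublished, so its printed nucleus-level
  detection rate can only be reproduced arithmetically from counts, not
  re-derived from recordings.
* **100 ms stream** — a 500 ms Hann-tapered FFT window advanced by
  100 ms; band power integrated over the closed 5 Hz interval around the
  control frequency and reported as the equivalent-sinusoid amplitude
  `√(2·band power)`. A 100 ms rectangular window cannot resolve a 5 Hz
  band at beta frequencies, so the 500 ms length is this package's
  documented choice. Sample times are window-end times.
* **Timeline** — arithmetic means of unblanked samples in 10-minute
  bins, 60-day capacity with oldest-first rotation; bins carry their
  sample counts.
* **Artifact flags** — ECG: autocorrelation of the rectified signal
  exceeding 0.15 at some lag in 0.6–2.0 s (30–100 bpm); movement: one
  0.5 s window's energy exceeding 8× the session median. Both thresholds
  are repo constants validated against generator fixtures.

## Controllers

Comparator → onset → ramp → blanking, stepped at the 100 ms detector
cadence (cadence violations are rejected):

* **Tie rule** — power exactly equal to a threshold is *not crossed*
  (below for single mode and the dual upper bound; between for the dual
  lower bound), mirroring the strict `>1.1 µVp` signal-test convention.
* **Onset** — counts consecutive 100 ms samples in the commanding
  region; one opposing sample resets it (no leaky integration). A ramp
  initiates when the timer reaches the onset duration. Defaults: 400 ms
  single (mid-range of the programmable 200–500 ms), 1600 ms dual
  (midpoint of 1.2–2 s).
* **Ramps** — ramp times denote full traversal of the stimulation
  window [lower, upper]; partial ramps use the same constant slope.
  Amplitude is evaluated in continuous time along the ramp line, so
  traversal times are exact rather than quantized to the cadence.
  Defaults: 250 ms both ways (single); 2.5 min up, 5 min down (dual,
  programmable 1–10 min).
* **Hold** — in dual mode the between region freezes the amplitude
  immediately (no onset requirement to stop), giving the incremental
  adjustment pattern; initiating a ramp in either direction requires
  onset.
* **Blanking** — a stimulation change suppresses detection for exactly
  the blanking duration (default 550 ms): samples in the window are
  flagged, excluded from timeline means, and do not advance onset.
  Whether the physical device suppresses sensing, detection or both is
  not public; this package blanks detection and flags the samples.
* **Bilateral linking** — a crossing in one hemisphere issues the same
  up/down command to both, each ramping within its own limits;
  idempotent under simultaneous crossings. With linking off, a
  hemisphere without an eligible signal holds a constant cDBS amplitude
  (defaulting to its upper stimulation limit). Each hemisphere is
  compared against the shared threshold configuration; per-hemisphere
  stimulation limits are supported.
* **Closed loop** — LFP synthesis, band-power streaming and the
  controller are co-simulated in 100 ms blocks; the stimulation
  amplitude applied to each 4 ms sample follows the analytic ramp line,
  and the beta envelope responds through the suppression sigmoid. The
  controller idles for the first 500 ms while the stream window fills.

## Programming workflow

Steps mirror the clinical procedure: stimulation limits are clinician
inputs (validated for ordering only); thresholds are 30 s means of the
100 ms stream at the prescribed stimulation level and medication state
(medication state changes are simulated by forcing the effect level);
dual mode measures the upper threshold at the *lower stimulation limit*
while single mode measures it at *0 mA* — replicated as prescribed,
without a stated clinical rationale. Inverted measurements (upper <
lower) halt the workflow with a diagnostic, since they indicate the
control signal did not respond to stimulation.

The orientation of the single-mode "75% of the way between upper
threshold and lower threshold" rule is ambiguous as written. The default
here measures **from the lower threshold toward the upper**
(`L + 0.75·(U−L)`), so stimulation escalates only for strong
control-signal elevations; the opposite orientation is available via
`derive_single_threshold(..., orientation="from_upper")`.

Ramp verification drives the controller with square-wave band-power
excursions (emulating repeated voluntary-movement modulation) over a
5-minute test and measures traversal times from the amplitude trace —
the window span divided by the fitted ramp slope — rather than echoing
the configuration.

## Cohort metrics

Band intervals for real-valued frequencies are [8,13), [13,21), [21,30],
covering the integer band definitions (alpha 8–12, low-beta 13–20,
high-beta 21–30) without gaps; the alternative 20–30 Hz high-beta
convention sometimes seen in discussion is noted but not used.
Percentages round half-away-from-zero to one decimal. The summarizer
reports its hemisphere denominators explicitly: participant-level rates
divide by participants, band rates by detected hemispheres.

TEED uses the current-controlled form `I²·Z·f·pw·t` (µJ) in place of the
voltage-based `V²/Z` original, appropriate for a current-controlled
device.

The exact binomial sample-size search enumerates n upward; for each n
the smallest critical value c with exact size ≤ α is checked for exact
power ≥ the target. The search is sawtooth-aware (exact power is not
monotone in n) and returns the first feasible n. For the performance-goal
quadruple (p₀ = 0.5, p₁ = 0.85, α = 0.0125, power = 0.9) the enumeration
gives **n = 22, c = 17** (size 0.00845, power 0.90005), verified directly
against the binomial tails in the tests. Published trial designs using
these inputs have reported larger minima (e.g. 36); such figures must
embed assumptions beyond the stated quadruple — attrition, per-mode
evaluation sets, or a different search convention — so the enumeration
here is the package's source of truth and the divergence is documented
rather than patched.

## Problem sizes and tolerances in the test suite

Spectral-fidelity checks use 60 s syntheses (tolerance max(0.1 µVp,
10%)); signal-test and workflow checks use the 30 s device epoch;
closed-loop tests run 8–60 s sessions; ramp verification uses 30 s
(single) and 300 s (dual) scripted tests; timeline and time-in-state
oracles use array-generated streams up to half a simulated day. Exact
quantities (ramp traversals, blanking window, threshold position,
cadence, table rates) are asserted to numerical precision; stochastic
spectral quantities at the estimator tolerances above.

## What the generator does and does not capture

Passing tests demonstrate that the sensing and control algorithms behave
correctly on signals with the assumed statistical structure — they do
not validate the generator against patient physiology. Not modeled:
biophysical neural dynamics (neural-mass or conductance models), volume
conduction and electrode geometry, gamma-band or tremor-frequency
pathology, stimulation pulse waveforms and charge-density limits,
nonstationarities beyond bursts/medication/circadian (e.g. sleep
architecture, dyskinesia-linked narrowband gamma), realistic ECG
morphology, and patient-level distributions of peak frequency and
amplitude (fixtures use representative point values). The published
detection-rate dependence on real recordings is reproducible only as
arithmetic on printed counts, which is how the cohort summarizer is
tested.
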