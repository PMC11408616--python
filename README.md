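# adbsim

A desk-scale simulator of LFP-guided **adaptive deep brain stimulation
(aDBS)** for Parkinson's disease, covering the full sensing-and-control
stack of a sensing-enabled neurostimulator: synthetic basal-ganglia local
field potentials (LFPs), the device sensing chain, single- and
dual-threshold closed-loop stimulation controllers, the clinician
threshold-programming workflow, and cohort-level LFP summary statistics.

It is intended for researchers and engineers who want to study, teach or
prototype physiological closed-loop control (PCLC) policies for DBS
without access to patient recordings or implanted hardware: every input
the algorithms need is generated synthetically, with each physiological
mechanism independently switchable.

## The model

**Sensing.** The LFP is sampled at 250 Hz. Spectra are amplitude
calibrated in µVp (microvolts-peak): the reported amplitude is
√(2·PSD·ENBW), so a sinusoid of amplitude *A* µV produces a spectral peak
of *A* µVp. The device features emulated are: 30 s Welch spectra
(0–100 Hz, ~1 Hz resolution); a *signal test* reporting the largest
spectral peak above 1.1 µVp; streaming power in a 5 Hz band centered on
the chosen peak, one sample every 100 ms; chronic 10-minute timeline
averages (60-day capacity); patient-triggered 30 s event spectra (up to
four labels); and ECG/movement artifact flagging.

**Control.** Both controllers implement the PCLC loop

    band power → comparator → onset timer → ramp engine → stimulation amplitude

with detection *blanking* (default 550 ms) after every stimulation change.
In **single-threshold** mode, power above/below one LFP threshold ramps
stimulation to the upper/lower stimulation limit with a fast 250 ms full
traversal (trapezoidal control; onset 200–500 ms, sized to catch beta
bursts longer than 500 ms). In **dual-threshold** mode, power above the
upper threshold ramps up over 2.5 min, below the lower threshold ramps
down over 5 min, and *holds* in between (onset 1.2–2 s). A threshold
crossing in one hemisphere can command both (bilateral linking).

**Programming.** The clinician workflow measures the LFP thresholds from
30 s epochs of the 100 ms band-power stream at prescribed stimulation
levels (0 mA or the lower limit for the upper threshold; the upper limit
for the lower threshold), then sets the single-mode default threshold at
**75% of the way from the lower threshold to the upper**.

**Synthesis.** Each hemisphere's LFP is a 1/f aperiodic background plus
narrowband Gaussian oscillations calibrated in µVp, multiplicatively
modulated by beta bursts (Poisson onsets, gamma durations), medication
state (bi-exponential wash-in/wash-out), stimulation (a saturating
sigmoid — this closes the loop), and a circadian sinusoid.

**Cohort metrics.** Peak classification into alpha (8–12), low-beta
(13–20) and high-beta (21–30 Hz); detection-rate summary tables with
explicit denominators; TEED (total electrical energy delivered,
I²·Z·f·pw); per-day time-in-state fractions; and the exact one-sided
binomial sample-size computation for performance-goal designs.

## Worked example

```python
import adbsim

config, manifest = adbsim.make_fixture("clean_beta_16p6", seed=42)
patient = config.patient

# screening: 30 s spectrum + signal test
rec = adbsim.generate_lfp(patient, "left", 30.5, seed=42, med_override=0.0)
reports, best = adbsim.signal_test({rec.channel_id: adbsim.compute_psd(rec)})
print(best.center_frequency, best.amplitude)   # 17.0 2.352...

# clinician programming workflow, single-threshold mode
record = adbsim.setup_workflow(patient, "single",
                               lower_stim_limit=0.5, upper_stim_limit=3.0,
                               seed=42)
print(record.transcript())
```

The transcript printed for this seed ends with:

```
Step 3 (left): stim 0.00 mA, 30 s mean 2.770 µVp -> upper LFP threshold
Step 4 (left): stim 3.00 mA, 30 s mean 1.397 µVp -> lower LFP threshold
Step 5: single threshold 2.427 µVp at 75% of [1.397, 2.770]; default ramp 250 ms, onset 400 ms
```

The patient's 16.6 Hz / 2.32 µVp low-beta peak is recovered by the signal
test at the spectrum's 1 Hz resolution. Stimulation at the 3 mA upper
limit suppresses the measured band power from 2.770 to 1.397 µVp
(the patient's suppression sigmoid at work), and the derived single
threshold 2.427 µVp sits exactly 75% of the way up that interval.

Closing the loop and verifying the programmed ramps:

```python
trace = adbsim.run_closed_loop(patient, record.config, 60.0, seed=42,
                               med_override=0.0)
print(len(trace.events))                        # 112 stimulation changes
report = adbsim.verify_ramp(record.config)
print(report["measured_up_traversal_s"])        # 0.25
```

The measured full ramp traversal of 0.25 s is recovered from the
simulated amplitude trace, not echoed from the configuration.

A command line mirrors the library: `adbsim simulate`, `signal-test`,
`program`, `run`, `summarize`, `teed`, `fixtures`.

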