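"""Clinician aDBS programming workflow.

Reproduces the six-step threshold-programming procedure a clinician
follows when setting up LFP-guided adaptive stimulation:

1. capture the upper stimulation limit (off medication) — clinician input;
2. capture the lower stimulation limit (on medication) — clinician input;
3. measure the upper LFP threshold off medication over a 30 s epoch,
   with stimulation held at the lower stimulation limit (dual mode) or at
   0 mA (single mode);
4. measure the lower LFP threshold off medication over a 30 s epoch with
   stimulation at the upper stimulation limit; in single mode, derive the
   default single threshold at 75% of the way between the two;
5. attach default ramp times and onset durations;
6. verify ramping behavior with a 5-minute scripted test.

Clinician-supplied quantities (stimulation limits, symptom acceptability)
are inputs, not computed; the workflow validates ordering only. Steps
prescribing a medication state are simulated by forcing the medication
effect level (off = 0, on = 1).

The direction of the "75% of the way" rule is ambiguous as stated
clinically; this package defaults to measuring from the lower LFP
threshold toward the upper (threshold = L + 0.75·(U − L)) so stimulation
escalates only for strong control-signal elevations, and exposes the
opposite orientation behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import controller as ctl
from . import sensing
from .sensing import PeakReport
from .synthetic import HEMISPHERES, PatientModel, generate_lfp

__all__ = [
    "ThresholdMeasurement",
    "ProgramRecord",
    "WorkflowError",
    "check_eligibility",
    "measure_threshold",
    "derive_single_threshold",
    "setup_workflow",
    "verify_ramp",
    "ELIGIBLE_BAND_HZ",
    "ELIGIBLE_MIN_UVP",
    "THRESHOLD_EPOCH_S",
    "SINGLE_THRESHOLD_POSITION",
]

#: Eligibility window for the control signal.
ELIGIBLE_BAND_HZ = (8.0, 30.0)
ELIGIBLE_MIN_UVP = 1.2  # inclusive

#: Threshold measurements use a 30 s epoch of the 100 ms stream.
THRESHOLD_EPOCH_S = 30.0

#: The default single threshold sits this fraction of the way along the
#: inter-threshold interval, measured from the lower LFP threshold.
SINGLE_THRESHOLD_POSITION = 0.75


class WorkflowError(RuntimeError):
    """A programming step failed with a clinically meaningful diagnostic."""


@dataclass
class ThresholdMeasurement:
    """Mean control-band power over a 30 s epoch at a held stimulation level."""

    stim_level: float  # mA
    epoch_duration: float  # s; always 30
    mean_band_power: float  # µVp
    channel: str

    def __post_init__(self) -> None:
        if self.epoch_duration != THRESHOLD_EPOCH_S:
            raise ValueError("threshold epochs must be exactly 30 s")
        if self.mean_band_power < 0:
            raise ValueError("mean band power must be non-negative")


@dataclass
class ProgramRecord:
    """Outcome of one programming workflow run."""

    mode: str
    eligibility: dict[str, PeakReport]
    eligible_hemispheres: list[str]
    control_frequencies: dict[str, float]
    measurements: dict[str, list[ThresholdMeasurement]]
    config: ctl.ControllerConfig | None
    log: list[str] = field(default_factory=list)

    def transcript(self) -> str:
        return "\n".join(self.log)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def check_eligibility(peak: PeakReport, artifact_flagged: bool = False) -> bool:
    """A control signal is eligible iff its peak lies in 8–30 Hz with
    amplitude ≥ 1.2 µVp on a channel not flagged for artifacts."""
    if artifact_flagged or not peak.detected:
        return False
    lo, hi = ELIGIBLE_BAND_HZ
    return lo <= peak.center_frequency <= hi and peak.amplitude >= ELIGIBLE_MIN_UVP


# ---------------------------------------------------------------------------
# Threshold measurement
# ---------------------------------------------------------------------------

def measure_threshold(
    model: PatientModel,
    hemisphere: str,
    stim_level: float,
    center_frequency: float,
    seed: int | np.random.SeedSequence = 0,
    med_state: str = "off",
) -> ThresholdMeasurement:
    """Mean of the 100 ms band-power stream over exactly 30 s.

    Stimulation is held constant at ``stim_level`` mA for the whole epoch
    and the medication effect is forced to the prescribed state.
    """
    med = {"off": 0.0, "on": 1.0}[med_state]
    # pad by one analysis window so the stream covers a full 30 s
    rec = generate_lfp(
        model,
        hemisphere,
        THRESHOLD_EPOCH_S + sensing.STREAM_WINDOW_S,
        stim_trace=stim_level,
        seed=seed,
        med_override=med,
    )
    stream = sensing.band_power_stream(rec, center_frequency)
    n_epoch = int(round(THRESHOLD_EPOCH_S / sensing.STREAM_STEP_S))
    if len(stream) < n_epoch:
        raise WorkflowError("insufficient data for a 30 s threshold epoch")
    mean = float(stream.band_power[:n_epoch].mean())
    return ThresholdMeasurement(
        stim_level=stim_level,
        epoch_duration=THRESHOLD_EPOCH_S,
        mean_band_power=mean,
        channel=rec.channel_id,
    )


def derive_single_threshold(
    upper_t: float,
    lower_t: float,
    orientation: str = "from_lower",
) -> float:
    """Default single-mode threshold, 75% of the way along [lower, upper].

    ``orientation="from_lower"`` (default) returns L + 0.75·(U − L);
    ``"from_upper"`` returns U − 0.75·(U − L). ``upper_t < lower_t``
    signals inverted physiology — stimulation failed to suppress the
    control signal — and halts the workflow.
    """
    if upper_t < lower_t:
        raise WorkflowError(
            f"inverted thresholds (upper {upper_t:.3f} < lower {lower_t:.3f} µVp): "
            "stimulation did not suppress the control signal; review the "
            "control band and stimulation titration before programming aDBS"
        )
    if orientation == "from_lower":
        return lower_t + SINGLE_THRESHOLD_POSITION * (upper_t - lower_t)
    if orientation == "from_upper":
        return upper_t - SINGLE_THRESHOLD_POSITION * (upper_t - lower_t)
    raise ValueError(f"unknown orientation {orientation!r}")


# ---------------------------------------------------------------------------
# Full workflow
# ---------------------------------------------------------------------------

def _screen_hemisphere(
    model: PatientModel, hemisphere: str, seed: np.random.SeedSequence
) -> tuple[PeakReport, bool]:
    """Signal test + artifact screen at 0 mA, off medication."""
    rec = generate_lfp(model, hemisphere, 30.0 + sensing.STREAM_WINDOW_S,
                       stim_trace=0.0, seed=seed, med_override=0.0)
    spectrum = sensing.compute_psd(rec)
    reports, _ = sensing.signal_test({rec.channel_id: spectrum})
    flagged = sensing.detect_artifacts(rec) != {"clean"}
    return reports[rec.channel_id], flagged


def setup_workflow(
    model: PatientModel,
    mode: str,
    lower_stim_limit: float | dict[str, float],
    upper_stim_limit: float | dict[str, float],
    seed: int | np.random.SeedSequence = 0,
    threshold_orientation: str = "from_lower",
) -> ProgramRecord:
    """Run the programming workflow and emit a ready-to-use controller config.

    ``lower_stim_limit`` / ``upper_stim_limit`` are the clinician-chosen
    stimulation limits (steps 1–2). Eligibility screening, 30 s threshold
    measurements at the prescribed stimulation levels and medication
    states (steps 3–4), and default timing constants (step 5) follow the
    mode's prescription. Deterministic given the seed.
    """
    if mode not in ("single", "dual"):
        raise ValueError("mode must be 'single' or 'dual'")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    screen_seeds = dict(zip(HEMISPHERES, ss.spawn(2)))
    meas_seeds = dict(zip(HEMISPHERES, ss.spawn(2)))

    def limit(value, hemi):
        return float(value[hemi]) if isinstance(value, dict) else float(value)

    log = [
        f"Step 1: upper stimulation limit (off medication, clinician input): "
        + ", ".join(f"{h}={limit(upper_stim_limit, h):.2f} mA" for h in HEMISPHERES),
        f"Step 2: lower stimulation limit (on medication, clinician input): "
        + ", ".join(f"{h}={limit(lower_stim_limit, h):.2f} mA" for h in HEMISPHERES),
    ]

    eligibility: dict[str, PeakReport] = {}
    eligible: list[str] = []
    freqs: dict[str, float] = {}
    for hemi in HEMISPHERES:
        peak, flagged = _screen_hemisphere(model, hemi, screen_seeds[hemi])
        eligibility[hemi] = peak
        if check_eligibility(peak, artifact_flagged=flagged):
            eligible.append(hemi)
            freqs[hemi] = peak.center_frequency
            log.append(
                f"Screening {hemi}: peak {peak.center_frequency:.1f} Hz, "
                f"{peak.amplitude:.2f} µVp -> eligible"
            )
        else:
            why = "artifact-flagged" if flagged else (
                "no peak detected" if not peak.detected else
                f"peak {peak.center_frequency:.1f} Hz / {peak.amplitude:.2f} µVp "
                "outside eligibility bounds"
            )
            log.append(f"Screening {hemi}: ineligible ({why})")

    if not eligible:
        raise WorkflowError(
            "no hemisphere has an eligible control signal (8-30 Hz, >=1.2 µVp, "
            "artifact-free); aDBS cannot be programmed"
        )

    measurements: dict[str, list[ThresholdMeasurement]] = {h: [] for h in eligible}
    upper_thr: dict[str, float] = {}
    lower_thr: dict[str, float] = {}
    for hemi in eligible:
        lo_ma, hi_ma = limit(lower_stim_limit, hemi), limit(upper_stim_limit, hemi)
        upper_meas_level = lo_ma if mode == "dual" else 0.0
        m_upper = measure_threshold(
            model, hemi, upper_meas_level, freqs[hemi], meas_seeds[hemi], med_state="off"
        )
        log.append(
            f"Step 3 ({hemi}): stim {upper_meas_level:.2f} mA, 30 s mean "
            f"{m_upper.mean_band_power:.3f} µVp -> upper LFP threshold"
        )
        m_lower = measure_threshold(
            model, hemi, hi_ma, freqs[hemi], meas_seeds[hemi], med_state="off"
        )
        log.append(
            f"Step 4 ({hemi}): stim {hi_ma:.2f} mA, 30 s mean "
            f"{m_lower.mean_band_power:.3f} µVp -> lower LFP threshold"
        )
        measurements[hemi] = [m_upper, m_lower]
        if m_upper.mean_band_power < m_lower.mean_band_power:
            raise WorkflowError(
                f"inverted thresholds in {hemi} hemisphere (upper "
                f"{m_upper.mean_band_power:.3f} < lower {m_lower.mean_band_power:.3f} "
                "µVp): stimulation did not suppress the control signal"
            )
        upper_thr[hemi] = m_upper.mean_band_power
        lower_thr[hemi] = m_lower.mean_band_power

    # a single control hemisphere drives both stimulation channels in dual
    # mode; in single mode the other hemisphere stays on cDBS
    primary = max(eligible, key=lambda h: eligibility[h].amplitude)
    common: dict = dict(
        lower_stim_limit=lower_stim_limit,
        upper_stim_limit=upper_stim_limit,
        control_hemispheres=eligible,
        center_frequency={h: freqs[h] for h in eligible} if len(eligible) > 1
        else freqs[primary],
    )
    if mode == "dual":
        config = ctl.ControllerConfig(
            mode="dual",
            lower_lfp_threshold=lower_thr[primary],
            upper_lfp_threshold=upper_thr[primary],
            bilateral_link=True,
            **common,
        )
        log.append(
            f"Step 5: dual mode thresholds ({lower_thr[primary]:.3f}, "
            f"{upper_thr[primary]:.3f}) µVp from {primary} hemisphere; default "
            "ramps 2.5 min up / 5 min down, onset 1600 ms"
        )
    else:
        single = derive_single_threshold(
            upper_thr[primary], lower_thr[primary], threshold_orientation
        )
        config = ctl.ControllerConfig(
            mode="single",
            single_threshold=single,
            bilateral_link=len(eligible) == 2,
            **common,
        )
        log.append(
            f"Step 5: single threshold {single:.3f} µVp at 75% of "
            f"[{lower_thr[primary]:.3f}, {upper_thr[primary]:.3f}]; default ramp "
            "250 ms, onset 400 ms"
        )
    if len(eligible) == 1:
        other = [h for h in HEMISPHERES if h != eligible[0]][0]
        log.append(
            f"Note: single viable signal ({eligible[0]}); "
            + (f"dual mode controls both hemispheres from it"
               if mode == "dual"
               else f"{other} hemisphere remains on cDBS")
        )
    log.append("Step 6: confirm performance after medication wash-in (clinical).")

    return ProgramRecord(
        mode=mode,
        eligibility=eligibility,
        eligible_hemispheres=eligible,
        control_frequencies=freqs,
        measurements=measurements,
        config=config,
        log=log,
    )


# ---------------------------------------------------------------------------
# Ramp verification
# ---------------------------------------------------------------------------

def verify_ramp(
    config: ctl.ControllerConfig,
    test_duration: float = 300.0,
    hemisphere: str | None = None,
) -> dict:
    """Measure ramp traversal times from a scripted 5-minute test.

    Drives the controller with square-wave band-power excursions (half the
    test spent clearly above the activating threshold, half clearly
    below), emulating repeated voluntary-movement LFP modulation, and
    measures from the amplitude trace: the full up and down traversal
    times (window span / fitted ramp slope) and the detection latency
    (trigger delay after an excursion onset).
    """
    hemi = hemisphere or config.control_hemispheres[0]
    lo, hi = config.stim_limits(hemi)
    if config.mode == "single":
        above = config.single_threshold * 2.0 + 1.0
        below = config.single_threshold * 0.5
    else:
        above = config.upper_lfp_threshold * 2.0 + 1.0
        below = config.lower_lfp_threshold * 0.5
    half = test_duration / 2.0

    def drive(t: float) -> float:
        return above if t <= half else below

    trace = ctl.run_scripted(drive, config, test_duration, hemisphere=hemi)
    stim = trace.stim[hemi]
    dt = ctl.CONTROL_DT_S

    def traversal(sign: int) -> float:
        d = np.diff(stim)
        moving = np.sign(d) == sign
        if not np.any(moving):
            return float("nan")
        # interior ramp samples carry the exact constant slope
        slopes = d[moving] / dt
        slope = np.max(np.abs(slopes))
        return float((hi - lo) / slope) if slope > 0 else float("nan")

    events = [e for e in trace.events if e["hemisphere"] == hemi]
    up_events = [e for e in events if e["to_ma"] > e["from_ma"]]
    down_events = [e for e in events if e["to_ma"] < e["from_ma"]]
    latency_up = up_events[0]["time_s"] if up_events else float("nan")
    latency_down = down_events[0]["time_s"] - half if down_events else float("nan")

    return {
        "mode": config.mode,
        "measured_up_traversal_s": traversal(+1),
        "measured_down_traversal_s": traversal(-1),
        "configured_up_traversal_s": config.ramp_up_time,
        "configured_down_traversal_s": config.ramp_down_time,
        "detection_latency_up_s": latency_up,
        "detection_latency_down_s": latency_down,
        "n_stimulation_changes": len(events),
    }
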