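"""Single- and dual-threshold closed-loop stimulation controllers.

Implements the physiological closed-loop control (PCLC) loop: the
comparator classifies the streaming control-band power against the LFP
threshold(s); onset timers require the commanding region to persist
before stimulation changes; a ramp engine moves stimulation amplitude
linearly between the clinician's lower and upper stimulation limits; and
a post-change blanking window suppresses detection so stimulation
transients cannot drive feedback. Bilateral linking directs one
hemisphere's threshold crossing to both stimulation channels.

Modes
-----
single
    Fast trapezoidal control: power above the single LFP threshold ramps
    stimulation to the upper limit, power below ramps to the lower limit,
    with a default full-range traversal of 250 ms and onset durations of
    200–500 ms (long enough to catch >500 ms beta bursts, short enough to
    reject brief fluctuations).
dual
    Slow incremental control with a hold region: power above the upper
    LFP threshold ramps amplitude up (default 2.5 min full traversal),
    below the lower threshold ramps down (default 5 min), and between the
    thresholds the amplitude holds. Onset durations are 1.2–2 s.

Ramp semantics: ramp times denote full traversal of the stimulation
window [lower, upper]; partial ramps use the same constant slope.
Amplitude is evaluated in continuous time along the ramp line, so
traversal times are exact rather than quantized to the 100 ms detector
cadence. Power exactly equal to a threshold is classified as not-crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import sensing
from .synthetic import (
    HEMISPHERES,
    PatientModel,
    stimulation_suppression_factor,
)
from .sensing import BandPowerSample, BandPowerStream, TimelineBin

__all__ = [
    "ControllerConfig",
    "HemisphereState",
    "ControllerState",
    "SessionTrace",
    "compare",
    "step",
    "link_bilateral",
    "run_closed_loop",
    "run_scripted",
    "CONTROL_DT_S",
]

#: Detector / controller cadence, seconds.
CONTROL_DT_S = 0.1

_DT_MS = CONTROL_DT_S * 1000.0

#: Mode-specific defaults (onset ms; ramp seconds).
SINGLE_ONSET_DEFAULT_MS = 400.0
DUAL_ONSET_DEFAULT_MS = 1600.0  # midpoint of the 1.2-2 s programmable range
SINGLE_RAMP_DEFAULT_S = 0.250
DUAL_RAMP_UP_DEFAULT_S = 150.0  # 2.5 min
DUAL_RAMP_DOWN_DEFAULT_S = 300.0  # 5 min
BLANKING_DEFAULT_MS = 550.0

#: Programmable ranges enforced at validation.
SINGLE_ONSET_RANGE_MS = (200.0, 500.0)
DUAL_ONSET_RANGE_MS = (1200.0, 2000.0)
DUAL_RAMP_RANGE_S = (60.0, 600.0)  # 1-10 min


class ControllerConfig(BaseModel):
    """PCLC set points, limits and timing constants.

    Stimulation limits and the control-band center frequency may be a
    single value shared by both hemispheres or a per-hemisphere mapping.
    ``onset_duration`` and ``blanking_duration`` are in ms; ramp times in
    seconds and denote full traversal of [lower, upper] stimulation.
    """

    mode: Literal["single", "dual"]
    lower_stim_limit: float | dict[str, float] = 0.0  # mA
    upper_stim_limit: float | dict[str, float] = 3.0  # mA
    single_threshold: float | None = None  # µVp
    lower_lfp_threshold: float | None = None  # µVp
    upper_lfp_threshold: float | None = None  # µVp
    onset_duration: float | None = None  # ms
    blanking_duration: float = Field(default=BLANKING_DEFAULT_MS, ge=0)  # ms
    ramp_up_time: float | None = Field(default=None, gt=0)  # s
    ramp_down_time: float | None = Field(default=None, gt=0)  # s
    bilateral_link: bool = True
    control_hemispheres: list[str] = Field(default_factory=lambda: list(HEMISPHERES))
    center_frequency: float | dict[str, float] = 18.0  # Hz
    cdbs_amplitude: float | dict[str, float] | None = None  # mA, non-aDBS hemisphere

    @model_validator(mode="after")
    def _apply_defaults_and_check(self) -> "ControllerConfig":
        if self.onset_duration is None:
            self.onset_duration = (
                SINGLE_ONSET_DEFAULT_MS if self.mode == "single" else DUAL_ONSET_DEFAULT_MS
            )
        if self.ramp_up_time is None:
            self.ramp_up_time = (
                SINGLE_RAMP_DEFAULT_S if self.mode == "single" else DUAL_RAMP_UP_DEFAULT_S
            )
        if self.ramp_down_time is None:
            self.ramp_down_time = (
                SINGLE_RAMP_DEFAULT_S if self.mode == "single" else DUAL_RAMP_DOWN_DEFAULT_S
            )

        if self.mode == "single":
            if self.single_threshold is None:
                raise ValueError("single mode requires single_threshold")
            lo, hi = SINGLE_ONSET_RANGE_MS
            if not (lo <= self.onset_duration <= hi):
                raise ValueError(
                    f"single-mode onset duration must lie in [{lo:.0f}, {hi:.0f}] ms"
                )
        else:
            if self.lower_lfp_threshold is None or self.upper_lfp_threshold is None:
                raise ValueError("dual mode requires lower and upper LFP thresholds")
            if not self.lower_lfp_threshold < self.upper_lfp_threshold:
                raise ValueError("dual mode requires lower_lfp_threshold < upper_lfp_threshold")
            lo, hi = DUAL_ONSET_RANGE_MS
            if not (lo <= self.onset_duration <= hi):
                raise ValueError(
                    f"dual-mode onset duration must lie in [{lo:.0f}, {hi:.0f}] ms"
                )
            rlo, rhi = DUAL_RAMP_RANGE_S
            for name, val in (("ramp_up_time", self.ramp_up_time),
                              ("ramp_down_time", self.ramp_down_time)):
                if not (rlo <= val <= rhi):
                    raise ValueError(
                        f"dual-mode {name} must lie in [{rlo/60:.0f}, {rhi/60:.0f}] min"
                    )

        for hemi in HEMISPHERES:
            lo, hi = self.stim_limits(hemi)
            if not (0 <= lo <= hi):
                raise ValueError(
                    f"stimulation limits for {hemi} must satisfy 0 <= lower <= upper"
                )
        for hemi in self.control_hemispheres:
            if hemi not in HEMISPHERES:
                raise ValueError(f"unknown control hemisphere {hemi!r}")
        return self

    def _per_hemi(self, value, hemisphere: str) -> float:
        if isinstance(value, dict):
            return float(value[hemisphere])
        return float(value)

    def stim_limits(self, hemisphere: str) -> tuple[float, float]:
        return (
            self._per_hemi(self.lower_stim_limit, hemisphere),
            self._per_hemi(self.upper_stim_limit, hemisphere),
        )

    def control_frequency(self, hemisphere: str) -> float:
        return self._per_hemi(self.center_frequency, hemisphere)

    def cdbs_level(self, hemisphere: str) -> float:
        """Constant amplitude for a hemisphere running cDBS (defaults to its
        upper stimulation limit, the chronically therapeutic setting)."""
        if self.cdbs_amplitude is None:
            return self.stim_limits(hemisphere)[1]
        return self._per_hemi(self.cdbs_amplitude, hemisphere)


# ---------------------------------------------------------------------------
# Comparator
# ---------------------------------------------------------------------------

def compare(power: float, config: ControllerConfig) -> str:
    """Classify a band-power sample against the configured threshold(s).

    Single mode returns "above"/"below" the single threshold; dual mode
    returns "above"/"between"/"below". Exact equality with a threshold is
    classified as not-crossed (below for single and the upper bound,
    between for the dual lower bound), mirroring the strict >1.1 µVp
    convention of the signal test.
    """
    if config.mode == "single":
        return "above" if power > config.single_threshold else "below"
    if power > config.upper_lfp_threshold:
        return "above"
    if power < config.lower_lfp_threshold:
        return "below"
    return "between"


# ---------------------------------------------------------------------------
# Controller state
# ---------------------------------------------------------------------------

@dataclass
class HemisphereState:
    """Evolving stimulation state of one hemisphere."""

    hemisphere: str
    current_amplitude: float  # mA
    ramp_target: float  # mA
    ramp_slope: float = 0.0  # mA/s, signed; 0 when idle
    ramp_active: bool = False
    comparator_region: str = "below"
    onset_timer: float = 0.0  # ms
    blanking_timer: float = 0.0  # ms remaining, kept for introspection
    blank_until: float | None = None  # s, end of the detection-suppression window
    time: float | None = None  # last step time, s
    events: list[dict] = dc_field(default_factory=list)

    def _in_blanking(self, now: float) -> bool:
        """Detection is suppressed for exactly blanking_duration after a
        stimulation change: samples with elapsed time in (0, blanking] are
        blanked."""
        if self.blank_until is None:
            return False
        if now <= self.blank_until + 1e-9:
            self.blanking_timer = max(0.0, (self.blank_until - now) * 1000.0)
            return True
        self.blanking_timer = 0.0
        self.blank_until = None
        return False

    def _advance_amplitude(self, dt: float) -> None:
        if not self.ramp_active:
            return
        nxt = self.current_amplitude + self.ramp_slope * dt
        if (self.ramp_slope > 0 and nxt >= self.ramp_target) or (
            self.ramp_slope < 0 and nxt <= self.ramp_target
        ):
            nxt = self.ramp_target
            self.ramp_active = False
            self.ramp_slope = 0.0
        self.current_amplitude = nxt

    def _initiate_ramp(self, target: float, config: ControllerConfig, now: float,
                       trigger: str) -> None:
        lo, hi = config.stim_limits(self.hemisphere)
        target = min(max(target, lo), hi)
        if target == self.current_amplitude and not self.ramp_active:
            return
        going_up = target > self.current_amplitude
        ramp_time = config.ramp_up_time if going_up else config.ramp_down_time
        span = hi - lo
        slope = (span / ramp_time) if span > 0 else 0.0
        self.ramp_slope = slope if going_up else -slope
        self.ramp_target = target
        self.ramp_active = span > 0 and slope > 0
        self.blanking_timer = config.blanking_duration
        self.blank_until = now + config.blanking_duration / 1000.0
        self.onset_timer = 0.0
        self.events.append(
            {
                "time_s": now,
                "hemisphere": self.hemisphere,
                "from_ma": self.current_amplitude,
                "to_ma": target,
                "trigger": trigger,
                "blank_until_s": now + config.blanking_duration / 1000.0,
            }
        )


@dataclass
class ControllerState:
    """Per-hemisphere stimulation states plus the shared event log."""

    hemispheres: dict[str, HemisphereState]

    @classmethod
    def initial(cls, config: ControllerConfig,
                initial_amplitude: float | dict[str, float] | None = None
                ) -> "ControllerState":
        states = {}
        for hemi in HEMISPHERES:
            lo, hi = config.stim_limits(hemi)
            if hemi in config.control_hemispheres or (
                config.mode == "dual" and config.bilateral_link
            ):
                amp = lo
            else:
                amp = config.cdbs_level(hemi)
            if initial_amplitude is not None:
                amp = (
                    float(initial_amplitude[hemi])
                    if isinstance(initial_amplitude, dict)
                    else float(initial_amplitude)
                )
            amp = min(max(amp, lo), hi)
            states[hemi] = HemisphereState(hemi, amp, amp)
        return cls(states)

    @property
    def events(self) -> list[dict]:
        out = [e for st in self.hemispheres.values() for e in st.events]
        out.sort(key=lambda e: e["time_s"])
        return out


def _commanded_target(
    region: str, state: HemisphereState, config: ControllerConfig
) -> float | None:
    lo, hi = config.stim_limits(state.hemisphere)
    if config.mode == "single":
        return hi if region == "above" else lo
    if region == "above":
        return hi
    if region == "below":
        return lo
    return None  # between: hold


def step(
    state: HemisphereState,
    power_sample: BandPowerSample,
    config: ControllerConfig,
) -> HemisphereState:
    """Advance one hemisphere's controller by one 100 ms detector sample.

    Mutates and returns ``state``; marks ``power_sample.blanked`` when the
    sample falls inside the post-change blanking window. Must be called
    at exactly the 100 ms cadence.
    """
    if state.time is not None:
        if abs(power_sample.time - state.time - CONTROL_DT_S) > 1e-6:
            raise ValueError(
                f"controller must be stepped at {CONTROL_DT_S*1000:.0f} ms cadence; "
                f"got {power_sample.time - state.time:.4f} s after previous sample"
            )
    state._advance_amplitude(CONTROL_DT_S)
    now = power_sample.time
    state.time = now

    if state._in_blanking(now):
        power_sample.blanked = True
        return state

    region = compare(power_sample.band_power, config)
    if region != state.comparator_region:
        state.onset_timer = 0.0
        state.comparator_region = region

    if config.mode == "dual" and region == "between" and state.ramp_active:
        # hold region: freeze the amplitude where the ramp has brought it
        state.ramp_active = False
        state.ramp_slope = 0.0
        state.ramp_target = state.current_amplitude

    target = _commanded_target(region, state, config)
    commands_change = (
        target is not None
        and abs(target - state.current_amplitude) > 1e-12
        and not (state.ramp_active and state.ramp_target == target)
    )
    if commands_change:
        state.onset_timer += _DT_MS
        if state.onset_timer >= config.onset_duration:
            state._initiate_ramp(target, config, now, trigger="onset")
    else:
        state.onset_timer = 0.0
    return state


def link_bilateral(
    states: ControllerState,
    trigger_hemisphere: str,
    config: ControllerConfig,
) -> ControllerState:
    """Propagate a threshold crossing in one hemisphere to the other(s).

    The triggering hemisphere's most recent ramp command is issued to
    every other hemisphere simultaneously, each ramping within its own
    stimulation limits. Idempotent when the other hemisphere already
    ramps toward (or sits at) the commanded limit.
    """
    if not config.control_hemispheres:
        raise ValueError("bilateral link requested with zero control hemispheres")
    trig = states.hemispheres[trigger_hemisphere]
    if not trig.events:
        return states
    last = trig.events[-1]
    lo_t, hi_t = config.stim_limits(trigger_hemisphere)
    going_up = last["to_ma"] >= last["from_ma"]
    for hemi, st in states.hemispheres.items():
        if hemi == trigger_hemisphere:
            continue
        lo, hi = config.stim_limits(hemi)
        target = hi if going_up else lo
        already = (not st.ramp_active and st.current_amplitude == target) or (
            st.ramp_active and st.ramp_target == target
        )
        if not already:
            st._initiate_ramp(target, config, last["time_s"], trigger="linked")
    return states


# ---------------------------------------------------------------------------
# Session trace
# ---------------------------------------------------------------------------

@dataclass
class SessionTrace:
    """Time-aligned record of one closed-loop session at 100 ms cadence."""

    times: np.ndarray
    band_power: dict[str, np.ndarray]  # µVp per hemisphere
    region: dict[str, np.ndarray]  # comparator output per hemisphere
    stim: dict[str, np.ndarray]  # mA per hemisphere
    blanked: dict[str, np.ndarray]
    events: list[dict]

    def stream(self, hemisphere: str) -> BandPowerStream:
        return BandPowerStream(
            self.times, self.band_power[hemisphere], self.blanked[hemisphere]
        )

    def timeline(self, hemisphere: str) -> list[TimelineBin]:
        return sensing.timeline_aggregate(
            self.stream(hemisphere), self.stim[hemisphere]
        )

    def to_frame(self):
        import pandas as pd

        cols = {"time_s": self.times}
        for hemi in self.band_power:
            cols[f"band_power_uvp_{hemi}"] = self.band_power[hemi]
            cols[f"region_{hemi}"] = self.region[hemi]
            cols[f"stim_ma_{hemi}"] = self.stim[hemi]
            cols[f"blanked_{hemi}"] = self.blanked[hemi]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Closed-loop co-simulation
# ---------------------------------------------------------------------------

def _amplitude_profile(st: HemisphereState, dt: float, k: int) -> np.ndarray:
    """Per-sample amplitude along the active ramp line over the next block."""
    t_rel = (np.arange(k) + 1) * dt
    if not st.ramp_active or st.ramp_slope == 0.0:
        return np.full(k, st.current_amplitude)
    a = st.current_amplitude + st.ramp_slope * t_rel
    if st.ramp_slope > 0:
        return np.minimum(a, st.ramp_target)
    return np.maximum(a, st.ramp_target)


def run_closed_loop(
    model: PatientModel,
    config: ControllerConfig,
    duration: float,
    seed: int | np.random.SeedSequence = 0,
    initial_amplitude: float | dict[str, float] | None = None,
    med_override: float | None = None,
    start_time: float = 0.0,
) -> SessionTrace:
    """Co-simulate LFP generation, sensing and the aDBS controller.

    The synthetic beta amplitude responds to the evolving stimulation
    through the suppression sigmoid, closing the loop. Fully reproducible
    from ``seed``. The controller idles during the first 500 ms while the
    streaming analysis window fills.
    """
    if duration < 1.0:
        raise ValueError("closed-loop runs require duration >= 1 s")
    fs = model.sample_rate
    hop = fs * CONTROL_DT_S
    win = fs * sensing.STREAM_WINDOW_S
    if abs(hop - round(hop)) > 1e-9 or abs(win - round(win)) > 1e-9:
        raise ValueError(
            f"model sample rate {fs} Hz does not tile the {CONTROL_DT_S*1000:.0f} ms "
            "control cadence"
        )
    hop, win = int(round(hop)), int(round(win))
    n = int(round(duration * fs))
    n_blocks = n // hop

    from .synthetic import lfp_components  # late import to avoid cycle at module load

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    hemi_seeds = dict(zip(HEMISPHERES, ss.spawn(len(HEMISPHERES))))

    comps = {
        hemi: lfp_components(
            model, hemi, duration, hemi_seeds[hemi], start_time, med_override
        )
        for hemi in HEMISPHERES
    }
    states = ControllerState.initial(config, initial_amplitude)

    times = []
    rec: dict[str, list] = {
        hemi: {"bp": [], "region": [], "stim": [], "blanked": []} for hemi in HEMISPHERES
    }
    buffers = {hemi: np.zeros(0) for hemi in HEMISPHERES}
    warm_blocks = win // hop

    for b in range(n_blocks):
        t_block_end = start_time + (b + 1) * CONTROL_DT_S
        # synthesize this 100 ms of LFP under the current ramp line
        for hemi in HEMISPHERES:
            st = states.hemispheres[hemi]
            bg, osc = comps[hemi]
            sl = slice(b * hop, (b + 1) * hop)
            amps = _amplitude_profile(st, 1.0 / fs, hop)
            factor = np.asarray(
                stimulation_suppression_factor(amps, model.hemisphere(hemi).modulation)
            )
            block = bg[sl] + factor * osc[sl]
            buffers[hemi] = np.concatenate([buffers[hemi], block])[-win:]

        if b + 1 < warm_blocks:
            continue

        times.append(t_block_end)
        triggered = []
        for hemi in HEMISPHERES:
            st = states.hemispheres[hemi]
            bp = sensing._window_band_amplitude(
                buffers[hemi], fs, config.control_frequency(hemi)
            )
            sample = BandPowerSample(time=t_block_end, band_power=bp)
            if hemi in config.control_hemispheres:
                n_events = len(st.events)
                step(st, sample, config)
                if len(st.events) > n_events:
                    triggered.append(hemi)
            else:
                # non-detector hemisphere: amplitude still follows its own
                # ramp line (it may receive linked commands)
                st._advance_amplitude(CONTROL_DT_S)
                if st._in_blanking(t_block_end):
                    sample.blanked = True
                st.time = t_block_end
            rec[hemi]["bp"].append(sample.band_power)
            rec[hemi]["region"].append(compare(sample.band_power, config))
            rec[hemi]["blanked"].append(sample.blanked)
            rec[hemi]["stim"].append(st.current_amplitude)

        if config.bilateral_link or (
            config.mode == "dual" and len(config.control_hemispheres) == 1
        ):
            for hemi in triggered:
                link_bilateral(states, hemi, config)
                # reflect the linked command in this step's recorded amplitude
                for other in HEMISPHERES:
                    rec[other]["stim"][-1] = states.hemispheres[other].current_amplitude

    times_arr = np.asarray(times)
    return SessionTrace(
        times=times_arr,
        band_power={h: np.asarray(rec[h]["bp"]) for h in HEMISPHERES},
        region={h: np.asarray(rec[h]["region"], dtype=object) for h in HEMISPHERES},
        stim={h: np.asarray(rec[h]["stim"]) for h in HEMISPHERES},
        blanked={h: np.asarray(rec[h]["blanked"], dtype=bool) for h in HEMISPHERES},
        events=states.events,
    )


def run_scripted(
    power: np.ndarray | Callable[[float], float],
    config: ControllerConfig,
    duration: float,
    hemisphere: str = "left",
    initial_amplitude: float | None = None,
) -> SessionTrace:
    """Drive the controller with a scripted band-power sequence.

    Bypasses LFP synthesis: ``power`` gives the control-band amplitude
    (µVp) directly, either as an array at 100 ms cadence or a function of
    time. Used for ramp-time verification and controller unit tests.
    """
    n_steps = int(round(duration / CONTROL_DT_S))
    if callable(power):
        seq = np.array([power((k + 1) * CONTROL_DT_S) for k in range(n_steps)])
    else:
        seq = np.asarray(power, dtype=float)
        if len(seq) < n_steps:
            raise ValueError("scripted power sequence shorter than duration")
        seq = seq[:n_steps]

    states = ControllerState.initial(config, initial_amplitude)
    st = states.hemispheres[hemisphere]
    other = [h for h in HEMISPHERES if h != hemisphere][0]
    other_st = states.hemispheres[other]
    times, bps, regions, stims, blanked, other_stims = [], [], [], [], [], []
    for k in range(n_steps):
        t = (k + 1) * CONTROL_DT_S
        sample = BandPowerSample(time=t, band_power=float(seq[k]))
        n_events = len(st.events)
        other_st._advance_amplitude(CONTROL_DT_S)
        step(st, sample, config)
        if len(st.events) > n_events and config.bilateral_link:
            link_bilateral(states, hemisphere, config)
        times.append(t)
        bps.append(sample.band_power)
        regions.append(compare(sample.band_power, config))
        stims.append(st.current_amplitude)
        blanked.append(sample.blanked)
        other_stims.append(other_st.current_amplitude)

    other_stim = np.asarray(other_stims)
    zeros = np.zeros(n_steps)
    return SessionTrace(
        times=np.asarray(times),
        band_power={hemisphere: np.asarray(bps), other: zeros},
        region={
            hemisphere: np.asarray(regions, dtype=object),
            other: np.asarray(["below"] * n_steps, dtype=object),
        },
        stim={hemisphere: np.asarray(stims), other: other_stim},
        blanked={
            hemisphere: np.asarray(blanked, dtype=bool),
            other: np.zeros(n_steps, dtype=bool),
        },
        events=states.events,
    )
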