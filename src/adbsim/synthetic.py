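"""Synthetic basal-ganglia LFP generation.

Produces local field potential time series with the statistical structure
that LFP-guided adaptive-DBS sensing and control algorithms assume: a 1/f
aperiodic background, narrowband oscillatory peaks in the alpha-beta range,
beta bursts, medication / stimulation / circadian amplitude modulation, and
ECG / movement artifacts. Every modulation source is independently
switchable so tests can isolate one mechanism at a time.

Oscillations are synthesized as narrowband Gaussian noise (band-pass
filtered white noise) rather than pure tones: basal-ganglia beta is
stochastic and bursty, and a filtered-noise process reproduces that
character while remaining amplitude-calibratable. Amplitudes are
calibrated in "µVp" — the spectral-peak amplitude a Welch estimator with a
1 s Hann window reports — matching the convention used by sensing
hardware that reports peak amplitudes in microvolts-peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import signal

__all__ = [
    "OscillatoryPeak",
    "SpectralProfile",
    "BurstParams",
    "ModulationParams",
    "MedicationSchedule",
    "ArtifactParams",
    "HemisphereModel",
    "PatientModel",
    "LfpRecording",
    "medication_effect",
    "stimulation_suppression_factor",
    "circadian_factor",
    "lfp_components",
    "generate_lfp",
    "inject_artifacts",
    "HEMISPHERES",
]

#: Default device sampling rate, Hz.
DEFAULT_SAMPLE_RATE = 250.0

#: Canonical hemisphere labels.
HEMISPHERES = ("left", "right")

#: Hann equivalent-noise-bandwidth factor (in bins) used for amplitude
#: calibration; must match the sensing module's spectral convention.
_HANN_ENBW_BINS = 1.5

#: Welch analysis window used to define the µVp calibration (seconds).
_CALIBRATION_WINDOW_S = 1.0

#: Raised-cosine edge applied to burst envelopes, seconds.
_BURST_EDGE_S = 0.010

#: Filter warm-up discarded before each narrowband realization (samples).
_FILTER_WARMUP = 2500


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class OscillatoryPeak(BaseModel):
    """One narrowband oscillatory source (e.g. a beta peak).

    ``base_amplitude`` is the spectral-peak amplitude in µVp of the
    unsuppressed rhythm; ``bandwidth`` is the full spectral width (Hz) of
    the generated narrowband process.
    """

    center_frequency: float = Field(gt=0, lt=125)
    base_amplitude: float = Field(ge=0)
    bandwidth: float = Field(default=3.0, gt=0)


class SpectralProfile(BaseModel):
    """Aperiodic 1/f background plus a list of oscillatory peaks.

    The aperiodic component has one-sided PSD ``10**aperiodic_offset /
    f**aperiodic_exponent`` in µV²/Hz; ``broadband_noise_floor`` is the RMS
    (µV) of an additional white measurement-noise floor.
    """

    aperiodic_offset: float = -1.5
    aperiodic_exponent: float = Field(default=1.0, ge=0)
    peaks: list[OscillatoryPeak] = Field(default_factory=list)
    broadband_noise_floor: float = Field(default=0.05, ge=0)


class BurstParams(BaseModel):
    """Beta-burst statistics: Poisson onsets, gamma-distributed durations.

    ``burst_duration_dispersion`` is the coefficient of variation of the
    duration distribution (gamma shape = 1/cv², scale = mean·cv²), so any
    positive dispersion gives a right tail that produces bursts > 500 ms
    when the mean is in the physiological few-hundred-ms range.
    ``burst_gain`` multiplies oscillatory amplitude during a burst.
    """

    burst_rate: float = Field(default=0.0, ge=0)
    mean_burst_duration: float = Field(default=400.0, ge=0)  # ms
    burst_duration_dispersion: float = Field(default=0.5, ge=0)
    burst_gain: float = Field(default=2.0, ge=0)


class ModulationParams(BaseModel):
    """Slow amplitude modulation of the oscillatory sources.

    * medication: amplitude × (1 − med_suppression_fraction · effect(t))
    * stimulation: amplitude × (1 − stim_suppression_fraction ·
      sigmoid((A − A₅₀)/slope)), slope defaulting to A₅₀/4
    * circadian: amplitude × (1 + circadian_fraction ·
      cos(2π (hour − acrophase)/24)); acrophase is the hour of maximum.

    Factors compose multiplicatively. Magnitudes of medication and
    stimulation suppression are placeholders chosen for plausibility —
    no quantitative in-cohort values exist for them; see the config docs.
    """

    med_suppression_fraction: float = Field(default=0.0, ge=0, le=1)
    stim_suppression_fraction: float = Field(default=0.0, ge=0, le=1)
    stim_half_suppression_amplitude: float = Field(default=1.5, gt=0)  # mA
    stim_sigmoid_slope: float | None = Field(default=None, gt=0)  # mA; None -> A50/4
    circadian_fraction: float = Field(default=0.0, ge=0, le=1)
    acrophase: float = Field(default=15.0, ge=0, lt=24)  # hour of day of maximum


class MedicationSchedule(BaseModel):
    """Levodopa dosing times with bi-exponential wash-in/wash-out."""

    dose_times: list[float] = Field(default_factory=list)  # hours of day
    washin_tau: float = Field(default=20.0, gt=0)  # min
    washout_tau: float = Field(default=90.0, gt=0)  # min


class ArtifactParams(BaseModel):
    """ECG and movement artifact settings (amplitudes in µV)."""

    ecg_enabled: bool = False
    ecg_rate: float = Field(default=70.0, ge=0)  # bpm
    ecg_amplitude: float = Field(default=0.0, ge=0)
    movement_rate: float = Field(default=0.0, ge=0)  # events/h
    movement_amplitude: float = Field(default=0.0, ge=0)


class HemisphereModel(BaseModel):
    """Generative description of one hemisphere's LFP."""

    spectral_profile: SpectralProfile = Field(default_factory=SpectralProfile)
    bursts: BurstParams = Field(default_factory=BurstParams)
    modulation: ModulationParams = Field(default_factory=ModulationParams)
    artifacts: ArtifactParams = Field(default_factory=ArtifactParams)


class PatientModel(BaseModel):
    """A simulated patient: exactly two hemispheres plus shared dosing."""

    hemispheres: dict[str, HemisphereModel]
    medication: MedicationSchedule = Field(default_factory=MedicationSchedule)
    sample_rate: float = Field(default=DEFAULT_SAMPLE_RATE, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "PatientModel":
        if set(self.hemispheres) != set(HEMISPHERES):
            raise ValueError(
                f"hemispheres must be exactly {set(HEMISPHERES)}, "
                f"got {set(self.hemispheres)}"
            )
        for label, hemi in self.hemispheres.items():
            for pk in hemi.spectral_profile.peaks:
                if self.sample_rate <= 2 * pk.center_frequency:
                    raise ValueError(
                        f"sample_rate {self.sample_rate} Hz cannot represent "
                        f"{pk.center_frequency} Hz peak in {label} hemisphere"
                    )
        return self

    def hemisphere(self, label: str) -> HemisphereModel:
        if label not in self.hemispheres:
            raise KeyError(f"unknown hemisphere {label!r}; expected one of {HEMISPHERES}")
        return self.hemispheres[label]


@dataclass
class LfpRecording:
    """A sampled LFP time series (µV) for one sensing channel."""

    channel_id: str
    hemisphere: str
    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0  # seconds since session start

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must all be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sample_rate

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "lfp_uv": self.samples})


# ---------------------------------------------------------------------------
# Modulation primitives
# ---------------------------------------------------------------------------

def _dose_response(dt_min: np.ndarray, washin: float, washout: float) -> np.ndarray:
    """Unit-peak bi-exponential effect of a single dose, dt in minutes."""
    dt = np.maximum(dt_min, 0.0)
    active = dt_min >= 0
    if math.isclose(washin, washout, rel_tol=1e-9):
        tau = washin
        curve = (dt / tau) * np.exp(1.0 - dt / tau)
    else:
        raw = np.exp(-dt / washout) - np.exp(-dt / washin)
        # peak time of the bi-exponential, where d/dt = 0
        tpk = (math.log(washout) - math.log(washin)) / (1 / washin - 1 / washout)
        peak = math.exp(-tpk / washout) - math.exp(-tpk / washin)
        curve = raw / peak
    return np.where(active, curve, 0.0)


def medication_effect(schedule: MedicationSchedule, t: float | np.ndarray) -> float | np.ndarray:
    """Medication effect level in [0, 1] at time ``t`` (hours).

    Each dose contributes a unit-peak bi-exponential wash-in/wash-out
    curve; doses are additive and the total is clipped at 1. Zero before
    the first dose; decays toward zero after the last.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 hours")
    total = np.zeros_like(t_arr)
    for dose in schedule.dose_times:
        total += _dose_response(
            (t_arr - dose) * 60.0, schedule.washin_tau, schedule.washout_tau
        )
    out = np.clip(total, 0.0, 1.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def stimulation_suppression_factor(
    amplitude_ma: float | np.ndarray, mod: ModulationParams
) -> float | np.ndarray:
    """Multiplicative beta-amplitude factor for a stimulation amplitude (mA).

    1 − f · sigmoid((A − A₅₀)/slope): a saturating dose-response anchored
    by the half-suppression amplitude A₅₀, slope defaulting to A₅₀/4.
    """
    if mod.stim_suppression_fraction == 0:
        return np.ones_like(np.asarray(amplitude_ma, dtype=float)) if not np.isscalar(
            amplitude_ma
        ) else 1.0
    a50 = mod.stim_half_suppression_amplitude
    slope = mod.stim_sigmoid_slope if mod.stim_sigmoid_slope is not None else a50 / 4.0
    x = (np.asarray(amplitude_ma, dtype=float) - a50) / slope
    factor = 1.0 - mod.stim_suppression_fraction / (1.0 + np.exp(-x))
    return float(factor) if np.isscalar(amplitude_ma) else factor


def circadian_factor(hour: float | np.ndarray, mod: ModulationParams) -> float | np.ndarray:
    """24 h sinusoidal amplitude factor; maximum at ``acrophase`` hours."""
    h = np.asarray(hour, dtype=float)
    factor = 1.0 + mod.circadian_fraction * np.cos(2 * np.pi * (h - mod.acrophase) / 24.0)
    return float(factor) if np.isscalar(hour) else factor


# ---------------------------------------------------------------------------
# Narrowband oscillation synthesis & calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _narrowband_scale(
    center_frequency: float, bandwidth: float, sample_rate: float
) -> float:
    """RMS (µV) a unit-µVp narrowband process must have.

    Computes the expected Welch-peak PSD of the unit-variance band-pass
    shape — including smoothing by the 1 s Hann analysis window — then
    inverts amplitude = √(2 · PSD_peak · ENBW) for the process variance
    giving a 1 µVp spectral peak. Scaling is linear in target amplitude.
    """
    lo = max(center_frequency - bandwidth / 2, 0.01)
    hi = min(center_frequency + bandwidth / 2, sample_rate / 2 * 0.999)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    f = np.linspace(0.0, sample_rate / 2, 20001)
    _, h = signal.sosfreqz(sos, worN=f, fs=sample_rate)
    shape = np.abs(h) ** 2
    shape /= np.trapezoid(shape, f)  # unit-variance one-sided PSD

    nwin = int(round(_CALIBRATION_WINDOW_S * sample_rate))
    w = signal.get_window("hann", nwin)
    nfft = 1 << 16
    wk = np.abs(np.fft.rfft(w, nfft)) ** 2
    fk = np.fft.rfftfreq(nfft, 1.0 / sample_rate)
    kf = np.concatenate([-fk[:0:-1], fk])
    kv = np.concatenate([wk[:0:-1], wk])
    kv /= np.trapezoid(kv, kf)  # unit-area smoothing kernel

    probe = np.linspace(center_frequency - 3.0, center_frequency + 3.0, 121)
    smoothed = [
        np.trapezoid(np.interp(fq - kf, f, shape, left=0.0, right=0.0) * kv, kf)
        for fq in probe
    ]
    peak_psd_per_var = max(smoothed)
    enbw_hz = _HANN_ENBW_BINS * sample_rate / nwin
    variance = 1.0 / (2.0 * peak_psd_per_var * enbw_hz)
    return math.sqrt(variance)


def _narrowband_process(
    rng: np.random.Generator,
    n: int,
    center_frequency: float,
    bandwidth: float,
    sample_rate: float,
) -> np.ndarray:
    """Unit-µVp narrowband Gaussian realization of length ``n``."""
    lo = max(center_frequency - bandwidth / 2, 0.01)
    hi = min(center_frequency + bandwidth / 2, sample_rate / 2 * 0.999)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    white = rng.standard_normal(n + _FILTER_WARMUP)
    x = signal.sosfilt(sos, white)[_FILTER_WARMUP:]
    std = x.std()
    if std > 0:
        x = x / std
    return x * _narrowband_scale(center_frequency, bandwidth, sample_rate)


def _aperiodic_background(
    rng: np.random.Generator, n: int, profile: SpectralProfile, sample_rate: float
) -> np.ndarray:
    """1/f-shaped Gaussian background with PSD 10^offset / f^exponent (µV²/Hz)."""
    if profile.aperiodic_offset == -np.inf:
        return np.zeros(n)
    nfft = int(2 ** math.ceil(math.log2(max(n, 2))))
    f = np.fft.rfftfreq(nfft, 1.0 / sample_rate)
    psd = np.zeros_like(f)
    fpos = f[1:]
    psd[1:] = 10.0 ** profile.aperiodic_offset / fpos**profile.aperiodic_exponent
    # frequency-domain coloring of white noise; one-sided PSD convention
    spec = (rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))) / math.sqrt(2)
    spec *= np.sqrt(psd * sample_rate * nfft / 2.0)
    spec[0] = 0.0
    if nfft % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, nfft) / math.sqrt(nfft)
    return x[:n] * math.sqrt(2.0)


def _burst_envelope(
    rng: np.random.Generator,
    n: int,
    params: BurstParams,
    sample_rate: float,
) -> np.ndarray:
    """Multiplicative burst envelope: 1 outside bursts, burst_gain inside.

    Onsets are Poisson; durations gamma-distributed; overlapping bursts
    are merged by taking the pointwise maximum. Raised-cosine 10 ms
    edges avoid spectral splatter.
    """
    env = np.ones(n)
    if params.burst_rate <= 0 or params.burst_gain == 1.0:
        return env
    duration_s = n / sample_rate
    n_bursts = rng.poisson(params.burst_rate * duration_s)
    if n_bursts == 0:
        return env
    onsets = rng.uniform(0.0, duration_s, size=n_bursts)
    durations = _sample_burst_durations(rng, n_bursts, params) / 1000.0  # s
    bump = np.zeros(n)
    edge = int(round(_BURST_EDGE_S * sample_rate))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, max(edge, 2))))
    for t0, dur in zip(onsets, durations):
        i0 = int(t0 * sample_rate)
        i1 = min(int((t0 + dur) * sample_rate), n)
        if i1 <= i0:
            continue
        b = np.ones(i1 - i0)
        k = min(edge, len(b))
        b[:k] = np.minimum(b[:k], ramp[:k])
        b[-k:] = np.minimum(b[-k:], ramp[:k][::-1])
        bump[i0:i1] = np.maximum(bump[i0:i1], b)
    return 1.0 + (params.burst_gain - 1.0) * bump


def _sample_burst_durations(
    rng: np.random.Generator, size: int, params: BurstParams
) -> np.ndarray:
    """Burst durations (ms): gamma with mean and CV = dispersion."""
    mean = params.mean_burst_duration
    cv = params.burst_duration_dispersion
    if cv <= 0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return rng.gamma(shape, scale, size=size)


# ---------------------------------------------------------------------------
# LFP generation
# ---------------------------------------------------------------------------

def lfp_components(
    model: PatientModel,
    hemisphere: str,
    duration: float,
    seed: int | np.random.SeedSequence = 0,
    start_time: float = 0.0,
    med_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulation-independent decomposition of one hemisphere's LFP.

    Returns ``(background, oscillation)`` arrays such that the full signal
    under a stimulation amplitude trace A(t) is
    ``background + stimulation_suppression_factor(A) * oscillation``.
    ``background`` holds the aperiodic 1/f component, the white noise
    floor, and any artifacts; ``oscillation`` holds the summed narrowband
    peaks already scaled by the burst, medication and circadian envelopes.
    Used directly by the closed-loop co-simulation, where A(t) is only
    known at run time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    hemi = model.hemisphere(hemisphere)
    fs = model.sample_rate
    n = int(round(duration * fs))
    times = start_time + np.arange(n) / fs

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # stable per-purpose substreams: background, bursts, artifacts, each peak
    kids = ss.spawn(3 + len(hemi.spectral_profile.peaks))
    rng_bg = np.random.default_rng(kids[0])
    rng_burst = np.random.default_rng(kids[1])
    rng_art = np.random.default_rng(kids[2])

    bg = _aperiodic_background(rng_bg, n, hemi.spectral_profile, fs)
    if hemi.spectral_profile.broadband_noise_floor > 0:
        bg = bg + hemi.spectral_profile.broadband_noise_floor * rng_bg.standard_normal(n)

    mod = hemi.modulation
    hours = times / 3600.0
    if med_override is not None:
        med = np.full(n, float(med_override))
    else:
        med = np.asarray(medication_effect(model.medication, hours))
    envelope = (
        (1.0 - mod.med_suppression_fraction * med)
        * np.asarray(circadian_factor(hours, mod))
        * _burst_envelope(rng_burst, n, hemi.bursts, fs)
    )

    osc = np.zeros(n)
    for pk, kid in zip(hemi.spectral_profile.peaks, kids[3:]):
        rng_pk = np.random.default_rng(kid)
        unit = _narrowband_process(rng_pk, n, pk.center_frequency, pk.bandwidth, fs)
        osc = osc + pk.base_amplitude * envelope * unit

    art = hemi.artifacts
    if (art.ecg_enabled and art.ecg_amplitude > 0) or (
        art.movement_rate > 0 and art.movement_amplitude > 0
    ):
        carrier = LfpRecording("tmp", hemisphere, fs, np.zeros(n), start_time)
        bg = bg + inject_artifacts(carrier, art, rng_art).samples
    return bg, osc


def generate_lfp(
    model: PatientModel,
    hemisphere: str,
    duration: float,
    stim_trace: float | np.ndarray = 0.0,
    seed: int | np.random.SeedSequence = 0,
    start_time: float = 0.0,
    med_override: float | None = None,
    channel_id: str | None = None,
) -> LfpRecording:
    """Generate one hemisphere's LFP recording (µV at ``model.sample_rate``).

    Parameters
    ----------
    stim_trace
        Constant stimulation amplitude (mA) or a per-sample array at the
        recording sample rate; must cover the full duration.
    seed
        Reproducibility seed; identical seed + inputs give identical samples.
    start_time
        Session-clock offset (s); drives circadian and medication phase.
    med_override
        Force the medication effect level (0 = off-meds, 1 = full effect)
        instead of evaluating the schedule — used by programming steps
        performed at a prescribed medication state.
    """
    hemi = model.hemisphere(hemisphere)
    fs = model.sample_rate
    n = int(round(duration * fs))
    if np.isscalar(stim_trace):
        stim = np.full(n, float(stim_trace))
    else:
        stim = np.asarray(stim_trace, dtype=float)
        if len(stim) < n:
            raise ValueError(
                f"stim_trace covers {len(stim)} samples but {n} are required"
            )
        stim = stim[:n]

    bg, osc = lfp_components(model, hemisphere, duration, seed, start_time, med_override)
    x = bg + np.asarray(stimulation_suppression_factor(stim, hemi.modulation)) * osc
    return LfpRecording(
        channel_id=channel_id or f"{hemisphere}_ring",
        hemisphere=hemisphere,
        sample_rate=fs,
        samples=x,
        start_time=start_time,
    )


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def _ecg_template(sample_rate: float) -> np.ndarray:
    """Triangular QRS-like unit-amplitude template, ~80 ms wide."""
    half = max(int(round(0.040 * sample_rate)), 1)
    up = np.linspace(0.0, 1.0, half, endpoint=False)
    down = np.linspace(1.0, 0.0, half + 1)
    return np.concatenate([up, down])


def inject_artifacts(
    recording: LfpRecording,
    params: ArtifactParams,
    seed: int | np.random.Generator = 0,
) -> LfpRecording:
    """Return a copy of ``recording`` with additive ECG/movement artifacts.

    ECG: a periodic triangular QRS-like template at ``ecg_rate`` bpm with
    ±5% beat-interval jitter. Movement: Poisson-timed 300 ms broadband
    transients. With both amplitudes zero the output equals the input
    sample-for-sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = recording.samples.copy()
    fs = recording.sample_rate
    n = len(x)

    if params.ecg_enabled and params.ecg_amplitude > 0 and params.ecg_rate > 0:
        template = _ecg_template(fs) * params.ecg_amplitude
        beat = 60.0 / params.ecg_rate
        t = rng.uniform(0.0, beat)
        while t < n / fs:
            i0 = int(round(t * fs))
            seg = template[: max(n - i0, 0)]
            x[i0 : i0 + len(seg)] += seg
            t += beat * (1.0 + rng.uniform(-0.05, 0.05))

    if params.movement_rate > 0 and params.movement_amplitude > 0:
        duration_h = n / fs / 3600.0
        n_events = rng.poisson(params.movement_rate * duration_h)
        width = int(round(0.300 * fs))
        env = np.hanning(width)
        for t0 in rng.uniform(0.0, n / fs, size=n_events):
            i0 = int(round(t0 * fs))
            seg = (env * rng.standard_normal(width) * params.movement_amplitude)[
                : max(n - i0, 0)
            ]
            x[i0 : i0 + len(seg)] += seg

    return LfpRecording(
        channel_id=recording.channel_id,
        hemisphere=recording.hemisphere,
        sample_rate=fs,
        samples=x,
        start_time=recording.start_time,
    )
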