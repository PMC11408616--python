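"""Device sensing-chain emulation.

Implements the spectral features a sensing-enabled DBS neurostimulator
exposes to the clinician: 30 s amplitude-calibrated power spectra (0–100
Hz), a signal test that reports the largest spectral peak above 1.1 µVp,
an offline automated peak detector working against a fitted 1/f
background, a streaming 5 Hz-wide band-power estimate updated every 100
ms, 10-minute timeline averaging with a 60-day capacity, patient-triggered
event capture (up to four labels), and ECG/movement artifact flagging.

Spectral convention: amplitudes are reported in µVp via
``sqrt(2 · PSD · ENBW)`` so a pure sinusoid of amplitude A µV yields a
spectral peak of A µVp. The 30 s PSD uses Welch with 1 s Hann windows at
50% overlap (~1 Hz resolution); the stream uses a 500 ms window advanced
by 100 ms — a 100 ms rectangular FFT cannot resolve a 5 Hz band at beta
frequencies, so the window length is this package's documented choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy import stats as sstats

from .synthetic import LfpRecording

__all__ = [
    "PowerSpectrum",
    "PeakReport",
    "BandPowerSample",
    "BandPowerStream",
    "TimelineBin",
    "compute_psd",
    "fit_aperiodic_background",
    "signal_test",
    "automated_peak_detect",
    "band_power_stream",
    "timeline_aggregate",
    "EventCaptureSession",
    "detect_artifacts",
    "band_label",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
    "SIGNAL_TEST_MIN_UVP",
    "STREAM_STEP_S",
    "STREAM_WINDOW_S",
    "CONTROL_BAND_HALF_WIDTH_HZ",
    "TIMELINE_BIN_S",
    "TIMELINE_CAPACITY_BINS",
]

#: Signal-test detection floor, µVp (strict inequality).
SIGNAL_TEST_MIN_UVP = 1.1

#: Streaming band-power cadence (s) and analysis-window length (s).
STREAM_STEP_S = 0.1
STREAM_WINDOW_S = 0.5

#: The control band is 5 Hz wide around the chosen peak.
CONTROL_BAND_HALF_WIDTH_HZ = 2.5

#: Timeline storage: 10 min bins, up to 60 days.
TIMELINE_BIN_S = 600.0
TIMELINE_CAPACITY_BINS = 60 * 144

#: Epoch length (s) for survey / signal-test / event spectra.
PSD_EPOCH_S = 30.0

#: Welch settings for the 30 s PSD.
_PSD_WINDOW_S = 1.0
_PSD_OVERLAP = 0.5
_HANN_ENBW_BINS = 1.5

#: Aperiodic background fit range (Hz) and default peak prominence (µVp).
APERIODIC_FIT_RANGE_HZ = (4.0, 45.0)
PEAK_PROMINENCE_UVP = 0.3

#: Frequency windows: signal test searches alpha/beta/gamma; the
#: automated detector is restricted to the alpha-beta control range.
SIGNAL_TEST_RANGE_HZ = (8.0, 100.0)
CONTROL_RANGE_HZ = (8.0, 30.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PowerSpectrum:
    """Amplitude-calibrated spectrum on a uniform 0–100 Hz grid."""

    frequencies: np.ndarray  # Hz
    amplitudes: np.ndarray  # µVp per bin
    resolution: float  # Hz
    channel: str
    epoch_duration: float  # s

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("spectrum amplitudes must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "resolution_hz": self.resolution,
            "epoch_duration_s": self.epoch_duration,
            "frequencies_hz": self.frequencies.tolist(),
            "amplitudes_uvp": self.amplitudes.tolist(),
        }


@dataclass
class PeakReport:
    """A detected (or absent) spectral peak on one channel."""

    channel: str
    center_frequency: float | None
    amplitude: float | None
    band: str  # alpha | low-beta | high-beta | other | none
    detected: bool

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "center_frequency_hz": self.center_frequency,
            "amplitude_uvp": self.amplitude,
            "band": self.band,
            "detected": self.detected,
        }


@dataclass
class BandPowerSample:
    """One 100 ms control-band amplitude sample (µVp)."""

    time: float  # s, end of the analysis window
    band_power: float  # µVp
    blanked: bool = False


class BandPowerStream:
    """Array-backed sequence of :class:`BandPowerSample` at 100 ms cadence."""

    def __init__(
        self,
        times: np.ndarray,
        band_power: np.ndarray,
        blanked: np.ndarray | None = None,
    ):
        self.times = np.asarray(times, dtype=float)
        self.band_power = np.asarray(band_power, dtype=float)
        if np.any(self.band_power < 0):
            raise ValueError("band power must be non-negative")
        self.blanked = (
            np.zeros(len(self.times), dtype=bool)
            if blanked is None
            else np.asarray(blanked, dtype=bool)
        )

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> BandPowerSample:
        return BandPowerSample(
            float(self.times[i]), float(self.band_power[i]), bool(self.blanked[i])
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "band_power_uvp": self.band_power,
                "blanked": self.blanked,
            }
        )


@dataclass
class TimelineBin:
    """One 10-minute timeline bin of unblanked band-power samples."""

    start_time: float  # s
    mean_band_power: float  # µVp
    mean_stim_amplitude: float  # mA (nan if no stim trace supplied)
    sample_count: int


# ---------------------------------------------------------------------------
# 30 s power spectra
# ---------------------------------------------------------------------------

def _amplitude_spectrum(
    x: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Welch PSD → µVp amplitude spectrum on the full 0–Nyquist grid."""
    nperseg = int(round(_PSD_WINDOW_S * fs))
    f, pxx = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * _PSD_OVERLAP),
        detrend="constant",
    )
    enbw_hz = _HANN_ENBW_BINS * fs / nperseg
    amp = np.sqrt(2.0 * pxx * enbw_hz)
    return f, amp, f[1] - f[0]


def compute_psd(recording: LfpRecording, epoch: float = PSD_EPOCH_S) -> PowerSpectrum:
    """Amplitude-calibrated spectrum of the first ``epoch`` seconds.

    A pure sinusoid of amplitude A µV yields a peak bin of ≈ A µVp. The
    reported grid covers 0–100 Hz.
    """
    if recording.duration < epoch:
        raise ValueError(
            f"recording of {recording.duration:.1f} s is shorter than the "
            f"{epoch:.0f} s epoch"
        )
    n = int(round(epoch * recording.sample_rate))
    f, amp, df = _amplitude_spectrum(recording.samples[:n], recording.sample_rate)
    keep = f <= 100.0
    return PowerSpectrum(
        frequencies=f[keep],
        amplitudes=amp[keep],
        resolution=df,
        channel=recording.channel_id,
        epoch_duration=epoch,
    )


# ---------------------------------------------------------------------------
# Aperiodic background & peak detection
# ---------------------------------------------------------------------------

def fit_aperiodic_background(spectrum: PowerSpectrum) -> np.ndarray:
    """Robust 1/f background estimate (µVp) over the spectrum's grid.

    Straight-line fit in log-frequency / log-power over 4–45 Hz using a
    Siegel repeated-median slope, followed by one re-fit with
    above-the-line points (candidate peak regions) masked out.
    """
    f = spectrum.frequencies
    power = spectrum.amplitudes**2
    lo, hi = APERIODIC_FIT_RANGE_HZ
    sel = (f >= lo) & (f <= hi) & (power > 0)
    if sel.sum() < 4:
        return np.zeros_like(f)
    lx, ly = np.log10(f[sel]), np.log10(power[sel])
    slope, intercept = sstats.siegelslopes(ly, lx)
    resid = ly - (intercept + slope * lx)
    keep = resid <= np.median(resid) + 1.0 * resid.std(ddof=0)
    if keep.sum() >= 4:
        slope, intercept = sstats.siegelslopes(ly[keep], lx[keep])
    with np.errstate(divide="ignore"):
        logf = np.where(f > 0, np.log10(np.maximum(f, 1e-12)), np.nan)
    bg_power = np.where(f > 0, 10.0 ** (intercept + slope * logf), 0.0)
    return np.sqrt(bg_power)


def band_label(frequency: float) -> str:
    """Coarse band label for peak reports: alpha/low-beta/high-beta/other."""
    if 8.0 <= frequency < 13.0:
        return "alpha"
    if 13.0 <= frequency < 21.0:
        return "low-beta"
    if 21.0 <= frequency <= 30.0:
        return "high-beta"
    return "other"


def _local_maxima(
    spectrum: PowerSpectrum, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and amplitudes of local maxima within [fmin, fmax]."""
    amp = spectrum.amplitudes
    idx, _ = signal.find_peaks(amp)
    sel = (spectrum.frequencies[idx] >= fmin) & (spectrum.frequencies[idx] <= fmax)
    idx = idx[sel]
    return idx, amp[idx]


def signal_test(
    spectra: dict[str, PowerSpectrum] | list[PowerSpectrum],
) -> tuple[dict[str, PeakReport], PeakReport | None]:
    """Per-channel largest spectral peak above 1.1 µVp, plus overall best.

    A peak must be a local maximum lying above the fitted aperiodic
    background with amplitude strictly greater than 1.1 µVp, searched
    across the alpha-beta-gamma range (8–100 Hz). Channels without such a
    peak report ``detected=False``; the overall best is the detected peak
    of largest amplitude across channels (None if none detected).
    """
    if isinstance(spectra, dict):
        items = list(spectra.items())
    else:
        items = [(sp.channel, sp) for sp in spectra]
    if not items:
        raise ValueError("signal_test requires at least one channel spectrum")

    reports: dict[str, PeakReport] = {}
    best: PeakReport | None = None
    for channel, sp in items:
        bg = fit_aperiodic_background(sp)
        idx, amps = _local_maxima(sp, *SIGNAL_TEST_RANGE_HZ)
        above = [
            (i, a)
            for i, a in zip(idx, amps)
            if a > SIGNAL_TEST_MIN_UVP and a > bg[i]
        ]
        if above:
            i, a = max(above, key=lambda pair: pair[1])
            freq = float(sp.frequencies[i])
            rep = PeakReport(channel, freq, float(a), band_label(freq), True)
            if best is None or a > best.amplitude:
                best = rep
        else:
            rep = PeakReport(channel, None, None, "none", False)
        reports[channel] = rep
    return reports, best


def automated_peak_detect(
    spectrum: PowerSpectrum,
    prominence_threshold: float = PEAK_PROMINENCE_UVP,
) -> list[PeakReport]:
    """Offline automated peak detector over the 8–30 Hz control range.

    Returns every local maximum whose amplitude exceeds the fitted
    aperiodic background by more than ``prominence_threshold`` µVp,
    ordered by frequency. This is a documented variant: the device's
    offline detector internals are not public.
    """
    if not np.any(spectrum.amplitudes > 0):
        return []
    bg = fit_aperiodic_background(spectrum)
    idx, amps = _local_maxima(spectrum, *CONTROL_RANGE_HZ)
    out = []
    for i, a in zip(idx, amps):
        if a - bg[i] > prominence_threshold:
            freq = float(spectrum.frequencies[i])
            out.append(PeakReport(spectrum.channel, freq, float(a), band_label(freq), True))
    out.sort(key=lambda r: r.center_frequency)
    return out


# ---------------------------------------------------------------------------
# Streaming band power
# ---------------------------------------------------------------------------

def _window_band_amplitude(
    frame: np.ndarray, fs: float, center_frequency: float
) -> float:
    """Control-band amplitude (µVp) of one analysis window.

    Hann-tapered periodogram; band power integrated over the closed
    interval [center − 2.5, center + 2.5] Hz and converted to the
    amplitude of an equivalent sinusoid, A = √(2 · band power).
    """
    n = len(frame)
    w = np.hanning(n)
    spec = np.fft.rfft(frame * w)
    # one-sided PSD density with window power normalization
    pxx = (np.abs(spec) ** 2) * 2.0 / (fs * np.sum(w**2))
    pxx[0] /= 2.0
    if n % 2 == 0:
        pxx[-1] /= 2.0
    f = np.fft.rfftfreq(n, 1.0 / fs)
    df = f[1] - f[0]
    lo = center_frequency - CONTROL_BAND_HALF_WIDTH_HZ
    hi = center_frequency + CONTROL_BAND_HALF_WIDTH_HZ
    band = (f >= lo) & (f <= hi)
    return float(np.sqrt(2.0 * np.sum(pxx[band]) * df))


def band_power_stream(
    recording: LfpRecording, center_frequency: float
) -> BandPowerStream:
    """Stream of 5 Hz-band amplitudes, one sample every 100 ms.

    Each sample integrates a 500 ms Hann-tapered FFT window ending at the
    sample time over [center − 2.5, center + 2.5] Hz. Sample times are
    window-end times on the session clock.
    """
    lo, hi = CONTROL_RANGE_HZ
    if not (lo <= center_frequency <= hi):
        warnings.warn(
            f"control frequency {center_frequency} Hz outside the "
            f"{lo}-{hi} Hz alpha-beta range",
            stacklevel=2,
        )
    fs = recording.sample_rate
    win = int(round(STREAM_WINDOW_S * fs))
    hop = int(round(STREAM_STEP_S * fs))
    x = recording.samples
    if len(x) < win:
        raise ValueError(
            f"recording of {recording.duration:.2f} s is shorter than the "
            f"{STREAM_WINDOW_S} s analysis window"
        )
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[::hop]
    w = np.hanning(win)
    spec = np.fft.rfft(frames * w, axis=1)
    pxx = (np.abs(spec) ** 2) * 2.0 / (fs * np.sum(w**2))
    pxx[:, 0] /= 2.0
    if win % 2 == 0:
        pxx[:, -1] /= 2.0
    f = np.fft.rfftfreq(win, 1.0 / fs)
    df = f[1] - f[0]
    band = (f >= center_frequency - CONTROL_BAND_HALF_WIDTH_HZ) & (
        f <= center_frequency + CONTROL_BAND_HALF_WIDTH_HZ
    )
    power = np.sqrt(2.0 * np.sum(pxx[:, band], axis=1) * df)
    k = np.arange(len(frames))
    times = recording.start_time + STREAM_WINDOW_S + k * STREAM_STEP_S
    return BandPowerStream(times, power)


# ---------------------------------------------------------------------------
# Timeline aggregation
# ---------------------------------------------------------------------------

def timeline_aggregate(
    stream: BandPowerStream,
    stim: np.ndarray | float | None = None,
) -> list[TimelineBin]:
    """Aggregate a band-power stream into 10-minute timeline bins.

    Bin means are arithmetic means over unblanked samples only (blanked
    samples accompany stimulation changes); each bin reports its sample
    count so downstream consumers can weight. Capacity is capped at 60
    days of bins — older bins rotate out first.
    """
    if len(stream) == 0:
        raise ValueError("cannot aggregate an empty stream")
    if stim is None:
        stim_arr = np.full(len(stream), np.nan)
    elif np.isscalar(stim):
        stim_arr = np.full(len(stream), float(stim))
    else:
        stim_arr = np.asarray(stim, dtype=float)
        if len(stim_arr) != len(stream):
            raise ValueError("stim trace length must match the stream")

    bin_idx = np.floor(stream.times / TIMELINE_BIN_S).astype(int)
    bins: list[TimelineBin] = []
    for b in np.unique(bin_idx):
        in_bin = (bin_idx == b) & ~stream.blanked
        count = int(in_bin.sum())
        if count == 0:
            mean_p = 0.0
            mean_s = float("nan")
        else:
            mean_p = float(stream.band_power[in_bin].mean())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_s = float(np.nanmean(stim_arr[in_bin]))
        bins.append(TimelineBin(float(b * TIMELINE_BIN_S), mean_p, mean_s, count))
    if len(bins) > TIMELINE_CAPACITY_BINS:
        bins = bins[-TIMELINE_CAPACITY_BINS:]
    return bins


# ---------------------------------------------------------------------------
# Event capture
# ---------------------------------------------------------------------------

class EventCaptureSession:
    """Patient-triggered 30 s spectrum snapshots, up to four unique labels."""

    MAX_LABELS = 4

    def __init__(self) -> None:
        self.events: list[tuple[str, PowerSpectrum]] = []

    @property
    def labels(self) -> set[str]:
        return {label for label, _ in self.events}

    def capture(self, recording: LfpRecording, label: str) -> PowerSpectrum:
        """Snapshot the trailing 30 s of ``recording`` under ``label``."""
        if label not in self.labels and len(self.labels) >= self.MAX_LABELS:
            raise ValueError(
                f"event capture supports at most {self.MAX_LABELS} unique "
                f"labels per session; {sorted(self.labels)} already used"
            )
        if recording.duration < PSD_EPOCH_S:
            raise ValueError("event capture requires at least 30 s of trailing data")
        n = int(round(PSD_EPOCH_S * recording.sample_rate))
        tail = LfpRecording(
            channel_id=recording.channel_id,
            hemisphere=recording.hemisphere,
            sample_rate=recording.sample_rate,
            samples=recording.samples[-n:],
            start_time=recording.start_time + recording.duration - PSD_EPOCH_S,
        )
        spectrum = compute_psd(tail, epoch=PSD_EPOCH_S)
        self.events.append((label, spectrum))
        return spectrum


# ---------------------------------------------------------------------------
# Artifact detection
# ---------------------------------------------------------------------------

#: Cardiac-periodicity lag window (s) and autocorrelation threshold.
ECG_LAG_RANGE_S = (0.6, 2.0)
ECG_AUTOCORR_THRESHOLD = 0.15

#: Movement flag: max 0.5 s window energy vs median window energy.
MOVEMENT_ENERGY_RATIO = 8.0


def detect_artifacts(recording: LfpRecording) -> set[str]:
    """Flag ECG and movement contamination; returns {"clean"} if neither.

    ECG is detected as cardiac-band periodicity: the autocorrelation of
    the rectified, mean-removed signal shows a peak above threshold at a
    lag of 0.6–2.0 s (100–30 bpm). Movement is detected as a broadband
    transient: one 0.5 s window's energy dwarfing the session median.
    Deterministic given the recording.
    """
    if recording.duration < 10.0:
        raise ValueError("artifact detection requires at least 10 s of data")
    fs = recording.sample_rate
    x = recording.samples
    flags: set[str] = set()

    # cardiac periodicity on the rectified signal (QRS spikes repeat at the
    # beat interval; narrowband oscillations decorrelate well before 0.6 s)
    r = np.abs(x - x.mean())
    r = r - r.mean()
    n = len(r)
    acf = signal.fftconvolve(r, r[::-1], mode="full")[n - 1 :]
    if acf[0] > 0:
        acf = acf / acf[0]
        lags = np.arange(n) / fs
        lag_sel = (lags >= ECG_LAG_RANGE_S[0]) & (lags <= ECG_LAG_RANGE_S[1])
        if np.any(lag_sel) and acf[lag_sel].max() > ECG_AUTOCORR_THRESHOLD:
            flags.add("ecg")

    # broadband transient energy in 0.5 s windows
    win = int(round(0.5 * fs))
    nwin = n // win
    if nwin >= 4:
        energies = (x[: nwin * win].reshape(nwin, win) ** 2).sum(axis=1)
        med = np.median(energies)
        if med > 0 and energies.max() > MOVEMENT_ENERGY_RATIO * med:
            flags.add("movement")

    return flags or {"clean"}


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def write_recording_csv(recording: LfpRecording, path) -> None:
    """Write a recording as two-column CSV (time_s, lfp_uv)."""
    recording.to_frame().to_csv(path, index=False)


def read_recording_csv(
    path, channel_id: str = "external", hemisphere: str = "left"
) -> LfpRecording:
    """Read a two-column CSV (time_s, lfp_uv) into an :class:`LfpRecording`."""
    import pandas as pd

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording CSV must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return LfpRecording(
        channel_id=channel_id,
        hemisphere=hemisphere,
        sample_rate=fs,
        samples=df["lfp_uv"].to_numpy(dtype=float),
        start_time=float(t[0]),
    )


def read_recording_edf(path, channel: str | int = 0) -> LfpRecording:
    """Read one channel of an EDF file (requires the optional ``mne`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF ingestion requires mne; install the 'edf' extra"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    name = raw.ch_names[channel] if isinstance(channel, int) else channel
    data = raw.get_data(picks=[name])[0] * 1e6  # volts -> µV
    return LfpRecording(
        channel_id=name,
        hemisphere="left",
        sample_rate=float(raw.info["sfreq"]),
        samples=data,
        start_time=0.0,
    )
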