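"""Sensing-chain tests: calibration, peak detection, streaming, timeline."""

import numpy as np
import pytest
from scipy.signal import butter, hilbert, sosfiltfilt

import adbsim
from adbsim import (
    BandPowerStream,
    EventCaptureSession,
    LfpRecording,
    automated_peak_detect,
    band_power_stream,
    compute_psd,
    detect_artifacts,
    signal_test,
    timeline_aggregate,
)
from adbsim.sensing import TIMELINE_CAPACITY_BINS, read_recording_csv, write_recording_csv

from conftest import FS, make_patient, tone_recording


class TestComputePsd:
    def test_all_zero_recording_gives_all_zero_spectrum(self):
        rec = LfpRecording("z", "left", FS, np.zeros(int(31 * FS)))
        sp = compute_psd(rec)
        assert np.all(sp.amplitudes == 0.0)
        assert sp.frequencies[0] == 0.0 and sp.frequencies[-1] <= 100.0
        assert sp.epoch_duration == 30.0

    @pytest.mark.parametrize("freq", [10, 15, 20, 25, 30, 35, 40, 45, 50, 55])
    def test_pure_tone_amplitude_calibration_within_5pct(self, freq):
        """A sinusoid of amplitude A µV yields a spectral peak of ≈ A µVp."""
        rec = tone_recording(freq, 1.0)
        sp = compute_psd(rec)
        peak = sp.amplitudes.max()
        assert sp.frequencies[np.argmax(sp.amplitudes)] == pytest.approx(freq, abs=1.0)
        assert abs(peak - 1.0) <= 0.05

    def test_parseval_total_power_matches_variance(self):
        """Total spectral power equals time-domain variance within 1% for a
        stationary band-limited input."""
        rec = tone_recording(20.0, 1.3)
        sp = compute_psd(rec)
        enbw = 1.5  # Hz, 1 s Hann window
        total_power = np.sum(sp.amplitudes**2 / (2 * enbw)) * sp.resolution
        variance = rec.samples[: int(30 * FS)].var()
        assert abs(total_power - variance) / variance < 0.01

    def test_short_recording_rejected(self):
        rec = LfpRecording("s", "left", FS, np.zeros(int(10 * FS)))
        with pytest.raises(ValueError):
            compute_psd(rec)


class TestSignalTest:
    def test_subthreshold_peaks_not_detected(self):
        spectra = {
            "a": compute_psd(tone_recording(15.0, 0.9, channel="a")),
            "b": compute_psd(tone_recording(20.0, 1.05, channel="b")),
        }
        reports, best = signal_test(spectra)
        assert not reports["a"].detected and not reports["b"].detected
        assert best is None

    def test_exactly_1p1_uvp_not_detected(self):
        sp = compute_psd(tone_recording(20.0, 1.1))
        # force the peak bin to exactly the cutoff to probe the strict rule
        sp.amplitudes[np.argmax(sp.amplitudes)] = 1.1
        reports, best = signal_test([sp])
        assert not reports["tone"].detected

    def test_largest_eligible_peak_wins_across_channels(self):
        """Channels at 1.0, 2.32 (16.6 Hz, synthetic) and 1.3 µVp (24 Hz):
        the overall best is the 16.6 Hz / 2.32 µVp worked-example peak."""
        m = make_patient(freq=16.6, amp=2.32)
        rec = adbsim.generate_lfp(m, "left", 30.5, seed=21, channel_id="b")
        spectra = {
            "a": compute_psd(tone_recording(12.0, 1.0, channel="a")),
            "b": compute_psd(rec),
            "c": compute_psd(tone_recording(24.0, 1.3, channel="c")),
        }
        reports, best = signal_test(spectra)
        assert best.channel == "b"
        assert abs(best.center_frequency - 16.6) <= 1.0
        assert abs(best.amplitude - 2.32) <= 0.232
        assert reports["c"].detected and reports["c"].band == "high-beta"
        assert not reports["a"].detected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            signal_test({})


class TestAutomatedPeakDetect:
    def test_pure_aperiodic_spectrum_yields_no_peaks(self):
        m = make_patient(amp=0.0)
        rec = adbsim.generate_lfp(m, "left", 30.5, seed=3)
        assert automated_peak_detect(compute_psd(rec)) == []

    def test_two_injected_peaks_returned_in_frequency_order(self):
        m = make_patient(freq=25.0, amp=2.0)
        for hemi in m.hemispheres.values():
            hemi.spectral_profile.peaks.append(
                adbsim.OscillatoryPeak(center_frequency=10.0, base_amplitude=1.6)
            )
        rec = adbsim.generate_lfp(m, "left", 30.5, seed=4)
        peaks = automated_peak_detect(compute_psd(rec))
        assert len(peaks) == 2
        assert peaks[0].center_frequency < peaks[1].center_frequency
        assert abs(peaks[0].center_frequency - 10.0) <= 1.0
        assert abs(peaks[1].center_frequency - 25.0) <= 1.0

    def test_peak_outside_8_30_window_ignored(self):
        m = make_patient(freq=35.0, amp=2.5)
        rec = adbsim.generate_lfp(m, "left", 30.5, seed=5)
        assert automated_peak_detect(compute_psd(rec)) == []

    def test_degenerate_all_zero_spectrum_returns_empty(self):
        sp = compute_psd(LfpRecording("z", "left", FS, np.zeros(int(31 * FS))))
        assert automated_peak_detect(sp) == []


class TestBandPowerStream:
    def test_cadence_exactly_100_ms(self):
        rec = tone_recording(18.0, 1.0, duration=10.0)
        stream = band_power_stream(rec, 18.0)
        assert np.abs(np.diff(stream.times) - 0.1).max() < 1e-9

    def test_silence_gives_zero_band_power(self):
        rec = LfpRecording("s", "left", FS, np.zeros(int(5 * FS)))
        stream = band_power_stream(rec, 20.0)
        assert np.all(stream.band_power < 1e-12)

    def test_stationary_tone_matches_hilbert_envelope_oracle(self):
        """An 18 Hz source of amplitude A: stream mean ≈ A, agreeing with the
        Hilbert-envelope mean of the band-passed signal."""
        A = 1.5
        rec = tone_recording(18.0, A, duration=40.0)
        stream = band_power_stream(rec, 18.0)
        sos = butter(4, [15.5, 20.5], btype="bandpass", fs=FS, output="sos")
        env = np.abs(hilbert(sosfiltfilt(sos, rec.samples)))
        oracle = env[500:-500].mean()
        assert stream.band_power.mean() == pytest.approx(oracle, rel=0.02)
        assert stream.band_power.mean() == pytest.approx(A, rel=0.02)
        assert stream.band_power.std() < 0.05 * A  # stationary input, tight estimator

    def test_out_of_band_center_warns_and_short_recording_errors(self):
        rec = tone_recording(18.0, 1.0, duration=2.0)
        with pytest.warns(UserWarning):
            band_power_stream(rec, 40.0)
        short = LfpRecording("s", "left", FS, np.zeros(50))
        with pytest.raises(ValueError):
            band_power_stream(short, 18.0)


class TestTimeline:
    def test_constant_stream_single_bin_mean(self):
        times = np.arange(6000) * 0.1  # 10 min
        stream = BandPowerStream(times, np.full(6000, 2.0))
        bins = timeline_aggregate(stream, stim=1.5)
        assert len(bins) == 1
        assert bins[0].mean_band_power == pytest.approx(2.0)
        assert bins[0].mean_stim_amplitude == pytest.approx(1.5)
        assert bins[0].sample_count == 6000

    def test_bin_means_match_bruteforce_oracle_and_exclude_blanked(self):
        rng = np.random.default_rng(8)
        n = 18000  # 30 min
        times = np.arange(n) * 0.1
        power = rng.uniform(0.5, 3.0, n)
        blanked = rng.random(n) < 0.1
        stream = BandPowerStream(times, power, blanked)
        bins = timeline_aggregate(stream)
        for b in bins:
            sel = (times >= b.start_time) & (times < b.start_time + 600) & ~blanked
            assert b.mean_band_power == pytest.approx(power[sel].mean())
            assert b.sample_count == sel.sum()

    def test_capacity_caps_at_60_days_rotating_oldest(self):
        n_bins = TIMELINE_CAPACITY_BINS + 60
        times = np.arange(n_bins) * 600.0 + 1.0  # one sample per 10-min bin
        stream = BandPowerStream(times, np.ones(n_bins))
        bins = timeline_aggregate(stream)
        assert len(bins) == TIMELINE_CAPACITY_BINS
        assert bins[0].start_time == 60 * 600.0  # oldest 60 bins rotated out


class TestEventCapture:
    def test_four_unique_labels_accepted_fifth_rejected(self):
        rec = tone_recording(20.0, 1.0, duration=31.0)
        session = EventCaptureSession()
        for label in ("dyskinesia", "tremor", "off", "sleep"):
            session.capture(rec, label)
        session.capture(rec, "tremor")  # repeats of an existing label are fine
        with pytest.raises(ValueError):
            session.capture(rec, "fifth")

    def test_snapshot_equals_compute_psd_of_trailing_window(self):
        rec = tone_recording(20.0, 1.0, duration=30.0)
        session = EventCaptureSession()
        snap = session.capture(rec, "event")
        ref = compute_psd(rec)
        assert np.allclose(snap.amplitudes, ref.amplitudes)

    def test_short_recording_rejected(self):
        rec = tone_recording(20.0, 1.0, duration=10.0)
        with pytest.raises(ValueError):
            EventCaptureSession().capture(rec, "x")


class TestArtifactDetection:
    def test_clean_beta_recording_is_clean(self):
        rec = adbsim.generate_lfp(make_patient(), "left", 30.0, seed=31)
        assert detect_artifacts(rec) == {"clean"}

    def test_strong_ecg_flagged(self):
        m = make_patient()
        for hemi in m.hemispheres.values():
            hemi.artifacts = adbsim.ArtifactParams(
                ecg_enabled=True, ecg_rate=70.0, ecg_amplitude=12.0
            )
        rec = adbsim.generate_lfp(m, "left", 30.0, seed=32)
        assert "ecg" in detect_artifacts(rec)

    def test_movement_transients_flagged(self):
        m = make_patient()
        for hemi in m.hemispheres.values():
            hemi.artifacts = adbsim.ArtifactParams(
                movement_rate=240.0, movement_amplitude=40.0
            )
        rec = adbsim.generate_lfp(m, "left", 30.0, seed=33)
        assert "movement" in detect_artifacts(rec)

    def test_too_short_recording_rejected(self):
        rec = tone_recording(20.0, 1.0, duration=5.0)
        with pytest.raises(ValueError):
            detect_artifacts(rec)


def test_recording_csv_round_trip(tmp_path):
    rec = adbsim.generate_lfp(make_patient(), "left", 3.0, seed=40)
    path = tmp_path / "rec.csv"
    write_recording_csv(rec, path)
    back = read_recording_csv(path)
    assert back.sample_rate == pytest.approx(rec.sample_rate)
    assert np.allclose(back.samples, rec.samples)
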