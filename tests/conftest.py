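"""Shared fixtures: small seeded synthetic patients and rosters."""

import numpy as np
import pytest

from adbsim import (
    ControllerConfig,
    HemisphereModel,
    HemispherePeak,
    LfpRecording,
    OscillatoryPeak,
    PatientModel,
    SpectralProfile,
)

FS = 250.0


def make_patient(
    freq=16.6,
    amp=2.32,
    noise_floor=0.05,
    aperiodic_offset=-1.5,
    stim_suppression=0.0,
    **hemi_kwargs,
):
    """Two identical hemispheres with one oscillatory peak."""
    from adbsim import ModulationParams

    hemi = HemisphereModel(
        spectral_profile=SpectralProfile(
            aperiodic_offset=aperiodic_offset,
            aperiodic_exponent=1.0,
            peaks=[OscillatoryPeak(center_frequency=freq, base_amplitude=amp)],
            broadband_noise_floor=noise_floor,
        ),
        modulation=ModulationParams(
            stim_suppression_fraction=stim_suppression,
            stim_half_suppression_amplitude=1.5,
        ),
        **hemi_kwargs,
    )
    return PatientModel(hemispheres={"left": hemi, "right": hemi.model_copy(deep=True)})


def tone_recording(freq, amplitude, duration=31.0, fs=FS, channel="tone"):
    t = np.arange(int(duration * fs)) / fs
    return LfpRecording(channel, "left", fs, amplitude * np.sin(2 * np.pi * freq * t))


@pytest.fixture
def beta_patient():
    return make_patient()


@pytest.fixture
def single_config():
    return ControllerConfig(
        mode="single",
        single_threshold=1.5,
        lower_stim_limit=1.0,
        upper_stim_limit=3.0,
        onset_duration=200,
    )


@pytest.fixture
def dual_config():
    return ControllerConfig(
        mode="dual",
        lower_lfp_threshold=1.0,
        upper_lfp_threshold=2.0,
        lower_stim_limit=1.0,
        upper_stim_limit=3.0,
    )


def table2_roster():
    """Roster whose counts reproduce the published enrollment summary.

    On medication: 66 participants — 43 bilateral, 13 unilateral, 10 with
    no peak; hemisphere bands 21 alpha / 41 low-beta / 37 high-beta.
    Off medication: 59 participants — 46 bilateral, 8 unilateral, 5 none;
    bands 31 / 34 / 35.
    """
    rows = []

    def band_freq(band):
        return {"alpha": 10.0, "low-beta": 16.0, "high-beta": 25.0}[band]

    def build(med, bilateral, unilateral, none, band_counts):
        bands = [b for b, c in band_counts.items() for _ in range(c)]
        it = iter(bands)
        pid = 0
        for _ in range(bilateral):
            pid += 1
            for hemi in ("left", "right"):
                rows.append(
                    HemispherePeak(
                        participant=f"{med}-{pid}", target="STN", hemisphere=hemi,
                        med_state=med, detected=True,
                        frequency=band_freq(next(it)), amplitude=2.0,
                    )
                )
        for _ in range(unilateral):
            pid += 1
            rows.append(
                HemispherePeak(
                    participant=f"{med}-{pid}", target="STN", hemisphere="left",
                    med_state=med, detected=True,
                    frequency=band_freq(next(it)), amplitude=2.0,
                )
            )
            rows.append(
                HemispherePeak(
                    participant=f"{med}-{pid}", target="STN", hemisphere="right",
                    med_state=med, detected=False,
                )
            )
        for _ in range(none):
            pid += 1
            for hemi in ("left", "right"):
                rows.append(
                    HemispherePeak(
                        participant=f"{med}-{pid}", target="STN", hemisphere=hemi,
                        med_state=med, detected=False,
                    )
                )

    build("on", 43, 13, 10, {"alpha": 21, "low-beta": 41, "high-beta": 37})
    build("off", 46, 8, 5, {"alpha": 31, "low-beta": 34, "high-beta": 35})
    return rows
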