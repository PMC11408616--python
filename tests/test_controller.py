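"""Controller tests: comparator, onset/blanking timers, ramps, linking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adbsim
from adbsim import BandPowerSample, ControllerConfig, compare, run_scripted, step
from adbsim.controller import ControllerState, CONTROL_DT_S

from conftest import make_patient


class TestCompare:
    def test_single_mode_above_below(self, single_config):
        assert compare(2.0, single_config) == "above"
        assert compare(1.0, single_config) == "below"

    def test_dual_mode_three_regions(self, dual_config):
        assert compare(2.5, dual_config) == "above"
        assert compare(1.5, dual_config) == "between"
        assert compare(0.5, dual_config) == "below"

    def test_exact_threshold_is_not_crossed(self, single_config, dual_config):
        assert compare(1.5, single_config) == "below"
        assert compare(2.0, dual_config) == "between"
        assert compare(1.0, dual_config) == "between"


class TestConfigValidation:
    def test_onset_ranges_enforced_per_mode(self):
        with pytest.raises(Exception):
            ControllerConfig(mode="single", single_threshold=1.0, onset_duration=100)
        with pytest.raises(Exception):
            ControllerConfig(
                mode="dual", lower_lfp_threshold=1.0, upper_lfp_threshold=2.0,
                onset_duration=500,
            )

    def test_dual_ramps_must_be_1_to_10_min(self):
        with pytest.raises(Exception):
            ControllerConfig(
                mode="dual", lower_lfp_threshold=1.0, upper_lfp_threshold=2.0,
                ramp_up_time=15 * 60.0,
            )

    def test_threshold_and_limit_ordering(self):
        with pytest.raises(Exception):
            ControllerConfig(mode="dual", lower_lfp_threshold=2.0, upper_lfp_threshold=1.0)
        with pytest.raises(Exception):
            ControllerConfig(mode="single", single_threshold=1.0,
                             lower_stim_limit=3.0, upper_stim_limit=1.0)

    def test_mode_defaults(self):
        s = ControllerConfig(mode="single", single_threshold=1.0)
        assert s.ramp_up_time == pytest.approx(0.25)
        assert s.onset_duration == 400.0
        d = ControllerConfig(mode="dual", lower_lfp_threshold=1.0, upper_lfp_threshold=2.0)
        assert d.ramp_up_time == pytest.approx(150.0)
        assert d.ramp_down_time == pytest.approx(300.0)
        assert d.onset_duration == 1600.0
        assert d.blanking_duration == 550.0


class TestSingleMode:
    def test_sub_onset_burst_causes_no_change(self, single_config):
        # 150 ms above threshold (one 100 ms sample), onset 200 ms
        power = np.full(50, 0.5)
        power[10] = 3.0
        trace = run_scripted(power, single_config, 5.0)
        assert len(trace.events) == 0
        assert np.all(trace.stim["left"] == 1.0)

    def test_sustained_drive_full_ramp_in_250_ms(self, single_config):
        """Sustained supra-threshold power ramps 1.0 → 3.0 mA linearly,
        completing the full traversal exactly 250 ms after ramp start."""
        trace = run_scripted(lambda t: 3.0, single_config, 5.0)
        ev = [e for e in trace.events if e["hemisphere"] == "left"][0]
        t0 = ev["time_s"]
        stim = trace.stim["left"]
        t = trace.times
        # linear interior samples and exact saturation at t0 + 0.25
        assert stim[np.isclose(t, t0 + 0.1)][0] == pytest.approx(1.0 + 2.0 * 0.1 / 0.25)
        assert stim[np.isclose(t, t0 + 0.2)][0] == pytest.approx(1.0 + 2.0 * 0.2 / 0.25)
        assert np.all(stim[t >= t0 + 0.25 - 1e-9] == 3.0)

    def test_trapezoid_slopes_only_zero_or_full_ramp_rate(self, single_config):
        rng = np.random.default_rng(0)
        power = np.where(rng.random(600) > 0.5, 3.0, 0.5)
        trace = run_scripted(power, single_config, 60.0)
        slopes = np.diff(trace.stim["left"]) / CONTROL_DT_S
        full = (3.0 - 1.0) / 0.25
        for s in slopes:
            assert (
                abs(s) < 1e-9
                or abs(abs(s) - full) < 1e-9
                or abs(s) < full + 1e-9  # partial first/last ramp step
            )
        # every nonzero slope magnitude is at most the full ramp rate
        assert np.max(np.abs(slopes)) <= full + 1e-9

    def test_amplitude_pinned_at_limits_under_constant_drive(self, single_config):
        up = run_scripted(lambda t: 9.9, single_config, 10.0)
        assert up.stim["left"][-1] == 3.0
        down = run_scripted(lambda t: 0.1, single_config, 10.0, initial_amplitude=3.0)
        assert down.stim["left"][-1] == 1.0


class TestDualMode:
    def test_hold_between_thresholds_for_entire_session(self, dual_config):
        trace = run_scripted(lambda t: 1.5, dual_config, 30.0)
        assert len(trace.events) == 0
        assert np.all(trace.stim["left"] == trace.stim["left"][0])

    def test_incremental_adjustment_stops_partway(self, dual_config):
        """Above-threshold drive followed by in-band drive leaves the
        amplitude strictly between the limits: adjustments are incremental,
        not full traversals."""
        power = np.concatenate([np.full(100, 3.0), np.full(200, 1.5)])
        trace = run_scripted(power, dual_config, 30.0)
        final = trace.stim["left"][-1]
        assert 1.0 < final < 3.0
        assert np.all(trace.stim["left"][-150:] == final)  # held constant in band

    def test_slow_ramp_rate_is_window_over_150_s(self, dual_config):
        trace = run_scripted(lambda t: 3.0, dual_config, 30.0)
        slopes = np.diff(trace.stim["left"]) / CONTROL_DT_S
        expected = (3.0 - 1.0) / 150.0
        moving = slopes[slopes > 1e-12]
        assert len(moving) > 0
        assert np.allclose(moving, expected)


class TestBlankingAndOnset:
    def test_blanked_samples_cover_exactly_550_ms_window(self, single_config):
        trace = run_scripted(lambda t: 3.0, single_config, 5.0)
        ev = trace.events[0]
        blanked_times = trace.times[trace.blanked["left"]]
        elapsed = blanked_times - ev["time_s"]
        assert np.all((elapsed > 0) & (elapsed <= 0.550 + 1e-9))
        assert len(blanked_times) == 5  # 100..500 ms on the 100 ms grid
        assert ev["blank_until_s"] - ev["time_s"] == pytest.approx(0.550)

    def test_no_two_ramp_initiations_within_blanking(self, single_config):
        rng = np.random.default_rng(1)
        power = np.where(rng.random(1200) > 0.5, 3.0, 0.5)
        trace = run_scripted(power, single_config, 120.0)
        times = [e["time_s"] for e in trace.events if e["hemisphere"] == "left"]
        gaps = np.diff(times)
        assert len(times) > 2
        assert np.all(gaps > 0.550)

    def test_onset_resets_on_region_flip(self, single_config):
        # alternate every sample: onset can never accumulate 200 ms
        power = np.tile([3.0, 0.5], 100)
        trace = run_scripted(power, single_config, 20.0)
        assert len(trace.events) == 0

    def test_cadence_violation_rejected(self, single_config):
        state = ControllerState.initial(single_config).hemispheres["left"]
        step(state, BandPowerSample(time=0.1, band_power=1.0), single_config)
        with pytest.raises(ValueError):
            step(state, BandPowerSample(time=0.35, band_power=1.0), single_config)


class TestBilateralLink:
    def test_one_hemisphere_crossing_ramps_both(self, single_config):
        trace = run_scripted(lambda t: 3.0, single_config, 5.0, hemisphere="left")
        assert trace.stim["left"][-1] == 3.0
        assert trace.stim["right"][-1] == 3.0
        triggers = {e["hemisphere"]: e["trigger"] for e in trace.events}
        assert triggers == {"left": "onset", "right": "linked"}

    def test_link_disabled_leaves_other_hemisphere_on_cdbs(self):
        cfg = ControllerConfig(
            mode="single", single_threshold=1.5, lower_stim_limit=1.0,
            upper_stim_limit=3.0, onset_duration=200,
            bilateral_link=False, control_hemispheres=["left"],
        )
        trace = run_scripted(lambda t: 3.0, cfg, 5.0, hemisphere="left")
        assert trace.stim["left"][-1] == 3.0
        assert np.all(trace.stim["right"] == trace.stim["right"][0])  # constant cDBS

    def test_simultaneous_crossing_idempotent(self, single_config):
        states = ControllerState.initial(single_config)
        for k in range(3):
            t = (k + 1) * CONTROL_DT_S
            for hemi in ("left", "right"):
                step(states.hemispheres[hemi],
                     BandPowerSample(time=t, band_power=3.0), single_config)
        # both triggered on their own; linking adds no duplicate commands
        n_before = len(states.events)
        adbsim.link_bilateral(states, "left", single_config)
        adbsim.link_bilateral(states, "right", single_config)
        assert len(states.events) == n_before

    def test_link_with_zero_control_hemispheres_rejected(self, single_config):
        states = ControllerState.initial(single_config)
        cfg = single_config.model_copy(update={"control_hemispheres": []})
        with pytest.raises(ValueError):
            adbsim.link_bilateral(states, "left", cfg)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    lo=st.floats(0.0, 2.0),
    span=st.floats(0.1, 4.0),
    threshold=st.floats(0.2, 3.0),
    onset=st.floats(200.0, 500.0),
    seed=st.integers(0, 2**16),
)
def test_amplitude_always_clamped_to_limits(lo, span, threshold, onset, seed):
    """Safety property: amplitude never leaves [lower, upper] under random
    configs and random band-power inputs."""
    cfg = ControllerConfig(
        mode="single", single_threshold=threshold,
        lower_stim_limit=lo, upper_stim_limit=lo + span, onset_duration=onset,
    )
    rng = np.random.default_rng(seed)
    power = rng.uniform(0.0, 4.0, 300)
    trace = run_scripted(power, cfg, 30.0)
    for hemi in ("left", "right"):
        assert np.all(trace.stim[hemi] >= lo - 1e-9)
        assert np.all(trace.stim[hemi] <= lo + span + 1e-9)


def test_monotone_time_at_upper_limit_vs_drive_level(single_config):
    """Raising the stationary input band power never decreases single-mode
    time at the upper stimulation limit (seeded sweep)."""
    rng_master = np.random.default_rng(77)
    noise = rng_master.normal(0.0, 0.4, 1200)
    fractions = []
    for level in (0.8, 1.3, 1.6, 2.0, 3.0):
        power = np.clip(level + noise, 0.0, None)
        trace = run_scripted(power, single_config, 120.0)
        fractions.append(np.mean(trace.stim["left"] == 3.0))
    assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))
    assert fractions[0] < 0.2 and fractions[-1] > 0.8


def test_square_wave_drive_fraction_at_upper_matches_duty_cycle(single_config):
    """30 s high / 30 s low square-wave drive: the fraction of time at the
    upper limit matches the 50% duty cycle up to onset/ramp transients."""
    trace = run_scripted(
        lambda t: 3.0 if (t // 30.0) % 2 == 0 else 0.5, single_config, 300.0
    )
    frac = np.mean(trace.stim["left"] == 3.0)
    assert frac == pytest.approx(0.5, abs=0.05)


class TestClosedLoop:
    def test_pinned_at_upper_when_power_always_above(self):
        m = make_patient(freq=18.0, amp=3.0)  # strong signal, no suppression
        cfg = ControllerConfig(
            mode="single", single_threshold=0.5, lower_stim_limit=1.0,
            upper_stim_limit=3.0, onset_duration=200, center_frequency=18.0,
        )
        trace = adbsim.run_closed_loop(m, cfg, 20.0, seed=5)
        settled = trace.stim["left"][trace.times > 2.0]
        assert np.all(settled == 3.0)

    def test_pinned_at_lower_when_power_always_below(self):
        m = make_patient(freq=18.0, amp=0.2)
        cfg = ControllerConfig(
            mode="single", single_threshold=5.0, lower_stim_limit=1.0,
            upper_stim_limit=3.0, onset_duration=200, center_frequency=18.0,
        )
        trace = adbsim.run_closed_loop(m, cfg, 20.0, seed=6)
        assert np.all(trace.stim["left"] == 1.0)
        assert len(trace.events) == 0

    def test_seed_reproducibility(self):
        m = make_patient(stim_suppression=0.5)
        cfg = ControllerConfig(
            mode="single", single_threshold=1.8, lower_stim_limit=0.5,
            upper_stim_limit=3.0, onset_duration=200, center_frequency=16.6,
        )
        a = adbsim.run_closed_loop(m, cfg, 30.0, seed=9)
        b = adbsim.run_closed_loop(m, cfg, 30.0, seed=9)
        assert np.array_equal(a.band_power["left"], b.band_power["left"])
        assert np.array_equal(a.stim["left"], b.stim["left"])

    def test_feedback_suppression_reduces_band_power_after_ramp(self):
        """With the suppression sigmoid active, stimulation reaching the
        upper limit measurably lowers the sensed beta amplitude."""
        m = make_patient(amp=3.0, stim_suppression=0.7)
        cfg = ControllerConfig(
            mode="single", single_threshold=0.3, lower_stim_limit=0.0,
            upper_stim_limit=3.0, onset_duration=200, center_frequency=16.6,
        )
        trace = adbsim.run_closed_loop(m, cfg, 30.0, seed=10)
        early = trace.band_power["left"][trace.times < 0.8].mean()
        late = trace.band_power["left"][trace.times > 5.0].mean()
        assert late < 0.7 * early

    def test_sample_rate_mismatch_rejected(self, single_config):
        m = make_patient()
        m.sample_rate = 213.0
        with pytest.raises(ValueError):
            adbsim.run_closed_loop(m, single_config, 5.0, seed=0)
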