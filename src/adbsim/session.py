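"""Session configuration, persistence and fixture generation.

Ties the generator, sensing chain, controller and programming workflow
into reproducible end-to-end sessions: a validated JSON session config
goes in; a self-describing bundle (programming record, closed-loop trace,
timeline bins, time-in-state summary, ramp-verification report, content
checksum) comes out. Two runs of the same config produce identical
checksums.

All randomness flows from the single session seed: per-purpose substreams
are derived with ``numpy.random.SeedSequence.spawn`` in a fixed order
(programming workflow first, then the closed-loop run), so adding
consumers never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import cohort, programming, sensing
from .controller import ControllerConfig, SessionTrace, run_closed_loop
from .programming import ProgramRecord, setup_workflow, verify_ramp
from .synthetic import (
    ArtifactParams,
    BurstParams,
    HemisphereModel,
    MedicationSchedule,
    ModulationParams,
    OscillatoryPeak,
    PatientModel,
    SpectralProfile,
)

__all__ = [
    "SessionConfig",
    "SessionBundle",
    "load_config",
    "run_session",
    "make_fixture",
    "fixture_names",
    "config_schema",
]

TOOL_VERSION = "0.1.0"


class SessionConfig(BaseModel):
    """One reproducible end-to-end session.

    ``patient`` may be inline or a path to a patient JSON document
    (resolved relative to the config file at load time). The seed is
    mandatory: every random draw in the session derives from it.
    """

    patient: PatientModel | str
    mode: str = "single"  # controller mode to program
    lower_stim_limit: float | dict[str, float] = 0.5  # mA
    upper_stim_limit: float | dict[str, float] = 3.0  # mA
    duration: float = Field(default=120.0, gt=0)  # s closed-loop run
    seed: int
    output_dir: str | None = None
    export_trace_csv: bool = False
    export_events_jsonl: bool = False
    controller_overrides: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_overrides(self) -> "SessionConfig":
        if self.mode not in ("single", "dual"):
            raise ValueError("mode must be 'single' or 'dual'")
        if self.controller_overrides:
            # validate timing/threshold overrides against the mode's
            # programmable ranges now, with placeholder thresholds (the real
            # ones are measured during the programming workflow)
            probe = {
                "mode": self.mode,
                "single_threshold": 1.0,
                "lower_lfp_threshold": 1.0,
                "upper_lfp_threshold": 2.0,
                "lower_stim_limit": self.lower_stim_limit,
                "upper_stim_limit": self.upper_stim_limit,
            }
            probe.update(self.controller_overrides)
            try:
                ControllerConfig.model_validate(probe)
            except (ValidationError, ValueError) as exc:
                raise ValueError(f"invalid controller_overrides: {exc}") from exc
        return self

    def resolve_patient(self, base: Path | None = None) -> PatientModel:
        if isinstance(self.patient, PatientModel):
            return self.patient
        path = Path(self.patient)
        if base is not None and not path.is_absolute():
            path = base / path
        if not path.exists():
            raise FileNotFoundError(f"referenced patient file {path} does not exist")
        return PatientModel.model_validate_json(path.read_text())


def load_config(path) -> SessionConfig:
    """Load and validate a session config JSON with field-path diagnostics."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cfg = SessionConfig.model_validate_json(path.read_text())
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ValueError(f"invalid session config {path}: {details}") from exc
    if isinstance(cfg.patient, str):
        cfg.resolve_patient(base=path.parent)  # existence check at load
    return cfg


def config_schema() -> dict:
    """JSON schema of the session config document."""
    return SessionConfig.model_json_schema()


# ---------------------------------------------------------------------------
# Session bundle
# ---------------------------------------------------------------------------

def _canonical(obj):
    """JSON-stable form: dicts sorted, floats rounded to 10 significant digits."""
    if isinstance(obj, dict):
        return {k: _canonical(obj[k]) for k in sorted(obj)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return 0.0 if v == 0 else float(f"{v:.10g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_canonical(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class SessionBundle:
    """Self-describing output of one session; units embedded in keys."""

    config: dict
    program: dict
    trace: dict
    timeline: dict
    time_in_state: list
    ramp_report: dict
    tool_version: str
    checksum: str = ""

    def payload(self) -> dict:
        return {
            "config": self.config,
            "program": self.program,
            "trace": self.trace,
            "timeline": self.timeline,
            "time_in_state": self.time_in_state,
            "ramp_report": self.ramp_report,
            "tool_version": self.tool_version,
        }

    def compute_checksum(self) -> str:
        blob = json.dumps(_canonical(self.payload()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def to_json(self) -> str:
        doc = _canonical(self.payload())
        doc["checksum"] = self.checksum
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SessionBundle":
        doc = json.loads(text)
        checksum = doc.pop("checksum")
        return cls(**doc, checksum=checksum)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return _canonical(self.payload()) == _canonical(other.payload())


def _program_dict(record: ProgramRecord) -> dict:
    return {
        "mode": record.mode,
        "eligibility": {h: r.to_dict() for h, r in record.eligibility.items()},
        "eligible_hemispheres": list(record.eligible_hemispheres),
        "control_frequencies_hz": dict(record.control_frequencies),
        "measurements": {
            h: [
                {
                    "stim_level_ma": m.stim_level,
                    "epoch_duration_s": m.epoch_duration,
                    "mean_band_power_uvp": m.mean_band_power,
                }
                for m in ms
            ]
            for h, ms in record.measurements.items()
        },
        "controller_config": record.config.model_dump() if record.config else None,
        "log": list(record.log),
    }


def _trace_dict(trace: SessionTrace) -> dict:
    return {
        "time_s": trace.times.tolist(),
        **{f"band_power_uvp_{h}": trace.band_power[h].tolist() for h in trace.band_power},
        **{f"stim_ma_{h}": trace.stim[h].tolist() for h in trace.stim},
        **{f"blanked_{h}": trace.blanked[h].astype(bool).tolist() for h in trace.blanked},
        "events": trace.events,
    }


def run_session(config: SessionConfig, base: Path | None = None) -> SessionBundle:
    """Programming workflow → closed-loop run → summaries, all seeded."""
    patient = config.resolve_patient(base)
    ss = np.random.SeedSequence(config.seed)
    prog_seed, loop_seed = ss.spawn(2)

    record = setup_workflow(
        patient,
        config.mode,
        config.lower_stim_limit,
        config.upper_stim_limit,
        seed=prog_seed,
    )
    ctl_config = record.config
    if config.controller_overrides:
        ctl_config = ControllerConfig.model_validate(
            {**ctl_config.model_dump(), **config.controller_overrides}
        )

    trace = run_closed_loop(
        patient, ctl_config, config.duration, seed=loop_seed, med_override=0.0
    )
    hemi = ctl_config.control_hemispheres[0]
    timeline = {
        "hemisphere": hemi,
        "bins": [
            {
                "start_time_s": b.start_time,
                "mean_band_power_uvp": b.mean_band_power,
                "mean_stim_amplitude_ma": b.mean_stim_amplitude,
                "sample_count": b.sample_count,
            }
            for b in trace.timeline(hemi)
        ],
    }
    tis = cohort.time_in_state(trace, ctl_config, hemisphere=hemi)
    ramp_report = verify_ramp(ctl_config)

    cfg_dict = config.model_dump()
    if isinstance(config.patient, PatientModel):
        cfg_dict["patient"] = config.patient.model_dump()
    bundle = SessionBundle(
        config=cfg_dict,
        program=_program_dict(record),
        trace=_trace_dict(trace),
        timeline=timeline,
        time_in_state=tis,
        ramp_report=ramp_report,
        tool_version=TOOL_VERSION,
    )
    bundle.checksum = bundle.compute_checksum()

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "session_bundle.json").write_text(bundle.to_json())
        if config.export_trace_csv:
            trace.to_frame().to_csv(out / "session_trace.csv", index=False)
        if config.export_events_jsonl:
            with open(out / "events.jsonl", "w") as fh:
                for e in trace.events:
                    fh.write(json.dumps(_canonical(e)) + "\n")
    return bundle


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _beta_hemisphere(
    amplitude: float = 2.32,
    frequency: float = 16.6,
    stim_suppression: float = 0.5,
    **hemi_kwargs,
) -> HemisphereModel:
    return HemisphereModel(
        spectral_profile=SpectralProfile(
            aperiodic_offset=-1.5,
            aperiodic_exponent=1.0,
            peaks=[OscillatoryPeak(center_frequency=frequency, base_amplitude=amplitude)],
            broadband_noise_floor=0.05,
        ),
        modulation=ModulationParams(
            stim_suppression_fraction=stim_suppression,
            stim_half_suppression_amplitude=1.5,
        ),
        **hemi_kwargs,
    )


def _flat_hemisphere() -> HemisphereModel:
    return HemisphereModel(
        spectral_profile=SpectralProfile(
            aperiodic_offset=-1.8, aperiodic_exponent=1.0, peaks=[],
            broadband_noise_floor=0.05,
        )
    )


def _fixture_clean_beta() -> PatientModel:
    return PatientModel(
        hemispheres={"left": _beta_hemisphere(), "right": _beta_hemisphere(2.0, 20.0)}
    )


def _fixture_no_signal() -> PatientModel:
    return PatientModel(hemispheres={"left": _flat_hemisphere(), "right": _flat_hemisphere()})


def _fixture_ecg() -> PatientModel:
    hemi = _beta_hemisphere()
    hemi.artifacts = ArtifactParams(ecg_enabled=True, ecg_rate=70.0, ecg_amplitude=12.0)
    other = _beta_hemisphere(2.0, 20.0)
    other.artifacts = ArtifactParams(ecg_enabled=True, ecg_rate=70.0, ecg_amplitude=12.0)
    return PatientModel(hemispheres={"left": hemi, "right": other})


def _fixture_bursty() -> PatientModel:
    bursts = BurstParams(
        burst_rate=0.5, mean_burst_duration=400.0,
        burst_duration_dispersion=0.6, burst_gain=2.5,
    )
    return PatientModel(
        hemispheres={
            "left": _beta_hemisphere(bursts=bursts),
            "right": _beta_hemisphere(2.0, 20.0, bursts=bursts),
        }
    )


def _fixture_med_cycling() -> PatientModel:
    model = _fixture_clean_beta()
    for hemi in model.hemispheres.values():
        hemi.modulation.med_suppression_fraction = 0.4
    model.medication = MedicationSchedule(
        dose_times=[8.0, 12.0, 16.0, 20.0], washin_tau=20.0, washout_tau=90.0
    )
    return model


def _fixture_single_viable() -> PatientModel:
    return PatientModel(
        hemispheres={"left": _beta_hemisphere(), "right": _flat_hemisphere()}
    )


_FIXTURES = {
    "clean_beta_16p6": _fixture_clean_beta,
    "no_signal": _fixture_no_signal,
    "ecg_contaminated": _fixture_ecg,
    "bursty_beta": _fixture_bursty,
    "medication_cycling": _fixture_med_cycling,
    "single_viable_signal": _fixture_single_viable,
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def make_fixture(name: str, seed: int = 0) -> tuple[SessionConfig, dict]:
    """Seeded test-patient config plus a manifest of measured expectations.

    The manifest values are computed by running the sensing chain on the
    fixture at the given seed (signal-test peak, eligibility verdicts,
    artifact flags) — they are measurements, not assertions.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}")
    patient = _FIXTURES[name]()
    config = SessionConfig(patient=patient, seed=seed, mode="single",
                           lower_stim_limit=0.5, upper_stim_limit=3.0)

    from .synthetic import generate_lfp

    ss = np.random.SeedSequence(seed)
    manifest: dict = {"fixture": name, "seed": seed, "hemispheres": {}}
    for hemi, child in zip(sorted(patient.hemispheres), ss.spawn(2)):
        rec = generate_lfp(patient, hemi, 30.5, stim_trace=0.0, seed=child,
                           med_override=0.0)
        spectrum = sensing.compute_psd(rec)
        reports, _ = sensing.signal_test({rec.channel_id: spectrum})
        report = reports[rec.channel_id]
        flags = sensing.detect_artifacts(rec)
        manifest["hemispheres"][hemi] = {
            "signal_test": report.to_dict(),
            "artifact_flags": sorted(flags),
            "eligible": programming.check_eligibility(
                report, artifact_flagged=flags != {"clean"}
            ),
        }
    return config, manifest
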