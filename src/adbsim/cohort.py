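"""Cohort-level LFP summary statistics and trial design computations.

Band classification of control-signal peaks (alpha 8–12, low-beta 13–20,
high-beta 21–30 Hz), participant-level peak-detection summary tables,
total electrical energy delivered (TEED), time-in-state fractions from
closed-loop traces, and the exact one-sided binomial sample-size
computation used for performance-goal trial designs.

Real-valued peak frequencies are classified with half-open intervals
[8,13), [13,21), [21,30] so the integer band definitions are covered
without gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats as sstats

from .controller import ControllerConfig, SessionTrace

__all__ = [
    "HemispherePeak",
    "CohortSummary",
    "TeedParams",
    "classify_band",
    "summarize_cohort",
    "teed",
    "time_in_state",
    "exact_binomial_sample_size",
    "read_roster_csv",
    "BANDS",
]

#: Real-valued band intervals (lower inclusive; high-beta upper inclusive).
BANDS = {"alpha": (8.0, 13.0), "low-beta": (13.0, 21.0), "high-beta": (21.0, 30.0)}

_SECONDS_PER_DAY = 86400.0


class HemispherePeak(BaseModel):
    """One hemisphere's clinician- or algorithm-identified peak."""

    participant: str
    target: str  # STN | GPi
    hemisphere: str
    med_state: str  # on | off
    detected: bool
    frequency: float | None = None  # Hz
    amplitude: float | None = None  # µVp

    def model_post_init(self, __context) -> None:
        if self.detected and (self.frequency is None or self.amplitude is None):
            raise ValueError("detected peaks require frequency and amplitude")
        if not self.detected and (self.frequency is not None or self.amplitude is not None):
            raise ValueError("undetected peaks must not carry frequency/amplitude")


@dataclass
class CohortSummary:
    """Participant- and hemisphere-level detection summary for one med state."""

    med_state: str
    participants: int
    detected: int
    detected_pct: float
    bilateral: int
    bilateral_pct: float
    unilateral: int
    unilateral_pct: float
    none: int
    none_pct: float
    hemispheres_total: int
    hemisphere_detected_pct: float  # detected hemispheres / all hemisphere records
    hemisphere_denominator: int  # detected hemispheres with in-range peaks
    band_counts: dict[str, int]
    band_pct: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "med_state": self.med_state,
            "participants_n": self.participants,
            "peak_detected_n": self.detected,
            "peak_detected_pct": self.detected_pct,
            "bilateral_n": self.bilateral,
            "bilateral_pct": self.bilateral_pct,
            "unilateral_n": self.unilateral,
            "unilateral_pct": self.unilateral_pct,
            "no_peaks_n": self.none,
            "no_peaks_pct": self.none_pct,
            "hemispheres_total_n": self.hemispheres_total,
            "hemisphere_detected_pct": self.hemisphere_detected_pct,
            "hemisphere_denominator_n": self.hemisphere_denominator,
            "band_counts_n": dict(self.band_counts),
            "band_pct": dict(self.band_pct),
        }

    def to_text(self) -> str:
        lines = [
            f"Cohort summary ({self.med_state} medication)",
            f"  Participants (N)        {self.participants}",
            f"  Peak detected           {self.detected} ({self.detected_pct}%)",
            f"    Bilateral peaks       {self.bilateral} ({self.bilateral_pct}%)",
            f"    Unilateral peak       {self.unilateral} ({self.unilateral_pct}%)",
            f"  No peaks                {self.none} ({self.none_pct}%)",
            f"  Hemispheres (N)         {self.hemisphere_denominator}",
        ]
        for band in BANDS:
            lines.append(
                f"    {band:<20}{self.band_counts[band]} ({self.band_pct[band]}%)"
            )
        return "\n".join(lines)


class TeedParams(BaseModel):
    """Stimulation parameters entering the TEED computation."""

    amplitude: float = Field(ge=0)  # mA
    pulse_width: float = Field(ge=0)  # µs
    rate: float = Field(ge=0)  # Hz
    impedance: float = Field(gt=0)  # Ω


# ---------------------------------------------------------------------------
# Band classification
# ---------------------------------------------------------------------------

def classify_band(frequency: float) -> str:
    """Band of a peak frequency: alpha [8,13), low-beta [13,21), high-beta [21,30]."""
    if not (8.0 <= frequency <= 30.0):
        raise ValueError(f"peak frequency {frequency} Hz outside the 8-30 Hz range")
    for band, (lo, hi) in BANDS.items():
        if band == "high-beta":
            if lo <= frequency <= hi:
                return band
        elif lo <= frequency < hi:
            return band
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def _pct(count: int, total: int) -> float:
    """Percent to one decimal, half-away-from-zero (table convention)."""
    if total == 0:
        return 0.0
    raw = Decimal(100 * count) / Decimal(total)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(peaks: list[HemispherePeak], med_state: str) -> CohortSummary:
    """Participant-level detection counts and hemisphere-level band counts.

    A participant counts as detected if at least one hemisphere has a
    detected peak, bilateral if both do. Band percentages use the number
    of detected hemispheres as denominator, reported explicitly in the
    summary. Percentages are recomputable from the counts.
    """
    rows = [p for p in peaks if p.med_state == med_state]
    if not rows:
        raise ValueError(f"no records for med_state={med_state!r}")
    seen: set[tuple[str, str]] = set()
    for p in rows:
        key = (p.participant, p.hemisphere)
        if key in seen:
            raise ValueError(f"duplicate hemisphere record {key}")
        seen.add(key)

    by_participant: dict[str, list[HemispherePeak]] = {}
    for p in rows:
        by_participant.setdefault(p.participant, []).append(p)

    n = len(by_participant)
    bilateral = unilateral = none = 0
    for recs in by_participant.values():
        k = sum(r.detected for r in recs)
        if k >= 2:
            bilateral += 1
        elif k == 1:
            unilateral += 1
        else:
            none += 1
    detected = bilateral + unilateral

    detected_hemis = [p for p in rows if p.detected]
    band_counts = {band: 0 for band in BANDS}
    for p in detected_hemis:
        band_counts[classify_band(p.frequency)] += 1
    denom = len(detected_hemis)

    return CohortSummary(
        med_state=med_state,
        participants=n,
        detected=detected,
        detected_pct=_pct(detected, n),
        bilateral=bilateral,
        bilateral_pct=_pct(bilateral, n),
        unilateral=unilateral,
        unilateral_pct=_pct(unilateral, n),
        none=none,
        none_pct=_pct(none, n),
        hemispheres_total=len(rows),
        hemisphere_detected_pct=_pct(denom, len(rows)),
        hemisphere_denominator=denom,
        band_counts=band_counts,
        band_pct={band: _pct(c, denom) for band, c in band_counts.items()},
    )


def read_roster_csv(path) -> list[HemispherePeak]:
    """Read a cohort roster CSV (participant, target, hemisphere, med_state,
    detected, freq_hz, amp_uvp) into :class:`HemispherePeak` records."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        detected = bool(row["detected"])
        out.append(
            HemispherePeak(
                participant=str(row["participant"]),
                target=str(row["target"]),
                hemisphere=str(row["hemisphere"]),
                med_state=str(row["med_state"]),
                detected=detected,
                frequency=float(row["freq_hz"]) if detected else None,
                amplitude=float(row["amp_uvp"]) if detected else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TEED
# ---------------------------------------------------------------------------

def teed(params: TeedParams, duration: float = 1.0) -> float:
    """Total electrical energy delivered over ``duration`` seconds, in µJ.

    Current-controlled form of the established voltage-based formula:
    I² · Z · rate · pulse_width · duration, with I in amps, Z in ohms and
    pulse width in seconds. Quadratic in amplitude and additive over
    concatenated intervals.
    """
    i_amp = params.amplitude * 1e-3
    pw_s = params.pulse_width * 1e-6
    joules = i_amp**2 * params.impedance * params.rate * pw_s * duration
    return joules * 1e6


# ---------------------------------------------------------------------------
# Time in state
# ---------------------------------------------------------------------------

def time_in_state(trace: SessionTrace, config: ControllerConfig,
                  hemisphere: str = "left") -> list[dict]:
    """Per-day fractions of unblanked samples below/between/above threshold.

    Dual mode reports {below, between, above}; single mode {below, above}.
    Fractions sum to 1 within each day by construction. Partial days
    report their coverage fraction (samples present / samples in a full
    day at the 100 ms cadence).
    """
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    power = trace.band_power[hemisphere]
    blanked = trace.blanked[hemisphere]
    days = np.floor(trace.times / _SECONDS_PER_DAY).astype(int)
    regions = ("below", "between", "above") if config.mode == "dual" else ("below", "above")
    step_s = float(np.median(np.diff(trace.times))) if len(trace.times) > 1 else 0.1
    full_day = _SECONDS_PER_DAY / step_s

    # vectorized comparator, same tie rules as controller.compare
    if config.mode == "dual":
        is_above = power > config.upper_lfp_threshold
        is_below = power < config.lower_lfp_threshold
        region_of = np.where(is_above, "above", np.where(is_below, "below", "between"))
    else:
        region_of = np.where(power > config.single_threshold, "above", "below")

    out = []
    for d in np.unique(days):
        sel = (days == d) & ~blanked
        total = int(sel.sum())
        fractions = {r: 0.0 for r in regions}
        if total:
            for r in regions:
                fractions[r] = int((region_of[sel] == r).sum()) / total
        out.append(
            {
                "day": int(d),
                "fractions": fractions,
                "unblanked_samples": total,
                "coverage": float((days == d).sum() / full_day),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Exact binomial sample size
# ---------------------------------------------------------------------------

def exact_binomial_sample_size(
    p0: float, p1: float, alpha: float, power: float, max_n: int = 10_000
) -> tuple[int, int]:
    """Smallest n for a one-sided exact binomial test of p0 vs p1 > p0.

    Returns ``(n, c)`` where c is the smallest rejection threshold with
    exact size P(X ≥ c | p0) ≤ alpha, and n is the smallest sample size
    for which that threshold also attains exact power P(X ≥ c | p1) ≥
    power. The search enumerates n upward and is sawtooth-aware: exact
    power is not monotone in n, and the first feasible n is returned.
    """
    if not (0 < p0 < p1 <= 1):
        raise ValueError("need 0 < p0 < p1 <= 1")
    if not (0 < alpha < 1) or not (0 <= power < 1):
        raise ValueError("need 0 < alpha < 1 and 0 <= power < 1")
    for n in range(1, max_n + 1):
        # smallest c with exact size <= alpha
        tail = sstats.binom.sf(np.arange(n + 1) - 1, n, p0)
        feasible = np.nonzero(tail <= alpha)[0]
        if len(feasible) == 0:
            continue
        c = int(feasible[0])
        if sstats.binom.sf(c - 1, n, p1) >= power:
            return n, c
    raise ValueError(f"no feasible design with n <= {max_n}")
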