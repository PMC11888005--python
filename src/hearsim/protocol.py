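"""Screening protocol: normative ranges, tympanogram typing, ground truth,
referral logic and event-log compliance auditing.

The screening protocol is fixed-level: tones at the screening level
(default 20 dB HL, the conventional "normal hearing" level) at each
required frequency (default 1000/2000/4000 Hz) in each ear. An ear passes
audiometry only if the subject responds at every required frequency; any
non-response refers that ear. Otoscopy refers on any visible abnormality;
tympanometry refers on a type B or C trace or an out-of-range ear canal
volume. Medical concerns (otoscopy/tympanometry) route to a physician,
audiologic concerns (audiometry) to an audiologist, and both together to
both — the standard screening disposition map.
"""

from __future__ import annotations

import json
from collections import Counter
from enum import Enum
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .patients import (
    AUDIOMETRIC_FREQUENCIES,
    AgeBand,
    BasePatient,
    TympanogramProfile,
)
from .session import Event, EventKind, ScreeningSession, TechnicianNotes

__all__ = [
    "ComplianceResult",
    "Finding",
    "FindingCode",
    "GroundTruth",
    "NormativeRanges",
    "ProtocolConfig",
    "Recommendation",
    "TympType",
    "audit_session",
    "check_compliance",
    "classify_tympanogram",
    "derive_ground_truth",
    "load_norms",
    "load_protocol",
    "recommend",
]


class ProtocolConfig(BaseModel):
    """Parameters of the fixed-level screening protocol."""

    model_config = ConfigDict(frozen=True)

    screening_level: int = 20
    required_frequencies: tuple[int, ...] = (1000, 2000, 4000)
    ears_required: tuple[str, ...] = ("left", "right")
    enforce_order: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ProtocolConfig":
        if not self.required_frequencies:
            raise ValueError("required_frequencies must be nonempty")
        bad = [f for f in self.required_frequencies if f not in AUDIOMETRIC_FREQUENCIES]
        if bad:
            raise ValueError(f"frequencies {bad} not in device set {AUDIOMETRIC_FREQUENCIES}")
        return self


class BandRange(BaseModel):
    model_config = ConfigDict(frozen=True)

    min: float
    max: float

    @model_validator(mode="after")
    def _check(self) -> "BandRange":
        if not self.min < self.max:
            raise ValueError(f"range min {self.min} must be < max {self.max}")
        return self

    def contains(self, x: float) -> bool:
        return self.min <= x <= self.max


class NormativeRanges(BaseModel):
    """Normative tympanometry ranges; ECV is age-band specific.

    Defaults are conventional screening values: middle-ear pressure
    -150..+100 daPa, static compliance 0.3..1.5 mL, ear canal volume
    0.4..1.0 mL for children and 0.6..2.0 mL for adults.
    """

    model_config = ConfigDict(frozen=True)

    peak_pressure_dapa: BandRange = BandRange(min=-150, max=100)
    static_compliance_ml: BandRange = BandRange(min=0.3, max=1.5)
    ear_canal_volume_ml: dict[AgeBand, BandRange] = Field(
        default_factory=lambda: {
            AgeBand.child: BandRange(min=0.4, max=1.0),
            AgeBand.adult: BandRange(min=0.6, max=2.0),
        }
    )


def load_protocol(path: str | Path) -> ProtocolConfig:
    """Load ``protocol.json``; raises ``ValueError`` on invalid content."""
    try:
        return ProtocolConfig.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))
    except (json.JSONDecodeError, ValidationError) as exc:
        raise ValueError(f"invalid protocol config {path}: {exc}")


def load_norms(path: str | Path) -> NormativeRanges:
    """Load ``norms.json``; raises ``ValueError`` on invalid content."""
    try:
        return NormativeRanges.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))
    except (json.JSONDecodeError, ValidationError) as exc:
        raise ValueError(f"invalid norms config {path}: {exc}")


class TympType(str, Enum):
    A = "A"
    As = "As"
    Ad = "Ad"
    B = "B"
    C = "C"


class Recommendation(str, Enum):
    passed = "pass"
    refer_audiologist = "refer_audiologist"
    refer_physician = "refer_physician"
    refer_both = "refer_both"


def classify_tympanogram(
    profile: TympanogramProfile,
    age_band: AgeBand,
    norms: NormativeRanges | None = None,
) -> tuple[TympType, str]:
    """Type a tympanogram and give its screening result.

    Flat trace -> B. Peak at pressure below the normative minimum -> C.
    Otherwise A/As/Ad by static compliance within/below/above the normative
    compliance range. The screening result is ``abnormal`` iff the type is
    B or C or the ear canal volume falls outside the age band's range; the
    shallow/deep A variants alone do not refer at screening.
    """
    norms = norms or NormativeRanges()
    if not profile.peak_present:
        ttype = TympType.B
    elif profile.peak_pressure_dapa < norms.peak_pressure_dapa.min:
        ttype = TympType.C
    elif profile.static_compliance_ml < norms.static_compliance_ml.min:
        ttype = TympType.As
    elif profile.static_compliance_ml > norms.static_compliance_ml.max:
        ttype = TympType.Ad
    else:
        ttype = TympType.A
    ecv_ok = norms.ear_canal_volume_ml[age_band].contains(profile.ear_canal_volume_ml)
    abnormal = ttype in (TympType.B, TympType.C) or not ecv_ok
    return ttype, ("abnormal" if abnormal else "normal")


class GroundTruth(BaseModel):
    """The correct per-ear results and disposition for a base patient."""

    model_config = ConfigDict(frozen=True)

    otoscopy: dict[str, str]  # ear -> normal | abnormal
    tympanometry: dict[str, str]  # ear -> normal | abnormal
    tymp_types: dict[str, TympType]
    audiometry: dict[str, str]  # ear -> pass | refer
    recommendation: Recommendation
    explanation: str

    def result_for(self, item: str) -> str:
        """Correct answer for a graded slot such as ``otoscopy_left``."""
        if item == "final_recommendation":
            return self.recommendation.value
        proc, _, side = item.rpartition("_")
        return getattr(self, proc)[side]

    @property
    def all_normal(self) -> bool:
        return self.recommendation == Recommendation.passed


def recommend(
    oto_results: dict[str, str],
    tymp_results: dict[str, str],
    aud_results: dict[str, str],
) -> Recommendation:
    """Map the six per-ear results to a screening disposition.

    Any abnormal otoscopy or tympanometry raises the medical flag; any
    audiometric refer raises the audiologic flag. (medical, audiologic) ->
    pass / refer_audiologist / refer_physician / refer_both.
    """
    for results, allowed, name in (
        (oto_results, {"normal", "abnormal"}, "otoscopy"),
        (tymp_results, {"normal", "abnormal"}, "tympanometry"),
        (aud_results, {"pass", "refer"}, "audiometry"),
    ):
        for side in ("left", "right"):
            if side not in results:
                raise ValueError(f"missing {name} result for {side} ear")
            if results[side] not in allowed:
                raise ValueError(f"invalid {name} result {results[side]!r}")
    medical = "abnormal" in oto_results.values() or "abnormal" in tymp_results.values()
    audiologic = "refer" in aud_results.values()
    return {
        (False, False): Recommendation.passed,
        (False, True): Recommendation.refer_audiologist,
        (True, False): Recommendation.refer_physician,
        (True, True): Recommendation.refer_both,
    }[(medical, audiologic)]


def derive_ground_truth(
    base: BasePatient,
    protocol: ProtocolConfig | None = None,
    norms: NormativeRanges | None = None,
) -> GroundTruth:
    """Derive the correct screening results from a base patient's profile.

    Deterministic: truth comes from authored thresholds and profiles, never
    from simulated response draws, so grading is stable even for subjects
    with inconsistent response behaviour. An ear's audiometry refers iff
    any required-frequency threshold exceeds the screening level.
    """
    protocol = protocol or ProtocolConfig()
    norms = norms or NormativeRanges()
    oto, tymp, types, aud = {}, {}, {}, {}
    for side in ("left", "right"):
        ear = base.ear(side)
        oto[side] = "normal" if ear.otoscopy.is_normal else "abnormal"
        ttype, result = classify_tympanogram(ear.tympanogram, base.age_band, norms)
        tymp[side], types[side] = result, ttype
        refer = any(
            ear.audiogram.threshold_at(f) > protocol.screening_level
            for f in protocol.required_frequencies
        )
        aud[side] = "refer" if refer else "pass"
    return GroundTruth(
        otoscopy=oto,
        tympanometry=tymp,
        tymp_types=types,
        audiometry=aud,
        recommendation=recommend(oto, tymp, aud),
        explanation=base.explanation,
    )


# ---------------------------------------------------------------------------
# Compliance auditing

class FindingCode(str, Enum):
    MISSING_PROCEDURE = "MISSING_PROCEDURE"
    EAR_NOT_TESTED = "EAR_NOT_TESTED"
    MISSING_FREQUENCY = "MISSING_FREQUENCY"
    WRONG_LEVEL = "WRONG_LEVEL"
    OUT_OF_ORDER = "OUT_OF_ORDER"
    INCOMPLETE_NOTES = "INCOMPLETE_NOTES"


class Finding(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: FindingCode
    detail: str
    severity: str = "error"  # OUT_OF_ORDER downgrades to "warning"


class ComplianceResult(BaseModel):
    """Audit outcome: findings (empty = fully compliant) plus tallies."""

    model_config = ConfigDict(frozen=True)

    findings: list[Finding]
    presentations: dict[str, int]  # "ear@freq" -> tone count
    positive_responses: int
    exams: dict[str, int]  # procedure -> exam count

    @property
    def compliant(self) -> bool:
        return not self.findings


_PROC_EVENTS = {
    "otoscopy": EventKind.oto_exam,
    "tympanometry": EventKind.tymp_exam,
    "audiometry": EventKind.tone_presented,
}


def check_compliance(
    event_log: list[Event],
    notes: TechnicianNotes,
    protocol: ProtocolConfig | None = None,
    *,
    closed: bool = True,
) -> ComplianceResult:
    """Audit a closed session's event log against the protocol.

    Emits at most one finding per independent deviation: a procedure never
    run at all is one MISSING_PROCEDURE (its per-ear gaps are subsumed); a
    procedure run in one ear only is one EAR_NOT_TESTED per missing ear
    (subsuming that ear's per-frequency gaps); otherwise audiometry gaps
    surface per (ear, frequency) as MISSING_FREQUENCY when no tone was
    presented there, or WRONG_LEVEL when tones were presented but none at
    the screening level. OUT_OF_ORDER (warning) fires when the first
    occurrences of the three procedures are not in otoscopy ->
    tympanometry -> audiometry order. INCOMPLETE_NOTES fires once per
    missing note slot.
    """
    if not closed:
        raise ValueError("compliance audit requires a closed session")
    protocol = protocol or ProtocolConfig()
    findings: list[Finding] = []

    ears_by_proc: dict[str, set[str]] = {p: set() for p in _PROC_EVENTS}
    tones: Counter[tuple[str, int]] = Counter()  # (ear, freq) -> count, any level
    on_level: Counter[tuple[str, int]] = Counter()  # at screening level
    presentations: Counter[str] = Counter()
    positive = 0
    exams: Counter[str] = Counter()
    first_seen: dict[str, float] = {}

    for event in event_log:
        for proc, kind in _PROC_EVENTS.items():
            if event.kind == kind:
                ear = event.params["ear"]
                ears_by_proc[proc].add(ear)
                first_seen.setdefault(proc, event.timestamp)
                exams[proc] += 1
        if event.kind == EventKind.tone_presented:
            ear = event.params["ear"]
            freq = event.params["frequency"]
            tones[(ear, freq)] += 1
            presentations[f"{ear}@{freq}"] += 1
            if event.params["level"] == protocol.screening_level:
                on_level[(ear, freq)] += 1
            if event.outcome.get("responded"):
                positive += 1

    for proc in ("otoscopy", "tympanometry", "audiometry"):
        if not ears_by_proc[proc]:
            findings.append(Finding(
                code=FindingCode.MISSING_PROCEDURE,
                detail=f"{proc} was never performed",
            ))
            continue
        for ear in protocol.ears_required:
            if ear not in ears_by_proc[proc]:
                findings.append(Finding(
                    code=FindingCode.EAR_NOT_TESTED,
                    detail=f"{proc} not performed on the {ear} ear",
                ))

    if ears_by_proc["audiometry"]:
        for ear in protocol.ears_required:
            if ear not in ears_by_proc["audiometry"]:
                continue  # already an EAR_NOT_TESTED finding
            for freq in protocol.required_frequencies:
                if tones[(ear, freq)] == 0:
                    findings.append(Finding(
                        code=FindingCode.MISSING_FREQUENCY,
                        detail=f"no tone presented at {freq} Hz in the {ear} ear",
                    ))
                elif on_level[(ear, freq)] == 0:
                    findings.append(Finding(
                        code=FindingCode.WRONG_LEVEL,
                        detail=(
                            f"{freq} Hz in the {ear} ear was never presented at the "
                            f"screening level ({protocol.screening_level} dB HL)"
                        ),
                    ))

    if protocol.enforce_order:
        order = sorted(first_seen, key=first_seen.__getitem__)
        expected = [p for p in ("otoscopy", "tympanometry", "audiometry") if p in first_seen]
        if order != expected:
            findings.append(Finding(
                code=FindingCode.OUT_OF_ORDER,
                detail=f"procedures started in order {' -> '.join(order)}; "
                       f"protocol order is otoscopy -> tympanometry -> audiometry",
                severity="warning",
            ))

    for slot in notes.missing_slots():
        findings.append(Finding(
            code=FindingCode.INCOMPLETE_NOTES,
            detail=f"notes missing {slot.replace('_', ' ')}",
        ))

    return ComplianceResult(
        findings=findings,
        presentations=dict(presentations),
        positive_responses=positive,
        exams=dict(exams),
    )


def audit_session(session: ScreeningSession, protocol: ProtocolConfig | None = None) -> ComplianceResult:
    """Convenience wrapper: audit a (closed) session object."""
    return check_compliance(session.event_log, session.notes, protocol, closed=session.closed)
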