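"""Virtual-patient data model, roster loading and demographic randomization.

A *base patient* is a ground-truth clinical case: per-ear pure-tone
thresholds, tympanometry parameters and an otoscopic finding, plus a
case-history template and an explanation of the correct screening results.
Each training run presents a demographically randomized *presentation* of a
base patient — new name, sex, slightly jittered age and re-rendered
backstory — while every clinical field stays exactly as authored. This
obfuscates case identity across repeat sessions and multiplies the apparent
patient pool (roster size x name-pool size distinct identities).
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .response import ResponseParams

__all__ = [
    "AUDIOMETRIC_FREQUENCIES",
    "AgeBand",
    "AudiogramProfile",
    "BasePatient",
    "EarProfiles",
    "NameEntry",
    "OtoscopyCategory",
    "OtoscopyFinding",
    "PatientPresentation",
    "RosterError",
    "Sex",
    "TympanogramProfile",
    "count_profile_space",
    "default_name_pool",
    "default_roster",
    "load_name_pool",
    "load_roster",
    "randomize_presentation",
    "write_roster",
]

#: Audiometric frequencies the virtual audiometer supports (Hz).
AUDIOMETRIC_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)

#: Screening frequencies every roster patient must carry thresholds for.
SCREENING_FREQUENCIES: tuple[int, ...] = (1000, 2000, 4000)

_DATA_DIR = Path(__file__).parent / "data"


class RosterError(ValueError):
    """Raised when a roster or name-pool file fails validation.

    Carries the offending patient id and field path where known, so that a
    facilitator editing a roster file can locate the problem.
    """

    def __init__(self, message: str, *, patient_id: str | None = None, field: str | None = None):
        self.patient_id = patient_id
        self.field = field
        prefix = ""
        if patient_id is not None:
            prefix += f"patient {patient_id!r}: "
        if field is not None:
            prefix += f"field {field!r}: "
        super().__init__(prefix + message)


class AgeBand(str, Enum):
    child = "child"
    adult = "adult"


class Sex(str, Enum):
    female = "female"
    male = "male"


class OtoscopyCategory(str, Enum):
    clear_normal = "clear_normal"
    occluding_cerumen = "occluding_cerumen"
    erythema = "erythema"
    effusion = "effusion"
    perforation = "perforation"
    pe_tube = "pe_tube"
    foreign_body = "foreign_body"
    other = "other"


class AudiogramProfile(BaseModel):
    """Per-ear hearing thresholds in dB HL, keyed by frequency in Hz.

    ``inconsistency`` optionally attaches psychometric response parameters;
    absent means the simulated subject responds deterministically (step
    function at threshold).
    """

    model_config = ConfigDict(frozen=True)

    thresholds: dict[int, int]
    inconsistency: Optional[ResponseParams] = None

    @model_validator(mode="after")
    def _check(self) -> "AudiogramProfile":
        for freq, thr in self.thresholds.items():
            if freq not in AUDIOMETRIC_FREQUENCIES:
                raise ValueError(f"unsupported audiometric frequency {freq} Hz")
            if not (-10 <= thr <= 120):
                raise ValueError(f"threshold {thr} dB HL at {freq} Hz outside -10..120")
        return self

    def threshold_at(self, frequency: int) -> int:
        if frequency not in self.thresholds:
            raise KeyError(f"no threshold authored at {frequency} Hz")
        return self.thresholds[frequency]


class TympanogramProfile(BaseModel):
    """Tympanometry result for one ear.

    A flat (type B) trace has no peak; then peak pressure and static
    compliance are undefined and must be omitted. Ear canal volume is always
    measured.
    """

    model_config = ConfigDict(frozen=True)

    peak_present: bool
    peak_pressure_dapa: Optional[int] = None
    static_compliance_ml: Optional[float] = None
    ear_canal_volume_ml: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "TympanogramProfile":
        if self.peak_present:
            if self.peak_pressure_dapa is None or self.static_compliance_ml is None:
                raise ValueError("peaked tympanogram requires peak_pressure_dapa and static_compliance_ml")
            if not (-400 <= self.peak_pressure_dapa <= 200):
                raise ValueError(f"peak pressure {self.peak_pressure_dapa} daPa outside -400..200")
            if self.static_compliance_ml < 0:
                raise ValueError("static compliance must be >= 0")
        else:
            if self.peak_pressure_dapa is not None or self.static_compliance_ml is not None:
                raise ValueError("flat tympanogram must not carry peak pressure or compliance")
        return self


class OtoscopyFinding(BaseModel):
    model_config = ConfigDict(frozen=True)

    category: OtoscopyCategory
    is_normal: bool
    description: str
    image_ref: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "OtoscopyFinding":
        if self.is_normal != (self.category == OtoscopyCategory.clear_normal):
            raise ValueError("is_normal must be true exactly when category is clear_normal")
        return self


class EarProfiles(BaseModel):
    """All three modality ground truths for one ear."""

    model_config = ConfigDict(frozen=True)

    audiogram: AudiogramProfile
    tympanogram: TympanogramProfile
    otoscopy: OtoscopyFinding


class BasePatient(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    age_years: int = Field(ge=0, le=120)
    age_band: AgeBand
    case_history_template: str
    explanation: str
    left: EarProfiles
    right: EarProfiles

    @model_validator(mode="after")
    def _check(self) -> "BasePatient":
        is_child = self.age_years < 18
        if is_child != (self.age_band == AgeBand.child):
            raise ValueError(f"age_band {self.age_band.value!r} inconsistent with age {self.age_years}")
        for side in ("left", "right"):
            have = self.ear(side).audiogram.thresholds
            for freq in SCREENING_FREQUENCIES:
                if freq not in have:
                    raise ValueError(
                        f"{side}.audiogram.thresholds missing the {freq} Hz screening frequency"
                    )
        return self

    def ear(self, side: str) -> EarProfiles:
        if side not in ("left", "right"):
            raise ValueError(f"ear must be 'left' or 'right', got {side!r}")
        return getattr(self, side)


class NameEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    sex: Sex


class PatientPresentation(BaseModel):
    """A randomized instance of a base patient as shown to the trainee.

    ``base`` retains the full clinical ground truth (hidden from trainee
    display); only the demographic surface differs from the base case.
    """

    model_config = ConfigDict(frozen=True)

    base: BasePatient
    display_name: str
    sex: Sex
    age_years: int
    backstory: str
    seed: int

    @property
    def base_id(self) -> str:
        return self.base.id


# ---------------------------------------------------------------------------
# Roster / name-pool I/O

def _wrap_validation_error(exc: ValidationError, patient_id: str | None) -> RosterError:
    err = exc.errors()[0]
    field = ".".join(str(p) for p in err["loc"]) or None
    return RosterError(err["msg"], patient_id=patient_id, field=field)


def load_roster(path: str | Path) -> list[BasePatient]:
    """Load and validate a JSON patient roster.

    The file holds ``{"patients": [...]}``. Raises :class:`RosterError`
    naming the offending patient id and field path on any violation:
    parse failure, duplicate id, missing required field, or a
    threshold/volume out of range. Every patient must carry thresholds for
    both ears at every supported screening frequency used by a protocol
    (checked again at protocol load; here the audiometric-set membership
    and range invariants are enforced).
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise RosterError(f"roster file not found: {path}")
    except json.JSONDecodeError as exc:
        raise RosterError(f"roster is not valid JSON: {exc}")
    if not isinstance(raw, dict) or "patients" not in raw:
        raise RosterError("roster must be an object with a 'patients' list")
    patients: list[BasePatient] = []
    seen: set[str] = set()
    for entry in raw["patients"]:
        pid = entry.get("id") if isinstance(entry, dict) else None
        try:
            patient = BasePatient.model_validate(entry)
        except ValidationError as exc:
            raise _wrap_validation_error(exc, pid)
        if patient.id in seen:
            raise RosterError("duplicate patient id", patient_id=patient.id, field="id")
        seen.add(patient.id)
        patients.append(patient)
    return patients


def write_roster(patients: list[BasePatient], path: str | Path) -> None:
    """Serialize a roster so that :func:`load_roster` round-trips it."""
    payload = {"patients": [p.model_dump(mode="json", exclude_none=True) for p in patients]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_name_pool(path: str | Path) -> list[NameEntry]:
    """Load the sex-tagged name pool (``{"names": [{"name", "sex"}, ...]}``)."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise RosterError(f"name pool file not found: {path}")
    except json.JSONDecodeError as exc:
        raise RosterError(f"name pool is not valid JSON: {exc}")
    if not isinstance(raw, dict) or "names" not in raw:
        raise RosterError("name pool must be an object with a 'names' list")
    try:
        pool = [NameEntry.model_validate(e) for e in raw["names"]]
    except ValidationError as exc:
        raise _wrap_validation_error(exc, None)
    if not pool:
        raise RosterError("name pool is empty")
    return pool


def default_roster() -> list[BasePatient]:
    """The bundled ten-case roster (two normals plus eight pathologies)."""
    return load_roster(_DATA_DIR / "roster.json")


def default_name_pool() -> list[NameEntry]:
    """The bundled pool of 100 sex-tagged names."""
    return load_name_pool(_DATA_DIR / "names.json")


# ---------------------------------------------------------------------------
# Demographic randomization

_PRONOUNS = {
    Sex.female: {"subject": "she", "object": "her", "possessive": "her"},
    Sex.male: {"subject": "he", "object": "him", "possessive": "his"},
}

# Age-band bounds used when clamping jittered ages. Children stay school-
# screening age; adults stay adult.
_BAND_BOUNDS = {AgeBand.child: (4, 17), AgeBand.adult: (18, 95)}


def _jitter_age(age: int, band: AgeBand, rng: np.random.Generator) -> int:
    spread = max(1, round(0.1 * age))
    lo, hi = _BAND_BOUNDS[band]
    jittered = age + int(rng.integers(-spread, spread + 1))
    return int(min(hi, max(lo, jittered)))


def randomize_presentation(
    base: BasePatient,
    name_pool: list[NameEntry],
    seed: int,
) -> PatientPresentation:
    """Build a demographically randomized presentation of ``base``.

    Deterministic in ``(base, name_pool, seed)``: the name (and with it the
    sex, since pool entries are sex-tagged) is drawn uniformly from the
    pool, the age receives a uniform integer jitter of up to ±10 % of the
    base age clamped to the age band, and the backstory template is
    rendered with the new demographics. Clinical ground truth is carried
    over untouched.
    """
    if not name_pool:
        raise RosterError("name pool is empty")
    rng = np.random.default_rng(seed)
    entry = name_pool[int(rng.integers(len(name_pool)))]
    age = _jitter_age(base.age_years, base.age_band, rng)
    pronouns = _PRONOUNS[entry.sex]
    first_name = entry.name.split()[0]
    backstory = base.case_history_template.format(
        name=entry.name,
        first_name=first_name,
        age=age,
        sex=entry.sex.value,
        pronoun_subject=pronouns["subject"],
        pronoun_object=pronouns["object"],
        pronoun_possessive=pronouns["possessive"],
    )
    return PatientPresentation(
        base=base,
        display_name=entry.name,
        sex=entry.sex,
        age_years=age,
        backstory=backstory,
        seed=seed,
    )


def count_profile_space(roster: list[BasePatient], name_pool: list[NameEntry]) -> int:
    """Number of distinct (base case, name) patient identities.

    Sex is determined by the name tag and age jitter is excluded, so this
    counts the guaranteed-distinct identities; with the bundled roster and
    pool it is 10 x 100 = 1000, before age variants multiply it further.
    """
    return len(roster) * len(name_pool)
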