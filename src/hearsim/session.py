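"""Device/session state machine with an append-only event log.

Models the virtual screening audiometer: mode and ear selection, the Oto
and Tymp exam buttons, tone presentation, and technician note capture.
Every trainee action appends a timestamped event; the log together with the
session seed is a sufficient statistic — replaying it against a fresh
session reproduces every outcome, which is what makes headless scripted
sessions and after-the-fact protocol auditing possible.

Timestamps come from an injectable clock so tests and scripted runs can use
a synthetic clock and obtain fully deterministic records.
"""

from __future__ import annotations

import json
import time
from enum import Enum
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .patients import AUDIOMETRIC_FREQUENCIES, PatientPresentation
from .response import simulate_response

__all__ = [
    "DEVICE_LEVEL_MAX",
    "DEVICE_LEVEL_MIN",
    "DEVICE_LEVEL_STEP",
    "Ear",
    "Event",
    "EventKind",
    "ManualClock",
    "Mode",
    "ScreeningSession",
    "SessionError",
    "TechnicianNotes",
    "load_actions",
    "run_script",
    "start_session",
]

#: Device level range in dB HL (5 dB attenuator steps).
DEVICE_LEVEL_MIN = -10
DEVICE_LEVEL_MAX = 90
DEVICE_LEVEL_STEP = 5


class SessionError(RuntimeError):
    """An action violated the device/session contract."""


class Mode(str, Enum):
    otoscopy = "otoscopy"
    tympanometry = "tympanometry"
    audiometry = "audiometry"


class Ear(str, Enum):
    left = "left"
    right = "right"


class EventKind(str, Enum):
    select_mode = "select_mode"
    select_ear = "select_ear"
    set_level = "set_level"
    set_frequency = "set_frequency"
    oto_exam = "oto_exam"
    tymp_exam = "tymp_exam"
    tone_presented = "tone_presented"
    notes_saved = "notes_saved"


class Event(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: EventKind
    timestamp: float
    params: dict[str, Any] = {}
    outcome: dict[str, Any] = {}


class ProcedureResult(str, Enum):
    normal = "normal"
    abnormal = "abnormal"


class ScreenResult(str, Enum):
    passed = "pass"
    refer = "refer"


class EarNotes(BaseModel):
    """Trainee-entered result + free comment for one procedure on one ear."""

    model_config = ConfigDict(frozen=True)

    result: Optional[str] = None
    comment: str = ""


_RESULT_ENUMS = {
    "otoscopy": {"normal", "abnormal"},
    "tympanometry": {"normal", "abnormal"},
    "audiometry": {"pass", "refer"},
}


class TechnicianNotes(BaseModel):
    """Per-procedure, per-ear trainee results plus the final recommendation.

    Partial notes are allowed while a session is open; completeness is a
    grading-time concern, surfaced by :meth:`missing_slots`.
    """

    model_config = ConfigDict(frozen=True)

    otoscopy_left: EarNotes = EarNotes()
    otoscopy_right: EarNotes = EarNotes()
    tympanometry_left: EarNotes = EarNotes()
    tympanometry_right: EarNotes = EarNotes()
    audiometry_left: EarNotes = EarNotes()
    audiometry_right: EarNotes = EarNotes()
    final_recommendation: Optional[str] = None
    final_comment: str = ""

    @model_validator(mode="after")
    def _check(self) -> "TechnicianNotes":
        for proc, allowed in _RESULT_ENUMS.items():
            for side in ("left", "right"):
                note: EarNotes = getattr(self, f"{proc}_{side}")
                if note.result is not None and note.result not in allowed:
                    raise ValueError(
                        f"{proc} result must be one of {sorted(allowed)}, got {note.result!r}"
                    )
        if self.final_recommendation is not None:
            from .protocol import Recommendation  # local import to avoid a cycle

            Recommendation(self.final_recommendation)
        return self

    def missing_slots(self) -> list[str]:
        missing = [
            f"{proc}_{side}"
            for proc in ("otoscopy", "tympanometry", "audiometry")
            for side in ("left", "right")
            if getattr(self, f"{proc}_{side}").result is None
        ]
        if self.final_recommendation is None:
            missing.append("final_recommendation")
        return missing

    @property
    def complete(self) -> bool:
        return not self.missing_slots()


class ManualClock:
    """Synthetic clock: starts at ``t0`` and advances ``tick`` per reading."""

    def __init__(self, t0: float = 0.0, tick: float = 1.0):
        self._t = t0
        self._tick = tick

    def __call__(self) -> float:
        t = self._t
        self._t += self._tick
        return t


class ScreeningSession:
    """One trainee's screening of one patient presentation.

    All stochastic behaviour (the subject's hand raises) flows from the
    session seed, so two sessions with the same presentation, seed and
    action sequence produce identical outcomes.
    """

    def __init__(
        self,
        technician_name: str,
        presentation: PatientPresentation,
        seed: int,
        clock: Callable[[], float] | None = None,
    ):
        if not technician_name or not technician_name.strip():
            raise SessionError("technician_name is required")
        self.technician_name = technician_name
        self.presentation = presentation
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self._clock = clock if clock is not None else time.time
        self.mode: Optional[Mode] = None
        self.selected_ear: Optional[Ear] = None
        self.selected_level: int = 20
        self.selected_frequency: int = 1000
        self.event_log: list[Event] = []
        self.notes: TechnicianNotes = TechnicianNotes()
        self.started_at: float = self._clock()
        self.first_test_at: Optional[float] = None
        self.ended_at: Optional[float] = None

    # -- internal helpers --------------------------------------------------

    def _log(self, kind: EventKind, params: dict | None = None, outcome: dict | None = None) -> Event:
        if self.ended_at is not None:
            raise SessionError("session is closed")
        event = Event(kind=kind, timestamp=self._clock(), params=params or {}, outcome=outcome or {})
        self.event_log.append(event)
        return event

    def _mark_first_test(self, timestamp: float) -> None:
        if self.first_test_at is None:
            self.first_test_at = timestamp

    def _require_ear(self) -> Ear:
        if self.selected_ear is None:
            raise SessionError("no ear selected")
        return self.selected_ear

    @staticmethod
    def _validate_level(level: int) -> int:
        level = int(level)
        if not (DEVICE_LEVEL_MIN <= level <= DEVICE_LEVEL_MAX) or level % DEVICE_LEVEL_STEP != 0:
            raise SessionError(
                f"level {level} dB HL outside device range "
                f"{DEVICE_LEVEL_MIN}..{DEVICE_LEVEL_MAX} in {DEVICE_LEVEL_STEP} dB steps"
            )
        return level

    @staticmethod
    def _validate_frequency(frequency: int) -> int:
        frequency = int(frequency)
        if frequency not in AUDIOMETRIC_FREQUENCIES:
            raise SessionError(
                f"frequency {frequency} Hz unsupported; device set is {AUDIOMETRIC_FREQUENCIES}"
            )
        return frequency

    # -- device controls ---------------------------------------------------

    def select_mode(self, mode: Mode | str) -> None:
        self.mode = Mode(mode)
        self._log(EventKind.select_mode, {"mode": self.mode.value})

    def select_ear(self, ear: Ear | str | None) -> None:
        self.selected_ear = None if ear in (None, "none") else Ear(ear)
        self._log(EventKind.select_ear, {"ear": self.selected_ear.value if self.selected_ear else "none"})

    def set_level(self, level: int) -> None:
        self.selected_level = self._validate_level(level)
        self._log(EventKind.set_level, {"level": self.selected_level})

    def set_frequency(self, frequency: int) -> None:
        self.selected_frequency = self._validate_frequency(frequency)
        self._log(EventKind.set_frequency, {"frequency": self.selected_frequency})

    # -- exams -------------------------------------------------------------

    def oto_exam(self, ear: Ear | str | None = None):
        """Press the Oto button: returns the selected ear's otoscopic finding.

        An inline ``ear`` argument sets the ear selector silently (the exam
        event records the ear), keeping logs compact and replayable.
        """
        if ear is not None:
            self.selected_ear = Ear(ear)
        side = self._require_ear()
        finding = self.presentation.base.ear(side.value).otoscopy
        event = self._log(
            EventKind.oto_exam,
            {"ear": side.value},
            {"category": finding.category.value, "is_normal": finding.is_normal},
        )
        self._mark_first_test(event.timestamp)
        return finding

    def tymp_exam(self, ear: Ear | str | None = None):
        """Press the Tymp button: returns the selected ear's tympanogram."""
        if ear is not None:
            self.selected_ear = Ear(ear)
        side = self._require_ear()
        profile = self.presentation.base.ear(side.value).tympanogram
        event = self._log(
            EventKind.tymp_exam,
            {"ear": side.value},
            {"peak_present": profile.peak_present, "ear_canal_volume_ml": profile.ear_canal_volume_ml},
        )
        self._mark_first_test(event.timestamp)
        return profile

    def present_tone(
        self,
        ear: Ear | str | None = None,
        frequency: int | None = None,
        level: int | None = None,
    ) -> bool:
        """Present a tone; returns whether the subject raised a hand."""
        if ear is not None:
            self.selected_ear = Ear(ear)
        if frequency is not None:
            self.selected_frequency = self._validate_frequency(frequency)
        if level is not None:
            self.selected_level = self._validate_level(level)
        side = self._require_ear()
        freq, lvl = self.selected_frequency, self.selected_level
        audiogram = self.presentation.base.ear(side.value).audiogram
        try:
            threshold = audiogram.threshold_at(freq)
        except KeyError as exc:
            raise SessionError(str(exc))
        responded = simulate_response(lvl, threshold, audiogram.inconsistency, self._rng)
        event = self._log(
            EventKind.tone_presented,
            {"ear": side.value, "frequency": freq, "level": lvl},
            {"responded": responded},
        )
        self._mark_first_test(event.timestamp)
        return responded

    # -- notes / lifecycle -------------------------------------------------

    def save_notes(self, notes: TechnicianNotes | dict) -> TechnicianNotes:
        if isinstance(notes, dict):
            try:
                notes = TechnicianNotes.model_validate(notes)
            except ValidationError as exc:
                raise SessionError(f"malformed notes: {exc.errors()[0]['msg']}")
        self.notes = notes
        self._log(EventKind.notes_saved, {"complete": notes.complete, "missing": notes.missing_slots()})
        return notes

    def close(self) -> None:
        if self.ended_at is None:
            self.ended_at = self._clock()

    @property
    def closed(self) -> bool:
        return self.ended_at is not None

    # -- durations ---------------------------------------------------------

    def testing_duration(self) -> float:
        """Seconds from the first exam/tone to session end (0 if untested)."""
        if self.ended_at is None:
            raise SessionError("session not closed")
        if self.first_test_at is None:
            return 0.0
        return self.ended_at - self.first_test_at

    def total_duration(self) -> float:
        if self.ended_at is None:
            raise SessionError("session not closed")
        return self.ended_at - self.started_at


def start_session(
    technician_name: str,
    presentation: PatientPresentation,
    seed: int,
    clock: Callable[[], float] | None = None,
) -> ScreeningSession:
    """Open a session: empty log, start time stamped, rng seeded."""
    return ScreeningSession(technician_name, presentation, seed, clock)


# ---------------------------------------------------------------------------
# Scripted (headless) sessions

_ACTIONS: dict[str, str] = {
    "select_mode": "select_mode",
    "select_ear": "select_ear",
    "set_level": "set_level",
    "set_frequency": "set_frequency",
    "oto_exam": "oto_exam",
    "tymp_exam": "tymp_exam",
    "present_tone": "present_tone",
    "save_notes": "save_notes",
}


def load_actions(path: str | Path) -> list[dict]:
    """Load and structurally validate an ``actions.json`` script.

    The format is a JSON list of ``{"action": <name>, "params": {...}}``
    steps executed in order by :func:`run_script`.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return validate_actions(raw)


def validate_actions(raw: Any) -> list[dict]:
    if not isinstance(raw, list):
        raise SessionError("action script must be a JSON list")
    for i, step in enumerate(raw):
        if not isinstance(step, dict) or "action" not in step:
            raise SessionError(f"step {i}: each step needs an 'action' key")
        if step["action"] not in _ACTIONS:
            raise SessionError(
                f"step {i}: unknown action {step['action']!r}; known: {sorted(_ACTIONS)}"
            )
        params = step.get("params", {})
        if not isinstance(params, dict):
            raise SessionError(f"step {i}: 'params' must be an object")
    return raw


def run_script(session: ScreeningSession, actions: list[dict], close: bool = True) -> ScreeningSession:
    """Drive a session headlessly from a validated action list."""
    validate_actions(actions)
    for step in actions:
        params = step.get("params", {})
        if step["action"] == "save_notes":
            session.save_notes(params.get("notes", params))
        else:
            getattr(session, _ACTIONS[step["action"]])(**params)
    if close:
        session.close()
    return session


def replay(
    presentation: PatientPresentation,
    technician_name: str,
    seed: int,
    event_log: list[Event],
    clock: Callable[[], float] | None = None,
) -> ScreeningSession:
    """Re-execute a logged session against a fresh state machine.

    With the same presentation and seed the replay reproduces every logged
    outcome; used by tests and audits to confirm the log is a sufficient
    record of the session.
    """
    session = start_session(technician_name, presentation, seed, clock)
    for event in event_log:
        kind, p = event.kind, event.params
        if kind == EventKind.select_mode:
            session.select_mode(p["mode"])
        elif kind == EventKind.select_ear:
            session.select_ear(p["ear"])
        elif kind == EventKind.set_level:
            session.set_level(p["level"])
        elif kind == EventKind.set_frequency:
            session.set_frequency(p["frequency"])
        elif kind == EventKind.oto_exam:
            session.oto_exam(p["ear"])
        elif kind == EventKind.tymp_exam:
            session.tymp_exam(p["ear"])
        elif kind == EventKind.tone_presented:
            session.present_tone(p["ear"], p["frequency"], p["level"])
        elif kind == EventKind.notes_saved:
            pass  # notes content lives outside the event payload
    session.close()
    return session
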