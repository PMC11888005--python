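"""An ideal scripted trainee: runs the full protocol and reads results off
the simulated instruments.

Used for demos, auditing fixtures and end-to-end checks: `protocol_actions`
emits a fully compliant action script, and `notes_from_observations`
fills in technician notes exactly as a perfect student would — otoscopy
from the displayed finding, tympanometry by classifying the displayed
trace, audiometry pass only when the subject responded at the screening
level at every required frequency.
"""

from __future__ import annotations

from .protocol import NormativeRanges, ProtocolConfig, classify_tympanogram, recommend
from .session import EventKind, ScreeningSession, TechnicianNotes

__all__ = ["protocol_actions", "notes_from_observations"]


def protocol_actions(protocol: ProtocolConfig | None = None) -> list[dict]:
    """Action script for one complete, in-order screening (notes excluded)."""
    protocol = protocol or ProtocolConfig()
    actions: list[dict] = [{"action": "select_mode", "params": {"mode": "otoscopy"}}]
    for ear in protocol.ears_required:
        actions.append({"action": "oto_exam", "params": {"ear": ear}})
    actions.append({"action": "select_mode", "params": {"mode": "tympanometry"}})
    for ear in protocol.ears_required:
        actions.append({"action": "tymp_exam", "params": {"ear": ear}})
    actions.append({"action": "select_mode", "params": {"mode": "audiometry"}})
    for ear in protocol.ears_required:
        for freq in protocol.required_frequencies:
            actions.append({
                "action": "present_tone",
                "params": {"ear": ear, "frequency": freq, "level": protocol.screening_level},
            })
    return actions


def notes_from_observations(
    session: ScreeningSession,
    protocol: ProtocolConfig | None = None,
    norms: NormativeRanges | None = None,
) -> TechnicianNotes:
    """Fill technician notes from what the session actually displayed.

    Only procedures that were run get results; audiometry for an ear passes
    iff every required frequency drew a response at the screening level.
    The final recommendation is filled only when all six results exist.
    """
    protocol = protocol or ProtocolConfig()
    norms = norms or NormativeRanges()
    base = session.presentation.base

    oto_seen: set[str] = set()
    responded: dict[tuple[str, int], bool] = {}
    tymp_seen: set[str] = set()
    for event in session.event_log:
        if event.kind == EventKind.oto_exam:
            oto_seen.add(event.params["ear"])
        elif event.kind == EventKind.tymp_exam:
            tymp_seen.add(event.params["ear"])
        elif event.kind == EventKind.tone_presented:
            if event.params["level"] == protocol.screening_level:
                key = (event.params["ear"], event.params["frequency"])
                # a response at any repetition counts
                responded[key] = responded.get(key, False) or bool(event.outcome["responded"])

    fields: dict[str, dict] = {}
    for side in ("left", "right"):
        if side in oto_seen:
            normal = base.ear(side).otoscopy.is_normal
            fields[f"otoscopy_{side}"] = {"result": "normal" if normal else "abnormal"}
        if side in tymp_seen:
            _, result = classify_tympanogram(base.ear(side).tympanogram, base.age_band, norms)
            fields[f"tympanometry_{side}"] = {"result": result}
        freqs_heard = [responded.get((side, f), False) for f in protocol.required_frequencies]
        tested = any((side, f) in responded for f in protocol.required_frequencies)
        if tested:
            fields[f"audiometry_{side}"] = {"result": "pass" if all(freqs_heard) else "refer"}

    notes = TechnicianNotes.model_validate(fields)
    if notes.missing_slots() == ["final_recommendation"]:
        rec = recommend(
            {s: getattr(notes, f"otoscopy_{s}").result for s in ("left", "right")},
            {s: getattr(notes, f"tympanometry_{s}").result for s in ("left", "right")},
            {s: getattr(notes, f"audiometry_{s}").result for s in ("left", "right")},
        )
        notes = notes.model_copy(update={"final_recommendation": rec.value})
    return notes
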