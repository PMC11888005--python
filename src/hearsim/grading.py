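"""Automatic grading of technician notes and debrief-report rendering.

Seven equally weighted graded slots: the six per-ear procedure results
(otoscopy, tympanometry, audiometry x left/right) plus the final
recommendation. Each graded item pairs the trainee's answer with the
correct one and the case's clinical explanation, so the report doubles as
immediate feedback and as the starting point for a facilitator debrief.
Free-text comments are shown but never auto-scored.
"""

from __future__ import annotations

import json
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .protocol import ComplianceResult, GroundTruth
from .session import ScreeningSession, TechnicianNotes

__all__ = ["GRADED_ITEMS", "DebriefReport", "GradedItem", "grade_session", "build_report", "render_report"]

#: The seven graded slots, in report order.
GRADED_ITEMS: tuple[str, ...] = (
    "otoscopy_left",
    "otoscopy_right",
    "tympanometry_left",
    "tympanometry_right",
    "audiometry_left",
    "audiometry_right",
    "final_recommendation",
)


class GradedItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    item: str
    student_answer: Optional[str]
    correct_answer: str
    correct: bool
    missing: bool
    explanation: str


class DebriefReport(BaseModel):
    """Session report: metadata, graded items, compliance and score."""

    model_config = ConfigDict(frozen=True)

    technician_name: str
    subject_name: str
    base_id: str
    seed: int
    testing_duration_s: float
    total_duration_s: float
    procedures_run: list[str]
    graded_items: list[GradedItem]
    score: float = Field(ge=0.0, le=1.0)
    compliance: ComplianceResult

    @property
    def n_correct(self) -> int:
        return sum(item.correct for item in self.graded_items)


def _student_answer(notes: TechnicianNotes, item: str) -> Optional[str]:
    if item == "final_recommendation":
        return notes.final_recommendation
    return getattr(notes, item).result


def grade_session(notes: TechnicianNotes, truth: GroundTruth) -> tuple[list[GradedItem], float]:
    """Grade the seven slots against ground truth.

    Pure and deterministic in (notes, truth). A missing answer is wrong
    and flagged ``missing``. Score = fraction correct out of 7.
    """
    items: list[GradedItem] = []
    for slot in GRADED_ITEMS:
        student = _student_answer(notes, slot)
        correct_answer = truth.result_for(slot)
        items.append(GradedItem(
            item=slot,
            student_answer=student,
            correct_answer=correct_answer,
            correct=student == correct_answer,
            missing=student is None,
            explanation=truth.explanation,
        ))
    score = sum(i.correct for i in items) / len(GRADED_ITEMS)
    return items, score


def build_report(
    session: ScreeningSession,
    truth: GroundTruth,
    compliance: ComplianceResult,
) -> DebriefReport:
    """Assemble the debrief report for a closed, audited session."""
    items, score = grade_session(session.notes, truth)
    return DebriefReport(
        technician_name=session.technician_name,
        subject_name=session.presentation.display_name,
        base_id=session.presentation.base_id,
        seed=session.seed,
        testing_duration_s=session.testing_duration(),
        total_duration_s=session.total_duration(),
        procedures_run=sorted(compliance.exams),
        graded_items=items,
        score=score,
        compliance=compliance,
    )


_ITEM_LABELS = {
    "otoscopy_left": "Otoscopy (left)",
    "otoscopy_right": "Otoscopy (right)",
    "tympanometry_left": "Tympanometry (left)",
    "tympanometry_right": "Tympanometry (right)",
    "audiometry_left": "Audiometry (left)",
    "audiometry_right": "Audiometry (right)",
    "final_recommendation": "Final recommendation",
}


def _render_markdown(report: DebriefReport) -> str:
    lines = [
        "# Hearing screening debrief report",
        "",
        f"- Technician: {report.technician_name}",
        f"- Subject: {report.subject_name} (case {report.base_id})",
        f"- Seed: {report.seed}",
        f"- Testing duration: {report.testing_duration_s:.0f} s",
        f"- Total session duration: {report.total_duration_s:.0f} s",
        f"- Procedures run: {', '.join(report.procedures_run) or 'none'}",
        "",
        f"## Results — score {report.n_correct}/{len(report.graded_items)}"
        f" ({report.score:.3f})",
        "",
        "| Item | Your answer | Correct answer | Graded |",
        "|---|---|---|---|",
    ]
    for item in report.graded_items:
        answer = item.student_answer if item.student_answer is not None else "(missing)"
        mark = "correct" if item.correct else ("missing" if item.missing else "incorrect")
        lines.append(
            f"| {_ITEM_LABELS.get(item.item, item.item)} | {answer} | {item.correct_answer} | {mark} |"
        )
    explanation = report.graded_items[0].explanation if report.graded_items else ""
    lines += ["", "## Explanation", "", explanation, "", "## Protocol compliance", ""]
    if report.compliance.compliant:
        lines.append("Session was fully compliant with the screening protocol.")
    else:
        for finding in report.compliance.findings:
            lines.append(f"- [{finding.severity}] {finding.code.value}: {finding.detail}")
    lines += [
        "",
        f"Tone presentations: {sum(report.compliance.presentations.values())} "
        f"({report.compliance.positive_responses} positive responses).",
        "",
    ]
    return "\n".join(lines)


def render_report(report: DebriefReport, format: str = "markdown") -> str:
    """Render a debrief report as ``markdown`` (for reading) or ``json``
    (loss-free; round-trips through ``DebriefReport.model_validate``)."""
    if format == "json":
        return json.dumps(report.model_dump(mode="json"), indent=2)
    if format == "markdown":
        return _render_markdown(report)
    raise ValueError(f"unknown report format {format!r}; use 'json' or 'markdown'")
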