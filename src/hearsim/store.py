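"""Append-only session store with student-history and cohort reporting.

Records live in a line-delimited JSON file (one session per line) behind a
small storage class, so the log stays human-diffable and backend-swappable.
Records are immutable once appended; reporting reads never mutate.
"""

from __future__ import annotations

import csv
import json
import uuid
from pathlib import Path
from typing import Iterator, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .grading import DebriefReport, GradedItem
from .protocol import ComplianceResult
from .session import Event, ScreeningSession, TechnicianNotes

__all__ = ["SessionRecord", "SessionStore", "StoreError", "record_from_session"]


class StoreError(RuntimeError):
    pass


class SessionRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    record_id: str
    timestamp: float
    technician_name: str
    base_id: str
    seed: int
    event_log: list[Event]
    notes: TechnicianNotes
    graded_items: list[GradedItem]
    score: float
    testing_duration_s: float
    total_duration_s: float
    compliance: ComplianceResult


def record_from_session(
    session: ScreeningSession,
    report: DebriefReport,
    record_id: Optional[str] = None,
) -> SessionRecord:
    """Freeze a closed, graded session into a storable record."""
    return SessionRecord(
        record_id=record_id or uuid.uuid4().hex,
        timestamp=session.started_at,
        technician_name=session.technician_name,
        base_id=session.presentation.base_id,
        seed=session.seed,
        event_log=session.event_log,
        notes=session.notes,
        graded_items=report.graded_items,
        score=report.score,
        testing_duration_s=report.testing_duration_s,
        total_duration_s=report.total_duration_s,
        compliance=report.compliance,
    )


class SessionStore:
    """JSONL-backed append-only store of completed screening sessions."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def _iter_records(self) -> Iterator[SessionRecord]:
        if not self.path.exists():
            return
        try:
            fh = self.path.open(encoding="utf-8")
        except OSError as exc:
            raise StoreError(f"cannot read session store {self.path}: {exc}")
        with fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    yield SessionRecord.model_validate(json.loads(line))
                except (json.JSONDecodeError, ValidationError) as exc:
                    raise StoreError(f"{self.path}:{lineno}: corrupt record: {exc}")

    def records(self) -> list[SessionRecord]:
        return list(self._iter_records())

    def __len__(self) -> int:
        return sum(1 for _ in self._iter_records())

    def append(self, record: SessionRecord) -> str:
        """Durably append one record; returns its id. Ids must be unique."""
        if any(r.record_id == record.record_id for r in self._iter_records()):
            raise StoreError(f"duplicate record id {record.record_id!r}")
        line = json.dumps(record.model_dump(mode="json")) + "\n"
        try:
            with self.path.open("a", encoding="utf-8") as fh:
                fh.write(line)
                fh.flush()
        except OSError as exc:
            raise StoreError(f"cannot write session store {self.path}: {exc}")
        return record.record_id

    def get(self, record_id: str) -> SessionRecord:
        for record in self._iter_records():
            if record.record_id == record_id:
                return record
        raise KeyError(record_id)

    # -- reporting ---------------------------------------------------------

    def student_history(self, technician_name: str) -> list[dict]:
        """Chronological history of one student's sessions."""
        rows = [
            {
                "timestamp": r.timestamp,
                "base_id": r.base_id,
                "score": r.score,
                "testing_duration_s": r.testing_duration_s,
                "total_duration_s": r.total_duration_s,
            }
            for r in self._iter_records()
            if r.technician_name == technician_name
        ]
        rows.sort(key=lambda row: row["timestamp"])
        return rows

    def cohort_summary(self) -> dict:
        """Cross-sectional aggregates over every stored session.

        Per-item error rate = fraction of sessions grading that slot
        incorrect (missing counts as incorrect).
        """
        records = self.records()
        if not records:
            raise StoreError("empty store: no sessions to summarize")
        n = len(records)
        item_errors: dict[str, int] = {}
        per_patient: dict[str, int] = {}
        for record in records:
            per_patient[record.base_id] = per_patient.get(record.base_id, 0) + 1
            for item in record.graded_items:
                item_errors[item.item] = item_errors.get(item.item, 0) + (not item.correct)
        return {
            "n_sessions": n,
            "mean_score": sum(r.score for r in records) / n,
            "mean_testing_duration_s": sum(r.testing_duration_s for r in records) / n,
            "mean_total_duration_s": sum(r.total_duration_s for r in records) / n,
            "per_item_error_rate": {k: v / n for k, v in sorted(item_errors.items())},
            "sessions_per_patient": dict(sorted(per_patient.items())),
        }

    def export_cohort_csv(self, path: str | Path) -> None:
        """Write the cohort summary as a flat two-column CSV."""
        summary = self.cohort_summary()
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            for key in ("n_sessions", "mean_score", "mean_testing_duration_s", "mean_total_duration_s"):
                writer.writerow([key, summary[key]])
            for item, rate in summary["per_item_error_rate"].items():
                writer.writerow([f"error_rate.{item}", rate])
            for base_id, count in summary["sessions_per_patient"].items():
                writer.writerow([f"sessions.{base_id}", count])
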