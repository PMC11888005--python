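"""JSON Schema exports for every external file format.

Schemas are generated from the pydantic models that validate the files, so
they always match the code. ``export_schemas`` writes one ``*.schema.json``
per format for editor tooling and external validators.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel

from .grading import DebriefReport
from .patients import BasePatient, NameEntry
from .protocol import NormativeRanges, ProtocolConfig
from .store import SessionRecord

__all__ = ["ACTIONS_SCHEMA", "export_schemas", "roster_schema", "names_schema"]

_KNOWN_ACTIONS = [
    "select_mode", "select_ear", "set_level", "set_frequency",
    "oto_exam", "tymp_exam", "present_tone", "save_notes",
]

#: Schema for the scripted-session actions.json format.
ACTIONS_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "hearsim action script",
    "type": "array",
    "items": {
        "type": "object",
        "required": ["action"],
        "properties": {
            "action": {"enum": _KNOWN_ACTIONS},
            "params": {"type": "object"},
        },
        "additionalProperties": False,
    },
}


def _listing(title: str, key: str, model: type[BaseModel]) -> dict:
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": title,
        "type": "object",
        "required": [key],
        "properties": {key: {"type": "array", "items": model.model_json_schema()}},
    }


def roster_schema() -> dict:
    return _listing("hearsim patient roster", "patients", BasePatient)


def names_schema() -> dict:
    return _listing("hearsim name pool", "names", NameEntry)


def export_schemas(out_dir: str | Path) -> list[Path]:
    """Write all format schemas into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs = {
        "roster.schema.json": roster_schema(),
        "names.schema.json": names_schema(),
        "protocol.schema.json": ProtocolConfig.model_json_schema(),
        "norms.schema.json": NormativeRanges.model_json_schema(),
        "actions.schema.json": ACTIONS_SCHEMA,
        "report.schema.json": DebriefReport.model_json_schema(),
        "session_record.schema.json": SessionRecord.model_json_schema(),
    }
    paths = []
    for name, doc in docs.items():
        path = out / name
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        paths.append(path)
    return paths
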