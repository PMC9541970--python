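"""Reading and writing encounters, truth records and results.

Encounters travel as JSONL (one encounter object per line, notes embedded)
or as a pair of CSVs (encounters, notes) joined on ``encounter_id``. Truth
and result tables are plain CSV handled through pandas.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .detector import DiagnosisCode, Encounter, EncounterResult, Note, TermMatch

__all__ = [
    "encounter_from_dict",
    "encounter_to_dict",
    "read_encounters_jsonl",
    "write_encounters_jsonl",
    "read_encounters_csv",
    "read_truth_csv",
    "write_truth_csv",
    "write_results_csv",
    "read_results_csv",
    "write_results_jsonl",
]


def _parse_date(value) -> datetime.date | None:
    if value in (None, ""):
        return None
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


def encounter_from_dict(obj: dict) -> Encounter:
    notes = [
        Note(
            note_id=n.get("note_id", ""),
            encounter_id=obj["encounter_id"],
            author_role=n.get("author_role", "other"),
            text=n.get("text", ""),
        )
        for n in obj.get("notes", [])
    ]
    # the chief complaint is just one more searchable note
    cc = obj.get("chief_complaint")
    if cc:
        notes.append(
            Note(
                note_id=f"{obj['encounter_id']}-cc",
                encounter_id=obj["encounter_id"],
                author_role="other",
                text=cc,
            )
        )
    codes = []
    for c in obj.get("diagnosis_codes", []):
        if isinstance(c, str):
            codes.append(DiagnosisCode(code=c))
        else:
            codes.append(DiagnosisCode(code=c["code"], revision=c.get("revision")))
    return Encounter(
        encounter_id=obj["encounter_id"],
        patient_id=obj.get("patient_id", ""),
        visit_date=_parse_date(obj.get("visit_date")),
        diagnosis_codes=codes,
        notes=notes,
    )


def encounter_to_dict(enc: Encounter) -> dict:
    return {
        "encounter_id": enc.encounter_id,
        "patient_id": enc.patient_id,
        "visit_date": enc.visit_date.isoformat() if enc.visit_date else None,
        "diagnosis_codes": [
            {"code": c.code, "revision": c.revision} for c in enc.diagnosis_codes
        ],
        "notes": [
            {"note_id": n.note_id, "author_role": n.author_role, "text": n.text}
            for n in enc.notes
        ],
    }


def read_encounters_jsonl(path) -> list:
    encounters = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                encounters.append(encounter_from_dict(json.loads(line)))
    return encounters


def write_encounters_jsonl(encounters: Iterable[Encounter], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for enc in encounters:
            fh.write(json.dumps(encounter_to_dict(enc), sort_keys=True) + "\n")


def read_encounters_csv(encounters_csv, notes_csv) -> list:
    """Join an encounters table and a notes table on encounter_id.

    The encounters CSV carries ``encounter_id, patient_id, visit_date,
    diagnosis_codes`` with codes ";"-joined as ``revision:code`` (revision
    optional); the notes CSV carries ``encounter_id, note_id, author_role,
    text``.
    """
    enc_df = pd.read_csv(encounters_csv, dtype=str).fillna("")
    notes_df = pd.read_csv(notes_csv, dtype=str).fillna("")
    notes_by_enc: dict[str, list[Note]] = {}
    for row in notes_df.itertuples(index=False):
        notes_by_enc.setdefault(row.encounter_id, []).append(
            Note(
                note_id=row.note_id,
                encounter_id=row.encounter_id,
                author_role=getattr(row, "author_role", "other") or "other",
                text=row.text,
            )
        )
    encounters = []
    for row in enc_df.itertuples(index=False):
        codes = []
        for item in (row.diagnosis_codes or "").split(";"):
            item = item.strip()
            if not item:
                continue
            if ":" in item:
                rev, code = item.split(":", 1)
                codes.append(DiagnosisCode(code=code, revision=int(rev)))
            else:
                codes.append(DiagnosisCode(code=item))
        encounters.append(
            Encounter(
                encounter_id=row.encounter_id,
                patient_id=row.patient_id,
                visit_date=_parse_date(row.visit_date),
                diagnosis_codes=codes,
                notes=notes_by_enc.get(row.encounter_id, []),
            )
        )
    return encounters


def write_truth_csv(truth_records: Iterable, path) -> None:
    rows = [
        {
            "encounter_id": t.encounter_id,
            "is_ipv": t.is_ipv,
            "phenomena": ";".join(sorted(t.phenomena)),
        }
        for t in truth_records
    ]
    pd.DataFrame(rows, columns=["encounter_id", "is_ipv", "phenomena"]).to_csv(
        path, index=False
    )


def read_truth_csv(path) -> dict:
    """Truth table as {encounter_id: bool}."""
    df = pd.read_csv(path, dtype={"encounter_id": str})
    truth = {}
    for row in df.itertuples(index=False):
        val = row.is_ipv
        truth[row.encounter_id] = (
            bool(val) if isinstance(val, (bool,)) else str(val).lower() == "true"
        )
    return truth


def _evidence_summary(res: EncounterResult) -> str:
    parts = []
    for ev in res.evidence:
        if isinstance(ev, TermMatch):
            parts.append(f"{ev.phrase}@{ev.note_id}")
        else:
            parts.append(str(ev))
    return ";".join(parts)


def write_results_csv(results: Iterable[EncounterResult], path) -> None:
    rows = [
        {
            "encounter_id": r.encounter_id,
            "approach": r.approach,
            "label": r.label,
            "evidence": _evidence_summary(r),
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["encounter_id", "approach", "label", "evidence"]
    ).to_csv(path, index=False)


def read_results_csv(path) -> list:
    df = pd.read_csv(path, dtype={"encounter_id": str}).fillna("")
    results = []
    for row in df.itertuples(index=False):
        label = row.label if isinstance(row.label, bool) else str(row.label).lower() == "true"
        results.append(
            EncounterResult(
                encounter_id=row.encounter_id,
                approach=row.approach,
                label=label,
                evidence=[e for e in str(row.evidence).split(";") if e],
            )
        )
    return results


def write_results_jsonl(results: Iterable[EncounterResult], path) -> None:
    """Full-evidence dump: TermMatch objects serialized field-for-field."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in results:
            obj = {
                "encounter_id": r.encounter_id,
                "approach": r.approach,
                "label": r.label,
                "evidence": [
                    dataclasses.asdict(ev) if isinstance(ev, TermMatch) else ev
                    for ev in r.evidence
                ],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")
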