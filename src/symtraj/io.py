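"""Readers, writers and schema validation for the on-disk formats.

* registry: TSV, one row per diagnosis event with the patient attributes
  repeated (``patient_id, sex, birth_date, status_code, death_date,
  event_code, admission_date, discharge_date, diagnosis_type,
  encounter_id``), ISO-8601 dates;
* clinical notes: JSONL ``{note_id, patient_id, date, text}``;
* gold annotations: TSV ``note_id, start, end, code, negated,
  other_person`` with 0-based half-open character offsets;
* symptom dictionary: TSV ``surface_form, code, provenance``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .cohort import EVENT_COLUMNS, PATIENT_COLUMNS, Registry

ICD_LEVEL3_RE = re.compile(r"^[A-Z][0-9]{2}$")
_REGISTRY_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "status_code",
    "death_date",
    "event_code",
    "admission_date",
    "discharge_date",
    "diagnosis_type",
    "encounter_id",
]
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def write_registry_tsv(registry: Registry, path) -> None:
    df = registry.events.merge(registry.patients, on="patient_id")
    df = df[_REGISTRY_COLUMNS].copy()
    for col in ("birth_date", "death_date", "admission_date", "discharge_date"):
        df[col] = df[col].dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep="\t", index=False)


def read_registry_tsv(path, confirmed_case_ids=()) -> Registry:
    df = pd.read_csv(path, sep="\t", dtype={"status_code": str, "patient_id": str})
    for col in ("birth_date", "death_date", "admission_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col])
    patients = (
        df[PATIENT_COLUMNS].drop_duplicates(subset="patient_id").reset_index(drop=True)
    )
    events = df[EVENT_COLUMNS].reset_index(drop=True)
    end = df["admission_date"].max()
    return Registry(
        patients=patients,
        events=events,
        confirmed_case_ids=frozenset(confirmed_case_ids),
        end_of_data=end,
    )


def write_notes_jsonl(notes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in notes.itertuples():
            fh.write(
                json.dumps(
                    {
                        "note_id": rec.note_id,
                        "patient_id": rec.patient_id,
                        "date": pd.Timestamp(rec.date).strftime("%Y-%m-%d"),
                        "text": rec.text,
                    }
                )
                + "\n"
            )


def read_notes_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    notes = pd.DataFrame(rows, columns=["note_id", "patient_id", "date", "text"])
    notes["date"] = pd.to_datetime(notes["date"])
    return notes


def write_gold_tsv(gold: pd.DataFrame, path) -> None:
    gold.to_csv(path, sep="\t", index=False)


def read_gold_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"note_id": str, "code": str}).astype(
        {"start": int, "end": int, "negated": bool, "other_person": bool}
    )


def validate_inputs(
    registry_path=None, notes_path=None, dictionary_path=None
) -> list[dict]:
    """Schema-check the input files; returns one issue dict per problem.

    Issues carry ``file, line, level ("error"/"warning"), message``.  Line
    numbers are 1-based and include the header line for TSVs.  Level-4+
    diagnosis codes are warnings with a truncation suggestion; malformed
    dates, missing columns and bad spans are errors.
    """
    issues: list[dict] = []

    def issue(file, line, level, message):
        issues.append({"file": str(file), "line": line, "level": level, "message": message})

    if registry_path is not None:
        path = Path(registry_path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            missing = [c for c in _REGISTRY_COLUMNS if c not in header]
            if missing:
                issue(path, 1, "error", f"missing columns: {missing}")
            else:
                col = {c: header.index(c) for c in _REGISTRY_COLUMNS}
                for lineno, line in enumerate(fh, start=2):
                    f = line.rstrip("\n").split("\t")
                    if len(f) != len(header):
                        issue(path, lineno, "error", "wrong field count")
                        continue
                    code = f[col["event_code"]]
                    if not ICD_LEVEL3_RE.match(code):
                        if re.match(r"^[A-Z][0-9]{2}", code):
                            issue(
                                path, lineno, "warning",
                                f"code {code!r} is below level 3; truncate to {code[:3]!r}",
                            )
                        else:
                            issue(path, lineno, "error", f"malformed code {code!r}")
                    for dcol in ("birth_date", "admission_date", "discharge_date"):
                        v = f[col[dcol]]
                        if not _DATE_RE.match(v) or not _valid_date(v):
                            issue(path, lineno, "error", f"bad date {v!r} in {dcol}")
                    v = f[col["death_date"]]
                    if v and not (_DATE_RE.match(v) and _valid_date(v)):
                        issue(path, lineno, "error", f"bad date {v!r} in death_date")

    if notes_path is not None:
        path = Path(notes_path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    issue(path, lineno, "error", f"invalid JSON: {exc}")
                    continue
                for key in ("note_id", "patient_id", "date", "text"):
                    if key not in rec:
                        issue(path, lineno, "error", f"missing key {key!r}")
                if "date" in rec and not (
                    _DATE_RE.match(str(rec["date"])) and _valid_date(str(rec["date"]))
                ):
                    issue(path, lineno, "error", f"bad date {rec.get('date')!r}")

    if dictionary_path is not None:
        path = Path(dictionary_path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["surface_form", "code"]:
                issue(path, 1, "error", "dictionary header must start surface_form, code")
            else:
                seen = set()
                for lineno, line in enumerate(fh, start=2):
                    f = line.rstrip("\n").split("\t")
                    if len(f) < 2 or not f[0] or not f[1]:
                        issue(path, lineno, "error", "surface form and code required")
                        continue
                    if f[0] in seen:
                        issue(path, lineno, "error", f"duplicate surface form {f[0]!r}")
                    seen.add(f[0])
    return issues


def _valid_date(v: str) -> bool:
    try:
        pd.Timestamp(v)
        return True
    except ValueError:
        return False
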