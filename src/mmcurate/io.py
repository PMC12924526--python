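"""Readers and writers for the tabular interchange formats.

Label tables travel as CSV (UTF-8, header row, RFC-4180 quoting) or JSONL
(one record per line); raw extractor payloads as JSONL.  Dates are always
ISO-8601 ``YYYY-MM-DD`` strings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .schema import LabelRecord

LABEL_COLUMNS = ["note_id", "patient_id", "field_id", "source", "value",
                 "timestamp", "failure_code"]


@dataclass(frozen=True)
class RawPayload:
    """Unparsed extractor output for one (note, workflow)."""

    note_id: str
    workflow_id: str
    raw_text: str

    def __post_init__(self) -> None:
        if not self.raw_text:
            raise ValueError("raw_text must be non-empty")


def records_to_frame(records: Iterable[LabelRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=LABEL_COLUMNS)
    return df.astype(object).where(df.notna(), None)


def frame_to_records(df: pd.DataFrame) -> list[LabelRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(LabelRecord(
            note_id=str(row.note_id), patient_id=str(row.patient_id),
            field_id=row.field_id, source=row.source, value=row.value,
            timestamp=_none(row.timestamp), failure_code=_none(row.failure_code)))
    return out


def _none(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return str(v)


def write_label_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_label_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.astype(object)
    for col in ("timestamp", "failure_code"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: v if v != "" else None)
    return df


def write_label_jsonl(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in df.to_dict(orient="records"):
            fh.write(json.dumps({k: v for k, v in rec.items() if v is not None},
                                ensure_ascii=False) + "\n")


def read_label_jsonl(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    df = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    return df.astype(object).where(df.notna(), None)


def write_payloads_jsonl(payloads: Sequence[RawPayload], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in payloads:
            fh.write(json.dumps(asdict(p), ensure_ascii=False) + "\n")


def read_payloads_jsonl(path: str | Path) -> list[RawPayload]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                d = json.loads(line)
                out.append(RawPayload(d["note_id"], d["workflow_id"], d["raw_text"]))
    return out


def read_two_column_csv(path: str | Path) -> dict[str, str]:
    """Load a brand or synonym map: ``from,to`` per row, lower-cased keys."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns[:2])
    return {str(k).strip().lower(): str(v).strip()
            for k, v in zip(df[cols[0]], df[cols[1]])}
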