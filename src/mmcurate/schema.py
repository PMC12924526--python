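"""Field catalog, label vocabularies, and validation primitives.

The catalog covers thirteen multiple-myeloma data fields documented in
free-text provider notes: disease state (diagnosis, status, diagnosis date),
transplant eligibility & status, ECOG performance status, plasmacytosis
percentage, bone lesions, extramedullary disease (presence and location),
and first-line therapy (regimen, start date, response, response date).

Each field carries a value type — ``binary``, ``categorical``, ``integer``,
``date`` or ``drug_set`` — with a closed label vocabulary or inclusive
numeric range.  The literal ``"Unspecified"`` denotes "not mentioned in the
note" and is a legal value for every field regardless of vocabulary
membership.

Values are carried through the pipeline in a canonical *string* encoding so
label tables round-trip losslessly through CSV/JSONL:

* binary/categorical: the canonical label,
* integer: decimal string,
* date: ISO-8601 ``YYYY-MM-DD``,
* drug_set: sorted lower-case ingredients joined with ``"|"``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import yaml

UNSPECIFIED = "Unspecified"

VALUE_TYPES = ("binary", "categorical", "integer", "date", "drug_set")

#: Value-set separator for drug_set canonical encoding.
SET_SEP = "|"


class SchemaError(ValueError):
    """Raised when a catalog, record, or value violates its contract."""


@dataclass(frozen=True)
class StudyPeriod:
    """Half-open-in-nothing calendar window: both endpoints inclusive."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SchemaError(f"study period start {self.start} !< end {self.end}")

    def contains(self, d: dt.date) -> bool:
        return self.start <= d <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days


#: Study window used throughout: Jan 1 2019 through Mar 31 2024.
DEFAULT_STUDY_PERIOD = StudyPeriod(dt.date(2019, 1, 1), dt.date(2024, 3, 31))


@dataclass(frozen=True)
class FieldSpec:
    """One data field: identity, value type, and allowed values.

    ``allowed_labels`` is the closed vocabulary for binary/categorical
    fields; ``numeric_range`` the inclusive [lo, hi] for integer fields.
    ``has_unspecified`` records whether "Unspecified" is part of the printed
    vocabulary (it is always accepted as a *value*).
    """

    field_id: str
    concept: str
    value_type: str
    allowed_labels: Optional[tuple[str, ...]] = None
    numeric_range: Optional[tuple[int, int]] = None
    has_unspecified: bool = True

    def __post_init__(self) -> None:
        if self.value_type not in VALUE_TYPES:
            raise SchemaError(f"{self.field_id}: unknown value_type {self.value_type!r}")
        if self.value_type == "integer" and self.numeric_range is None:
            raise SchemaError(f"{self.field_id}: integer field requires numeric_range")
        if self.value_type in ("binary", "categorical"):
            if not self.allowed_labels:
                raise SchemaError(f"{self.field_id}: label field requires allowed_labels")
            if self.has_unspecified and UNSPECIFIED not in self.allowed_labels:
                raise SchemaError(f"{self.field_id}: vocabulary must contain {UNSPECIFIED!r}")

    # ---- canonical string encoding -------------------------------------

    def encode(self, value) -> str:
        """Canonical string encoding of a decoded value."""
        if value is None:
            return UNSPECIFIED
        if isinstance(value, str) and value == UNSPECIFIED:
            return UNSPECIFIED
        if self.value_type == "integer":
            return str(int(value))
        if self.value_type == "date":
            if isinstance(value, dt.date):
                return value.isoformat()
            return str(value)
        if self.value_type == "drug_set":
            if isinstance(value, str):
                parts = [p for p in value.split(SET_SEP) if p]
            else:
                parts = list(value)
            return SET_SEP.join(sorted({p.strip().lower() for p in parts}))
        return str(value)

    def decode(self, s: str):
        """Inverse of :meth:`encode`; ``Unspecified`` decodes to itself."""
        if s == UNSPECIFIED:
            return UNSPECIFIED
        if self.value_type == "integer":
            return int(s)
        if self.value_type == "date":
            return dt.date.fromisoformat(s)
        if self.value_type == "drug_set":
            return frozenset(p for p in s.split(SET_SEP) if p)
        return s

    def conforms(self, s: str, period: StudyPeriod = DEFAULT_STUDY_PERIOD) -> bool:
        """Whether an encoded value is legal for this field (or Unspecified)."""
        if s == UNSPECIFIED:
            return True
        try:
            v = self.decode(s)
        except (ValueError, TypeError):
            return False
        if self.value_type == "integer":
            lo, hi = self.numeric_range
            return lo <= v <= hi
        if self.value_type == "date":
            return period.contains(v)
        if self.value_type == "drug_set":
            return len(v) > 0
        return v in self.allowed_labels


@dataclass(frozen=True)
class LabelRecord:
    """One value for one (note, field) from one source.

    ``source`` is an annotator id, ``"consensus"``, or a workflow id.
    ``value`` is in the canonical string encoding.  ``timestamp`` is an
    optional ISO date attached to the label (used by timelines).
    """

    note_id: str
    patient_id: str
    field_id: str
    source: str
    value: str
    timestamp: Optional[str] = None
    failure_code: Optional[str] = None

    def validate(self, spec: FieldSpec, period: StudyPeriod = DEFAULT_STUDY_PERIOD) -> "LabelRecord":
        if spec.field_id != self.field_id:
            raise SchemaError(f"record field {self.field_id} != spec {spec.field_id}")
        if not spec.conforms(self.value, period):
            raise SchemaError(
                f"value {self.value!r} does not conform to field {self.field_id}"
            )
        if self.timestamp is not None:
            dt.date.fromisoformat(self.timestamp)
        return self


# ---------------------------------------------------------------------------
# Built-in catalog
# ---------------------------------------------------------------------------

_IMWG_RESPONSES = (
    "Stringent Complete Response",
    "Complete Response",
    "Very Good Partial Response",
    "Partial Response",
    "Minimal Response",
    "No Response",
    "Progressive Disease",
    UNSPECIFIED,
)


def builtin_catalog() -> list[FieldSpec]:
    """The thirteen-field catalog, in stable display order.

    EMD location is typed categorical (three labels are printed for it);
    bone-lesion presence keeps its printed four-label "binary" typing and is
    scored like any other closed vocabulary.
    """
    return [
        FieldSpec("mm_diagnosis", "MM diagnosis", "categorical",
                  ("Yes", "Likely", "No", UNSPECIFIED)),
        FieldSpec("mm_status", "MM status", "categorical",
                  ("Newly diagnosed", "Relapsed", "Refractory", "Remission"),
                  has_unspecified=False),
        FieldSpec("mm_diagnosis_date", "MM diagnosis date", "date"),
        FieldSpec("transplant_status", "Transplant eligibility & status", "categorical",
                  ("Eligible", "Eligible but deferred", "Ineligible", "Performed",
                   UNSPECIFIED)),
        FieldSpec("ecog_score", "ECOG score", "integer", numeric_range=(0, 5)),
        FieldSpec("plasmacytosis", "Plasmacytosis percentage", "integer",
                  numeric_range=(0, 100)),
        FieldSpec("bone_lesion", "MM-related bone lesion presence", "binary",
                  ("Yes", "No", "Unrelated", UNSPECIFIED)),
        FieldSpec("emd_presence", "EMD presence", "binary",
                  ("Present", "No", UNSPECIFIED)),
        FieldSpec("emd_location", "EMD location", "categorical",
                  ("Paramedullary", "Soft tissue", UNSPECIFIED)),
        FieldSpec("flt_regimen", "FLT regimen", "drug_set"),
        FieldSpec("flt_start_date", "FLT start date", "date"),
        FieldSpec("flt_response", "FLT response", "categorical", _IMWG_RESPONSES),
        FieldSpec("flt_response_date", "FLT response date", "date"),
    ]


def catalog_by_id(catalog: Sequence[FieldSpec]) -> dict[str, FieldSpec]:
    out: dict[str, FieldSpec] = {}
    for spec in catalog:
        if spec.field_id in out:
            raise SchemaError(f"duplicate field_id {spec.field_id}")
        out[spec.field_id] = spec
    return out


def apply_field_exclusion(
    catalog: Sequence[FieldSpec],
    presence_fraction_by_field: Mapping[str, float],
    min_fraction: float,
) -> tuple[list[FieldSpec], list[tuple[str, str]]]:
    """Drop fields whose information is present in too few notes.

    Returns ``(retained, excluded)`` where ``excluded`` lists
    ``(field_id, reason)`` pairs.  Monotone in ``min_fraction``.
    """
    if not 0.0 < min_fraction < 1.0:
        raise SchemaError("min_fraction must lie in (0, 1)")
    ids = {s.field_id for s in catalog}
    unknown = set(presence_fraction_by_field) - ids
    if unknown:
        raise SchemaError(f"unknown field_id(s) in presence map: {sorted(unknown)}")
    missing = ids - set(presence_fraction_by_field)
    if missing:
        raise SchemaError(f"presence map missing field(s): {sorted(missing)}")
    for fid, frac in presence_fraction_by_field.items():
        if not 0.0 <= frac <= 1.0:
            raise SchemaError(f"presence fraction for {fid} outside [0,1]: {frac}")
    retained, excluded = [], []
    for spec in catalog:
        frac = presence_fraction_by_field[spec.field_id]
        if frac >= min_fraction:
            retained.append(spec)
        else:
            excluded.append(
                (spec.field_id,
                 f"present in {frac:.1%} of notes (< {min_fraction:.0%} threshold)")
            )
    return retained, excluded


# ---------------------------------------------------------------------------
# Catalog serialization (structured config)
# ---------------------------------------------------------------------------

def catalog_to_yaml(catalog: Sequence[FieldSpec]) -> str:
    docs = []
    for s in catalog:
        d = {"field_id": s.field_id, "concept": s.concept, "value_type": s.value_type,
             "has_unspecified": s.has_unspecified}
        if s.allowed_labels is not None:
            d["allowed_labels"] = list(s.allowed_labels)
        if s.numeric_range is not None:
            d["numeric_range"] = list(s.numeric_range)
        docs.append(d)
    return yaml.safe_dump(docs, sort_keys=False)


def catalog_from_yaml(text: str) -> list[FieldSpec]:
    docs = yaml.safe_load(text)
    out = []
    for d in docs:
        out.append(FieldSpec(
            field_id=d["field_id"], concept=d["concept"], value_type=d["value_type"],
            allowed_labels=tuple(d["allowed_labels"]) if "allowed_labels" in d else None,
            numeric_range=tuple(d["numeric_range"]) if "numeric_range" in d else None,
            has_unspecified=d.get("has_unspecified", True),
        ))
    catalog_by_id(out)  # uniqueness check
    return out
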