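"""Strict-schema post-processing of raw extractor output.

Generative extractors are prompted to return JSON, but what comes back may
be fenced in markdown, prefixed with prose, syntactically broken, off-scale,
or use brand names instead of ingredients.  This module makes every field
comparable against reference labels: parse, validate, coerce to the field
vocabulary, harmonize drug names, and — when the payload is malformed —
apply up to three deterministic repair transforms before giving up and
marking the field "Unspecified" with a failure code.

Repair transform sequence (fixed, no model re-query):

1. parse the text as-is;
2. strip markdown code fences and any prose outside the outermost
   ``{...}`` braces, re-parse;
3. additionally remove trailing commas and normalize single quotes to
   double quotes, re-parse.

The loop is total: every input string terminates in a schema-conformant
value or ``"Unspecified"`` plus a failure code, and re-processing an
already-valid value is a no-op.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

from .io import RawPayload, read_two_column_csv
from .schema import (DEFAULT_STUDY_PERIOD, UNSPECIFIED, FieldSpec, LabelRecord,
                     StudyPeriod)

# failure codes
MALFORMED_JSON = "malformed_json"
MISSING_FIELD = "missing_field"
OUT_OF_RANGE = "out_of_range"
INVALID_DATE = "invalid_date"
UNKNOWN_LABEL = "unknown_label"
INVALID_TYPE = "invalid_type"


class ParseFailure:
    """Sentinel for an unparseable payload (a value, not an exception)."""

    __slots__ = ("reason",)

    def __init__(self, reason: str = MALFORMED_JSON) -> None:
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParseFailure({self.reason!r})"


@dataclass(frozen=True)
class CoercionResult:
    """Outcome of post-processing one field of one payload."""

    label_record: LabelRecord
    status: str  # ok | coerced | repaired | failed
    attempts: int
    failure_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "failed":
            assert self.label_record.value == UNSPECIFIED and self.failure_code
        if self.attempts < 1:
            raise ValueError("attempts must be >= 1")


def default_brand_map() -> dict[str, str]:
    with resources.files("mmcurate.data").joinpath("brand_map.csv").open() as fh:
        import pandas as pd
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
        return {k.strip().lower(): v.strip() for k, v in zip(df.brand, df.ingredient)}


def default_synonym_map() -> dict[str, str]:
    with resources.files("mmcurate.data").joinpath("synonym_map.csv").open() as fh:
        import pandas as pd
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
        return {k.strip().lower(): v.strip() for k, v in zip(df.synonym, df.label)}


# ---------------------------------------------------------------------------
# Parsing and repair transforms
# ---------------------------------------------------------------------------

_FENCE_RE = re.compile(r"```[a-zA-Z]*\n?|```")
_TRAILING_COMMA_RE = re.compile(r",\s*([}\]])")


def _strip_fences_and_prose(text: str) -> str:
    text = _FENCE_RE.sub("", text)
    start, end = text.find("{"), text.rfind("}")
    if start != -1 and end > start:
        return text[start:end + 1]
    return text.strip()


def _fix_commas_and_quotes(text: str) -> str:
    text = _TRAILING_COMMA_RE.sub(r"\1", text)
    if '"' not in text and "'" in text:
        text = text.replace("'", '"')
    return text


#: Cumulative transform pipeline; attempt i applies _TRANSFORMS[i-1].
_TRANSFORMS = (
    lambda t: t,
    _strip_fences_and_prose,
    lambda t: _fix_commas_and_quotes(_strip_fences_and_prose(t)),
)


def parse_payload(raw: RawPayload | str):
    """Parse raw text as a key/value mapping; failure is a value.

    Applies only the first (identity) transform; the repair loop escalates.
    """
    text = raw.raw_text if isinstance(raw, RawPayload) else raw
    return _try_parse(text)


def _try_parse(text: str):
    try:
        obj = json.loads(text)
    except (json.JSONDecodeError, TypeError):
        return ParseFailure()
    if not isinstance(obj, dict):
        return ParseFailure()
    return obj


def parse_with_repairs(text: str, max_attempts: int = 3) -> tuple[object, int]:
    """Escalate through the repair transforms; returns (mapping|failure, attempts)."""
    attempts = 0
    for i, transform in enumerate(_TRANSFORMS[:max_attempts], start=1):
        attempts = i
        parsed = _try_parse(transform(text))
        if not isinstance(parsed, ParseFailure):
            return parsed, attempts
    return ParseFailure(), max(attempts, min(max_attempts, len(_TRANSFORMS)))


# ---------------------------------------------------------------------------
# Value-level validation and coercion
# ---------------------------------------------------------------------------

def validate_date(s, period: StudyPeriod = DEFAULT_STUDY_PERIOD):
    """Return a calendar date, or a rejection reason string.

    Accepts ``YYYY-MM-DD`` (also ``/``-separated); rejects impossible
    calendar dates and dates outside the study period.
    """
    if isinstance(s, dt.date):
        d = s
    else:
        if not isinstance(s, str):
            return "impossible"
        txt = s.strip().replace("/", "-")
        try:
            d = dt.date.fromisoformat(txt[:10])
        except ValueError:
            return "impossible"
    if not period.contains(d):
        return "outside_period"
    return d


def harmonize_regimen(mentions, brand_map: Optional[Mapping[str, str]] = None) -> frozenset[str]:
    """Map brand-name drug mentions to ingredient names; dedup case-folded."""
    if brand_map is None:
        brand_map = default_brand_map()
    out = set()
    for m in mentions:
        key = str(m).strip().lower()
        if not key:
            continue
        out.add(brand_map.get(key, key))
    return frozenset(out)


def coerce_value(
    spec: FieldSpec,
    v,
    synonym_map: Optional[Mapping[str, str]] = None,
    brand_map: Optional[Mapping[str, str]] = None,
    period: StudyPeriod = DEFAULT_STUDY_PERIOD,
) -> tuple[str, str, Optional[str]]:
    """Coerce one parsed value to the field's vocabulary.

    Returns ``(encoded_value, status, failure_code)`` with status in
    {ok, coerced, failed}.  Categorical/binary values match the vocabulary
    case-insensitively, directly or through the synonym map; integers must
    fall in the field range; dates must be real and in-period.
    """
    if synonym_map is None:
        synonym_map = default_synonym_map()

    if v is None:
        return UNSPECIFIED, "coerced", None

    if spec.value_type == "integer":
        if isinstance(v, bool):
            return UNSPECIFIED, "failed", INVALID_TYPE
        if isinstance(v, str):
            s = v.strip().rstrip("%").strip()
            if s == UNSPECIFIED or s.lower() in synonym_map and synonym_map[s.lower()] == UNSPECIFIED:
                return UNSPECIFIED, "coerced", None
            try:
                num = int(float(s))
            except ValueError:
                return UNSPECIFIED, "failed", INVALID_TYPE
            status = "coerced"
        elif isinstance(v, (int, float)):
            num = int(v)
            status = "ok" if isinstance(v, int) else "coerced"
        else:
            return UNSPECIFIED, "failed", INVALID_TYPE
        lo, hi = spec.numeric_range
        if not lo <= num <= hi:
            return UNSPECIFIED, "failed", OUT_OF_RANGE
        return str(num), status, None

    if spec.value_type == "date":
        if isinstance(v, str) and v.strip() == UNSPECIFIED:
            return UNSPECIFIED, "ok", None
        d = validate_date(v, period)
        if isinstance(d, str):
            return UNSPECIFIED, "failed", INVALID_DATE
        encoded = d.isoformat()
        status = "ok" if (isinstance(v, str) and v.strip() == encoded) else "coerced"
        return encoded, status, None

    if spec.value_type == "drug_set":
        if isinstance(v, str):
            if v.strip() == UNSPECIFIED:
                return UNSPECIFIED, "ok", None
            mentions = re.split(r"[|,+/;]", v)
        elif isinstance(v, (list, tuple, set, frozenset)):
            mentions = list(v)
        else:
            return UNSPECIFIED, "failed", INVALID_TYPE
        ingredients = harmonize_regimen(mentions, brand_map)
        if not ingredients:
            return UNSPECIFIED, "coerced", None
        encoded = spec.encode(ingredients)
        raw_encoded = spec.encode([str(m) for m in mentions if str(m).strip()])
        status = "ok" if encoded == raw_encoded and not isinstance(v, str) else "coerced"
        return encoded, status, None

    # binary / categorical
    if not isinstance(v, str):
        v = str(v)
    s = v.strip()
    if s in spec.allowed_labels or s == UNSPECIFIED:
        return s, "ok", None
    lowered = s.lower()
    by_case = {lbl.lower(): lbl for lbl in spec.allowed_labels}
    if lowered in by_case:
        return by_case[lowered], "coerced", None
    if lowered in synonym_map:
        mapped = synonym_map[lowered]
        if mapped in spec.allowed_labels or mapped == UNSPECIFIED:
            return mapped, "coerced", None
    return UNSPECIFIED, "failed", UNKNOWN_LABEL


# ---------------------------------------------------------------------------
# The repair loop
# ---------------------------------------------------------------------------

def repair_loop(
    raw: RawPayload,
    spec: FieldSpec,
    max_attempts: int = 3,
    synonym_map: Optional[Mapping[str, str]] = None,
    brand_map: Optional[Mapping[str, str]] = None,
    period: StudyPeriod = DEFAULT_STUDY_PERIOD,
    patient_id: str = "",
) -> CoercionResult:
    """Parse → repair → coerce one field of one payload; never raises.

    ``status`` is ``ok`` when the payload parsed on the first attempt and the
    value needed no coercion, ``coerced`` when only the value was adjusted,
    ``repaired`` when a repair transform was needed, and ``failed`` when the
    loop exhausted its attempts or the value could not be made conformant.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    parsed, attempts = parse_with_repairs(raw.raw_text, max_attempts)

    def record(value: str, failure_code: Optional[str] = None) -> LabelRecord:
        return LabelRecord(note_id=raw.note_id, patient_id=patient_id,
                           field_id=spec.field_id, source=raw.workflow_id,
                           value=value, failure_code=failure_code)

    if isinstance(parsed, ParseFailure):
        return CoercionResult(record(UNSPECIFIED, MALFORMED_JSON), "failed",
                              attempts, MALFORMED_JSON)

    if spec.field_id not in parsed:
        return CoercionResult(record(UNSPECIFIED, MISSING_FIELD), "failed",
                              attempts, MISSING_FIELD)

    value, status, failure_code = coerce_value(
        spec, parsed[spec.field_id], synonym_map, brand_map, period)
    if status == "failed":
        return CoercionResult(record(UNSPECIFIED, failure_code), "failed",
                              attempts, failure_code)
    if attempts > 1:
        status = "repaired"
    return CoercionResult(record(value), status, attempts, None)


def postprocess_payloads(
    payloads,
    catalog,
    max_attempts: int = 3,
    synonym_map: Optional[Mapping[str, str]] = None,
    brand_map: Optional[Mapping[str, str]] = None,
    period: StudyPeriod = DEFAULT_STUDY_PERIOD,
    patient_by_note: Optional[Mapping[str, str]] = None,
):
    """Run the repair loop over every payload × catalog field.

    Returns a DataFrame of coercion outcomes, one row per (note, workflow,
    field), usable directly as a workflow prediction label table.
    """
    import pandas as pd
    if synonym_map is None:
        synonym_map = default_synonym_map()
    if brand_map is None:
        brand_map = default_brand_map()
    rows = []
    for p in payloads:
        pid = (patient_by_note or {}).get(p.note_id, "")
        for spec in catalog:
            res = repair_loop(p, spec, max_attempts, synonym_map, brand_map,
                              period, patient_id=pid)
            r = res.label_record
            rows.append((r.note_id, r.patient_id, r.field_id, r.source, r.value,
                         res.status, res.attempts, res.failure_code))
    return pd.DataFrame(rows, columns=["note_id", "patient_id", "field_id",
                                       "source", "value", "status", "attempts",
                                       "failure_code"]).astype(object)
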