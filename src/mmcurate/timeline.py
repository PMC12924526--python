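"""Patient event timelines around the index (diagnosis) date.

Each extracted label gets a timestamp in two steps: if the extractor found
an explicit date near the mention and it validates (real calendar date,
inside the study period), that date is used; otherwise the note's
encounter date is assigned.  Events are windowed to ±``window_days`` of
the patient's index date (endpoints inclusive), and within each
(patient, field, label) the earliest event is flagged as the first
occurrence — ties broken by note id — with later duplicates retained but
unflagged.  Cohort-level summaries histogram the first-occurrence offsets
per label and report their medians.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .postprocess import validate_date
from .schema import DEFAULT_STUDY_PERIOD, StudyPeriod

EXPLICIT_DATE = "explicit_date"
NOTE_DATE = "note_date"

DEFAULT_WINDOW_DAYS = 120


def assign_timestamp(
    extracted_date: Optional[str],
    note_date: dt.date,
    period: StudyPeriod = DEFAULT_STUDY_PERIOD,
) -> tuple[dt.date, str]:
    """Validated explicit date when available, else the note encounter date."""
    if extracted_date is not None:
        d = validate_date(extracted_date, period)
        if isinstance(d, dt.date):
            return d, EXPLICIT_DATE
    return note_date, NOTE_DATE


def build_timeline(
    events: pd.DataFrame,
    index_dates: Mapping[str, dt.date] | pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
    period: StudyPeriod = DEFAULT_STUDY_PERIOD,
) -> pd.DataFrame:
    """Window, timestamp, and first-occurrence-mark labeled extractions.

    ``events`` columns: patient_id, note_id, field_id, label,
    extracted_date (nullable ISO string), note_date (ISO string).
    ``index_dates`` maps patient_id -> index date (or a DataFrame with
    those two columns).  Events with |timestamp - index| > window_days are
    dropped.
    """
    if isinstance(index_dates, pd.DataFrame):
        index_map = {str(r.patient_id): _as_date(r.index_date)
                     for r in index_dates.itertuples(index=False)}
    else:
        index_map = {str(k): _as_date(v) for k, v in index_dates.items()}

    rows = []
    for r in events.itertuples(index=False):
        idx = index_map.get(str(r.patient_id))
        if idx is None:
            continue
        ts, source = assign_timestamp(
            r.extracted_date if isinstance(r.extracted_date, str) and r.extracted_date
            else None,
            _as_date(r.note_date), period)
        offset = (ts - idx).days
        if abs(offset) > window_days:
            continue
        rows.append((str(r.patient_id), str(r.note_id), r.field_id, r.label,
                     ts.isoformat(), source, offset))
    df = pd.DataFrame(rows, columns=["patient_id", "note_id", "field_id",
                                     "label", "timestamp", "source",
                                     "offset_days"])
    if df.empty:
        df["is_first"] = pd.Series(dtype=bool)
        return df
    df = df.sort_values(["patient_id", "field_id", "label", "timestamp",
                         "note_id"], kind="mergesort").reset_index(drop=True)
    df["is_first"] = ~df.duplicated(["patient_id", "field_id", "label"])
    return df


def _as_date(v) -> dt.date:
    if isinstance(v, dt.datetime):
        return v.date()
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def summarize_first_occurrences(
    timeline: pd.DataFrame,
    bin_days: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort summary of first-occurrence timing per (field, label).

    Returns ``(summary, histogram)``: the summary has one row per label
    with patient count and median/mean offset; the histogram counts first
    occurrences per ``bin_days``-wide offset bin (bin_left inclusive).
    """
    if timeline.empty:
        raise ValueError("need >= 1 timeline event")
    firsts = timeline[timeline["is_first"]]
    sum_rows, hist_rows = [], []
    for (fid, label), grp in firsts.groupby(["field_id", "label"], sort=True):
        offsets = grp["offset_days"].to_numpy(dtype=float)
        sum_rows.append((fid, label, int(grp["patient_id"].nunique()),
                         float(np.median(offsets)), float(offsets.mean())))
        bins = np.floor(offsets / bin_days).astype(int)
        for b, cnt in sorted(pd.Series(bins).value_counts().items()):
            hist_rows.append((fid, label, int(b) * bin_days, int(cnt)))
    summary = pd.DataFrame(sum_rows, columns=["field_id", "label", "n_patients",
                                              "median_offset", "mean_offset"])
    hist = pd.DataFrame(hist_rows, columns=["field_id", "label", "bin_left",
                                            "count"])
    return summary, hist
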