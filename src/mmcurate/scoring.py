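"""Scoring of workflow predictions against consensus reference labels.

Closed-vocabulary fields are scored with macro-F1 (unweighted mean of
per-class F1 over the classes observed in prediction or reference; classes
absent from both drop out).  Date fields use a buffer-tolerant weighted F1:
a predicted date counts as matching the reference iff they differ by at
most ``buffer_days`` whole days, and per-class F1 values are averaged
weighted by reference support.  Numeric fields additionally get Spearman's
rank correlation.  "Unspecified" is scored as an ordinary class by default.

Scoring is deterministic: identical inputs give bit-identical scores.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score

from .schema import UNSPECIFIED, FieldSpec

DATE_BUFFERS = (7, 30, 60, 90, 180)


def _class_labels(pred, truth, class_set=None, include_unspecified=True):
    observed = set(pred) | set(truth)
    if class_set is not None:
        labels = [c for c in class_set if c in observed]
    else:
        labels = sorted(observed)
    if not include_unspecified:
        labels = [c for c in labels if c != UNSPECIFIED]
    return labels


def macro_f1(
    pred: Sequence,
    truth: Sequence,
    class_set: Optional[Iterable] = None,
    include_unspecified: bool = True,
) -> float:
    """Unweighted mean of per-class F1.

    The class set defaults to the labels present in either vector; classes
    absent from both are dropped from the mean.
    """
    pred, truth = list(pred), list(truth)
    if not pred or len(pred) != len(truth):
        raise ValueError("pred and truth must be non-empty and aligned")
    labels = _class_labels(pred, truth, class_set, include_unspecified)
    if not labels:
        raise ValueError("no classes to score")
    return float(f1_score(truth, pred, labels=labels, average="macro",
                          zero_division=0))


def weighted_f1_dates(
    pred: Sequence[tuple],
    truth: Sequence[tuple],
    buffer_days: int,
    support_weighted: bool = True,
) -> float:
    """Buffer-tolerant F1 for (label, date) pairs.

    A prediction is a true positive for class ``c`` when its label equals
    the reference label ``c`` and the dates agree within ``buffer_days``
    (both absent also agrees).  Per-class F1 is averaged weighted by
    reference support (or unweighted on request).  Non-decreasing in
    ``buffer_days``.
    """
    if buffer_days < 0:
        raise ValueError("buffer_days must be >= 0")
    pred, truth = list(pred), list(truth)
    if not truth or len(pred) != len(truth):
        raise ValueError("truth must be non-empty and aligned with pred")

    def compatible(dp, dt_) -> bool:
        if dp is None and dt_ is None:
            return True
        if dp is None or dt_ is None:
            return False
        return abs((dp - dt_).days) <= buffer_days

    labels = sorted({lbl for lbl, _ in pred} | {lbl for lbl, _ in truth})
    f1s, weights = [], []
    for c in labels:
        tp = sum(1 for (lp, dp), (lt, dtr) in zip(pred, truth)
                 if lp == c and lt == c and compatible(dp, dtr))
        support = sum(1 for lt, _ in truth if lt == c)
        n_pred = sum(1 for lp, _ in pred if lp == c)
        fn = support - tp
        fp = n_pred - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        f1s.append(f1)
        weights.append(support)
    f1s, weights = np.asarray(f1s, float), np.asarray(weights, float)
    if support_weighted:
        if weights.sum() == 0:
            raise ValueError("reference has no support for any class")
        return float(np.average(f1s, weights=weights))
    return float(f1s.mean())


def spearman_rho(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Rank correlation with average ranks for ties; NaN when degenerate."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.size != truth.size:
        raise ValueError("pred and truth must be aligned")
    if pred.size < 3 or np.unique(pred).size < 2 or np.unique(truth).size < 2:
        return float("nan")
    rho = stats.spearmanr(pred, truth).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Field-level dispatch shared with the IRR statistic
# ---------------------------------------------------------------------------

def _date_pairs(values: Sequence[str]):
    out = []
    for v in values:
        if v == UNSPECIFIED:
            out.append((UNSPECIFIED, None))
        else:
            out.append(("Date", dt.date.fromisoformat(v)))
    return out


def field_f1(
    pred: Sequence[str],
    truth: Sequence[str],
    spec: FieldSpec,
    buffer_days: int = 30,
    include_unspecified: bool = True,
    drug_mode: str = "exact-set",
    support_weighted: bool = True,
) -> float:
    """F1 for one field under its type-appropriate definition.

    * date fields → buffer-tolerant weighted F1,
    * drug_set fields → exact-set classes (default) or per-ingredient
      micro-F1,
    * everything else → macro-F1 on the canonical labels.
    """
    if spec.value_type == "date":
        return weighted_f1_dates(_date_pairs(pred), _date_pairs(truth),
                                 buffer_days, support_weighted)
    if spec.value_type == "drug_set" and drug_mode == "per-ingredient":
        tp = fp = fn = 0
        for p, t in zip(pred, truth):
            ps = set() if p == UNSPECIFIED else set(p.split("|"))
            ts = set() if t == UNSPECIFIED else set(t.split("|"))
            tp += len(ps & ts)
            fp += len(ps - ts)
            fn += len(ts - ps)
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return macro_f1(pred, truth, include_unspecified=include_unspecified)


def _numeric_values(values: Sequence[str], spec: FieldSpec):
    out = []
    for v in values:
        if v == UNSPECIFIED:
            out.append(np.nan)
        elif spec.value_type == "date":
            out.append(float(dt.date.fromisoformat(v).toordinal()))
        else:
            out.append(float(v))
    return np.asarray(out)


NUMERIC_TYPES = ("integer", "date")


def score_workflows(
    predictions: pd.DataFrame,
    reference: pd.DataFrame,
    catalog: Sequence[FieldSpec],
    buffers: Sequence[int] = DATE_BUFFERS,
    design_buffer: int = 30,
    include_unspecified: bool = True,
    drug_mode: str = "exact-set",
    support_weighted: bool = True,
) -> pd.DataFrame:
    """Tidy score table: one row per workflow × field × metric (× buffer).

    ``predictions`` and ``reference`` are label tables keyed by
    (note_id, field_id); predictions carry multiple sources (workflows).
    Date fields are scored at every buffer (``weighted_f1``); numeric
    fields (integers and dates) additionally get ``spearman_rho``.
    """
    by_id = {s.field_id: s for s in catalog}
    unknown = set(predictions["field_id"]) - set(by_id)
    if unknown:
        raise KeyError(f"prediction field(s) not in catalog: {sorted(unknown)}")

    ref = reference.set_index(["note_id", "field_id"])["value"]
    rows = []
    for (workflow, field_id), grp in predictions.groupby(["source", "field_id"],
                                                         sort=True):
        spec = by_id[field_id]
        keys = [(n, field_id) for n in grp["note_id"]]
        mask = [k in ref.index for k in keys]
        pred_vals = [v for v, m in zip(grp["value"], mask) if m]
        truth_vals = [ref.loc[k] for k, m in zip(keys, mask) if m]
        n = len(pred_vals)
        if n == 0:
            continue
        if spec.value_type == "date":
            for b in buffers:
                val = field_f1(pred_vals, truth_vals, spec, buffer_days=b,
                               support_weighted=support_weighted)
                rows.append((workflow, field_id, "weighted_f1", b, val, n))
        else:
            val = field_f1(pred_vals, truth_vals, spec,
                           include_unspecified=include_unspecified,
                           drug_mode=drug_mode)
            rows.append((workflow, field_id, "macro_f1", None, val, n))
        if spec.value_type in NUMERIC_TYPES:
            p = _numeric_values(pred_vals, spec)
            t = _numeric_values(truth_vals, spec)
            ok = ~(np.isnan(p) | np.isnan(t))
            rho = spearman_rho(p[ok], t[ok]) if ok.sum() >= 3 else float("nan")
            rows.append((workflow, field_id, "spearman_rho", None, rho, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["workflow_id", "field_id", "metric_name",
                                      "buffer_days", "value", "n"])
    return out


def primary_f1(score_table: pd.DataFrame, design_buffer: int = 30) -> pd.DataFrame:
    """One F1 per (workflow, field): macro-F1, or weighted F1 at the design buffer."""
    macro = score_table[score_table.metric_name == "macro_f1"]
    dated = score_table[(score_table.metric_name == "weighted_f1")
                        & (score_table.buffer_days == design_buffer)]
    out = pd.concat([macro, dated], ignore_index=True)
    return out[["workflow_id", "field_id", "value", "n"]].rename(
        columns={"value": "f1"})


def wide_matrix(score_table: pd.DataFrame, design_buffer: int = 30) -> pd.DataFrame:
    """Fields × workflows F1 matrix (plot-ready)."""
    f1 = primary_f1(score_table, design_buffer)
    return f1.pivot(index="field_id", columns="workflow_id", values="f1")
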