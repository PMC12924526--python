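"""Inter-rater reliability: Krippendorff's alpha and the consensus-F1 IRR.

Two chance-independent views of annotator agreement are computed per field:

* **Krippendorff's alpha** — ``1 - D_o / D_e`` from the coincidence matrix
  of pairable values, with nominal, interval, or day-interval (for dates)
  distance; missing annotations are excluded pairwise.
* **IRR-F1** — the mean of each annotator's F1 against the arbitrated
  consensus, using the same per-field F1 definition as workflow scoring.
  IRR-F1 doubles as a measure of abstraction difficulty: it is the
  covariate the driver analysis regresses workflow performance on.

Arbitration follows the double-abstraction gold standard: where the two
independent annotators agree their label stands; where they disagree the
third abstractor's label is adopted.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schema import UNSPECIFIED, FieldSpec
from . import scoring

METRICS = ("nominal", "interval", "date_days")


def _to_numeric(values, metric: str) -> np.ndarray:
    if metric == "date_days":
        return np.array([dt.date.fromisoformat(v).toordinal() for v in values],
                        dtype=float)
    return np.asarray(values, dtype=float)


def krippendorff_alpha(matrix, metric: str = "nominal") -> float:
    """Krippendorff's alpha for a units × annotators matrix.

    ``matrix`` is a 2-D array-like or DataFrame (rows = items, columns =
    annotators, ``None``/NaN = missing).  Units with fewer than two
    non-missing values are skipped.  Returns NaN when expected disagreement
    is zero (all pairable values identical), which is reported as
    not-computable rather than perfect agreement.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    arr = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(
        matrix, dtype=object)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 annotators")

    units = []
    for row in arr:
        vals = [v for v in row
                if v is not None and not (isinstance(v, float) and np.isnan(v))]
        if len(vals) >= 2:
            units.append(vals)
    if len(units) < 2:
        raise ValueError("need >= 2 items with pairable values")

    domain = sorted({v for u in units for v in u}, key=str)
    index = {v: i for i, v in enumerate(domain)}
    k = len(domain)

    # distance matrix
    if metric == "nominal":
        delta = 1.0 - np.eye(k)
    else:
        nums = _to_numeric(domain, metric)
        delta = (nums[:, None] - nums[None, :]) ** 2

    # coincidence matrix: each ordered within-unit pair weighted 1/(m_u - 1)
    coincidence = np.zeros((k, k))
    for vals in units:
        m = len(vals)
        counts = np.zeros(k)
        for v in vals:
            counts[index[v]] += 1
        pair = np.outer(counts, counts) - np.diag(counts)
        coincidence += pair / (m - 1)

    n_c = coincidence.sum(axis=1)
    n_total = n_c.sum()
    d_o = (coincidence * delta).sum() / n_total
    d_e = (np.outer(n_c, n_c) * delta).sum() / (n_total * (n_total - 1))
    if d_e == 0:
        return float("nan")
    return float(1.0 - d_o / d_e)


def arbitrate(a: Sequence, b: Sequence, arbiter: Sequence) -> list:
    """Consensus labels: annotator agreement stands, disagreement defers
    to the arbiter; a missing arbiter where needed is an error."""
    if not (len(a) == len(b) == len(arbiter)):
        raise ValueError("label vectors must have equal length")
    out = []
    for i, (x, y, z) in enumerate(zip(a, b, arbiter)):
        if x == y:
            out.append(x)
        else:
            if z is None or (isinstance(z, float) and np.isnan(z)):
                raise ValueError(f"arbiter label missing at disagreement (item {i})")
            out.append(z)
    return out


def irr_f1(
    a: Sequence[str],
    b: Sequence[str],
    consensus: Sequence[str],
    spec: FieldSpec,
    buffer_days: int = 30,
    include_unspecified: bool = True,
) -> float:
    """Mean F1 of each annotator against consensus; symmetric in (a, b)."""
    if not len(a):
        raise ValueError("empty input")
    fa = scoring.field_f1(list(a), list(consensus), spec, buffer_days,
                          include_unspecified)
    fb = scoring.field_f1(list(b), list(consensus), spec, buffer_days,
                          include_unspecified)
    return 0.5 * (fa + fb)


def alpha_metric_for(spec: FieldSpec) -> str:
    """Default distance metric per field type."""
    if spec.value_type == "date":
        return "date_days"
    if spec.value_type == "integer":
        return "interval"
    return "nominal"


def _alpha_matrix(a_vals, b_vals, spec: FieldSpec):
    metric = alpha_metric_for(spec)
    if metric != "nominal":
        # dates/integers: "Unspecified" is not on the interval scale; pairs
        # involving it are excluded pairwise
        rows = []
        for x, y in zip(a_vals, b_vals):
            rows.append([x if x != UNSPECIFIED else None,
                         y if y != UNSPECIFIED else None])
        return rows, metric
    return [[x, y] for x, y in zip(a_vals, b_vals)], metric


def compute_irr_report(
    annotator_a: pd.DataFrame,
    annotator_b: pd.DataFrame,
    arbiter: pd.DataFrame,
    catalog: Sequence[FieldSpec],
    notes: Optional[pd.DataFrame] = None,
    buffer_days: int = 30,
) -> pd.DataFrame:
    """Per-field alpha, IRR-F1 and n, plus split-restricted variants.

    Inputs are label tables; when ``notes`` (with a ``split`` column) is
    given, a ``test``-only report is computed alongside the combined one.
    """
    splits: dict[str, Optional[set]] = {"combined": None}
    if notes is not None and "split" in notes.columns:
        splits["test"] = set(notes.loc[notes["split"] == "test", "note_id"])

    rows = []
    for spec in catalog:
        av = annotator_a[annotator_a.field_id == spec.field_id].set_index("note_id")["value"]
        bv = annotator_b[annotator_b.field_id == spec.field_id].set_index("note_id")["value"]
        rv = arbiter[arbiter.field_id == spec.field_id].set_index("note_id")["value"]
        common = av.index.intersection(bv.index).intersection(rv.index)
        for split_name, keep in splits.items():
            idx = [n for n in common if keep is None or n in keep]
            if not idx:
                continue
            a, b, r = list(av.loc[idx]), list(bv.loc[idx]), list(rv.loc[idx])
            consensus = arbitrate(a, b, r)
            mat, metric = _alpha_matrix(a, b, spec)
            try:
                alpha = krippendorff_alpha(mat, metric)
            except ValueError:
                alpha = float("nan")
            f1 = irr_f1(a, b, consensus, spec, buffer_days)
            rows.append((spec.field_id, split_name, alpha, f1, len(idx)))
    return pd.DataFrame(rows, columns=["field_id", "split", "k_alpha",
                                       "irr_f1", "n_items"])


def irr_study_averages(report: pd.DataFrame) -> pd.DataFrame:
    """Study-level mean alpha and IRR-F1 per split."""
    return (report.groupby("split")[["k_alpha", "irr_f1"]]
            .mean().reset_index())
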