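"""Drivers of workflow performance: ANOVA, post-hoc tests, trendlines.

The design has one observation per (workflow, field): its F1, the
workflow's model size (8B vs 70B) and prompt style (ZSL vs CoT), the
field's 3-way type (numeric / binary / categorical), and the field's
IRR-F1 (difficulty of abstraction).  A sequential (Type-I) ANOVA in the
fixed order model_size, prompt_style, irr_f1, field_type yields per-term
F statistics and eta-squared effect sizes (term SS over total SS, so the
effect sizes including the residual sum to one).

Post-hoc: paired t-tests pairing the two levels of model size and prompt
style within each field, OLS of F1 on IRR-F1, and a one-way ANOVA with
Tukey HSD over field type.  Trendlines fit per-workflow OLS of F1 on
IRR-F1 and report pairwise crossing points inside the observed IRR range.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .schema import FieldSpec

MODEL_SIZES = ("8B", "70B")
PROMPT_STYLES = ("ZSL", "CoT")
LLAMA_WORKFLOWS = ("8B-ZSL", "8B-CoT", "70B-ZSL", "70B-CoT")

DEFAULT_TERM_ORDER = ("model_size", "prompt_style", "irr_f1", "field_type")


def field_type_of(spec: FieldSpec, date_field_type: str = "numeric") -> str:
    """Map a field's value type onto the 3-way ANOVA typing."""
    if spec.value_type == "integer":
        return "numeric"
    if spec.value_type == "date":
        return date_field_type
    if spec.value_type == "binary":
        return "binary"
    return "categorical"


def parse_workflow_id(workflow_id: str) -> tuple[str, str]:
    size, prompt = workflow_id.split("-", 1)
    if size not in MODEL_SIZES or prompt not in PROMPT_STYLES:
        raise ValueError(f"not a Llama workflow id: {workflow_id!r}")
    return size, prompt


def build_design(
    f1_table: pd.DataFrame,
    irr_report: pd.DataFrame,
    catalog: Sequence[FieldSpec],
    workflows: Sequence[str] = LLAMA_WORKFLOWS,
    irr_split: str = "combined",
    date_field_type: str = "numeric",
) -> pd.DataFrame:
    """One design row per (workflow, field).

    ``f1_table`` holds columns (workflow_id, field_id, f1), e.g. from
    :func:`mmcurate.scoring.primary_f1`; ``irr_report`` supplies per-field
    IRR-F1 (the ``irr_split`` rows).  Every listed workflow must score
    every field exactly once.
    """
    by_id = {s.field_id: s for s in catalog}
    irr = irr_report[irr_report["split"] == irr_split].set_index("field_id")["irr_f1"] \
        if "split" in irr_report.columns else irr_report.set_index("field_id")["irr_f1"]

    sub = f1_table[f1_table.workflow_id.isin(workflows)]
    dup = sub.duplicated(["workflow_id", "field_id"])
    if dup.any():
        raise ValueError("duplicate (workflow, field) observations in design")
    rows = []
    for wf in workflows:
        size, prompt = parse_workflow_id(wf)
        got = sub[sub.workflow_id == wf].set_index("field_id")["f1"]
        missing = set(by_id) - set(got.index)
        if missing:
            raise ValueError(f"missing F1 for workflow {wf}, fields {sorted(missing)}")
        for fid, spec in by_id.items():
            rows.append((wf, fid, float(got[fid]), size, prompt,
                         field_type_of(spec, date_field_type), float(irr[fid])))
    return pd.DataFrame(rows, columns=["workflow_id", "field_id", "f1",
                                       "model_size", "prompt_style",
                                       "field_type", "irr_f1"])


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one term (treatment coding, first level dropped)."""
    if term == "irr_f1":
        return design[["irr_f1"]].to_numpy(float)
    levels = sorted(design[term].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {term} needs >= 2 levels")
    return np.column_stack([(design[term] == lv).to_numpy(float)
                            for lv in levels[1:]])


def anova_f1(
    design: pd.DataFrame,
    order: Sequence[str] = DEFAULT_TERM_ORDER,
) -> pd.DataFrame:
    """Sequential (Type-I) ANOVA of F1 on the design factors.

    Terms enter strictly in ``order`` (default: model size, prompt style,
    IRR-F1, field type); each term's sum of squares is the drop in
    residual SS when it joins the model.  Returns one row per term plus a
    Residuals row with columns df, sum_sq, mean_sq, F, eta_sq, p_value;
    eta_sq = SS_term / SS_total, so effect sizes including the residual
    sum to one.
    """
    if design["f1"].nunique() <= 1:
        raise ValueError("response is constant; ANOVA not computable")
    y = design["f1"].to_numpy(float)
    n = y.size
    X = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    ss_total = rss_prev
    rows = []
    for term in order:
        cols = _term_columns(design, term)
        X = np.column_stack([X, cols])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"singular design when adding term {term}")
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(resid @ resid)
        rows.append((term, cols.shape[1], rss_prev - rss))
        rss_prev = rss
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_prev / df_resid
    out_rows = []
    for term, df_t, ss in rows:
        ms = ss / df_t
        f = ms / ms_resid if ms_resid > 0 else float("nan")
        p = float(stats.f.sf(f, df_t, df_resid)) if np.isfinite(f) else float("nan")
        out_rows.append((term, df_t, ss, ms, f, ss / ss_total, p))
    out_rows.append(("Residuals", df_resid, rss_prev, ms_resid, float("nan"),
                     rss_prev / ss_total, float("nan")))
    return pd.DataFrame(out_rows, columns=["term", "df", "sum_sq", "mean_sq",
                                           "F", "eta_sq", "p_value"])


def _paired_level_test(design: pd.DataFrame, factor: str, hi: str, lo: str):
    """Within-field paired t-test of two factor levels (other factors averaged)."""
    means = (design.groupby(["field_id", factor])["f1"].mean()
             .unstack(factor))
    if len(means) < 2:
        raise ValueError("need >= 2 fields for pairing")
    diffs = (means[hi] - means[lo]).to_numpy()
    estimate = float(diffs.mean())
    if np.allclose(diffs, diffs[0]):
        if np.allclose(diffs, 0.0):
            return 0.0, 0.0, 1.0
    t, p = stats.ttest_1samp(diffs, 0.0)
    return estimate, float(t), float(p)


def posthoc(design: pd.DataFrame) -> dict:
    """Univariate post-hoc tests of each performance driver.

    Returns a dict with a tidy ``table`` (estimate/statistic/p per driver),
    the Tukey HSD pairwise comparison of field types, and the raw OLS fit
    of F1 on IRR-F1.
    """
    rows = []
    est, t, p = _paired_level_test(design, "model_size", "70B", "8B")
    rows.append(("model_size_70B_vs_8B", est, t, p, "paired t-test"))
    est, t, p = _paired_level_test(design, "prompt_style", "CoT", "ZSL")
    rows.append(("prompt_style_CoT_vs_ZSL", est, t, p, "paired t-test"))

    ols = smf.ols("f1 ~ irr_f1", data=design).fit()
    rows.append(("irr_f1", float(ols.params["irr_f1"]),
                 float(ols.tvalues["irr_f1"]), float(ols.pvalues["irr_f1"]), "OLS"))

    groups = [g["f1"].to_numpy() for _, g in design.groupby("field_type")]
    f_stat, f_p = stats.f_oneway(*groups)
    rows.append(("field_type", float("nan"), float(f_stat), float(f_p),
                 "one-way ANOVA"))

    tukey = pairwise_tukeyhsd(design["f1"].to_numpy(),
                              design["field_type"].to_numpy())
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])

    table = pd.DataFrame(rows, columns=["driver", "estimate", "statistic",
                                        "p_value", "test"])
    return {"table": table, "tukey": tukey_df, "ols_fit": ols}


def trendlines(
    design: pd.DataFrame,
    extra_workflows: Optional[pd.DataFrame] = None,
) -> dict:
    """Per-workflow OLS of F1 on IRR-F1 and pairwise crossing points.

    ``extra_workflows`` (same columns, e.g. an encoder baseline) is
    appended before fitting.  Crossings are reported only when the lines
    are non-parallel and the intersection falls inside the observed IRR
    range.
    """
    data = design if extra_workflows is None else pd.concat(
        [design, extra_workflows], ignore_index=True)
    fits = []
    for wf, grp in data.groupby("workflow_id", sort=True):
        if grp["irr_f1"].nunique() < 2:
            raise ValueError(f"workflow {wf} needs >= 2 distinct IRR values")
        res = stats.linregress(grp["irr_f1"], grp["f1"])
        fits.append((wf, float(res.slope), float(res.intercept),
                     float(res.rvalue), len(grp)))
    fits_df = pd.DataFrame(fits, columns=["workflow_id", "slope", "intercept",
                                          "r", "n"])

    lo, hi = float(data["irr_f1"].min()), float(data["irr_f1"].max())
    crossings = []
    for i in range(len(fits_df)):
        for j in range(i + 1, len(fits_df)):
            a, b = fits_df.iloc[i], fits_df.iloc[j]
            if np.isclose(a.slope, b.slope):
                continue  # parallel (or identical): no unique crossing
            x = (b.intercept - a.intercept) / (a.slope - b.slope)
            if lo <= x <= hi:
                y = a.intercept + a.slope * x
                crossings.append((a.workflow_id, b.workflow_id,
                                  float(x), float(y)))
    crossings_df = pd.DataFrame(crossings, columns=["workflow_a", "workflow_b",
                                                    "irr_at_crossing",
                                                    "f1_at_crossing"])
    return {"fits": fits_df, "crossings": crossings_df,
            "irr_range": (lo, hi)}
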