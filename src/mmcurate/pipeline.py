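"""End-to-end composition of the evaluation stages.

simulate → adjudicate (IRR) → post-process → score → analyze drivers →
select workflows → build timelines.  Used by the command-line interface
and by the reproduction script; every stage is a pure function of the
bundle and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import agreement, drivers, postprocess, scoring, selector, timeline
from .schema import UNSPECIFIED, apply_field_exclusion
from .simulate import (GeneratedBundle, ScenarioConfig, simulate_corpus,
                       simulate_timeline_events)


@dataclass
class PipelineResult:
    bundle: GeneratedBundle
    retained_catalog: list
    excluded_fields: list
    irr_report: pd.DataFrame
    irr_averages: pd.DataFrame
    predictions: pd.DataFrame
    score_table: pd.DataFrame
    f1_table: pd.DataFrame
    design: pd.DataFrame
    anova: pd.DataFrame
    posthoc: dict
    trend: dict
    recommendations: pd.DataFrame
    timeline_events: pd.DataFrame
    timeline_table: pd.DataFrame
    timeline_summary: pd.DataFrame
    timeline_hist: pd.DataFrame


def presence_fractions(reference: pd.DataFrame) -> dict[str, float]:
    """Fraction of notes in which each field's value is not Unspecified."""
    out = {}
    for fid, grp in reference.groupby("field_id"):
        out[fid] = float((grp["value"] != UNSPECIFIED).mean())
    return out


def consensus_table(bundle: GeneratedBundle) -> pd.DataFrame:
    """Arbitrated consensus labels as a reference label table."""
    a = bundle.annotator_a.set_index(["note_id", "field_id"])["value"]
    b = bundle.annotator_b.set_index(["note_id", "field_id"])["value"]
    r = bundle.arbiter.set_index(["note_id", "field_id"])["value"]
    cons = bundle.arbiter.copy()
    vals = []
    for row in cons.itertuples(index=False):
        key = (row.note_id, row.field_id)
        vals.append(a[key] if a[key] == b[key] else r[key])
    cons["value"] = vals
    cons["source"] = "consensus"
    return cons


def run_pipeline(
    cfg: Optional[ScenarioConfig] = None,
    seed: int = 0,
    buffers=scoring.DATE_BUFFERS,
    design_buffer: int = 30,
    threshold: float = selector.DEFAULT_IRR_THRESHOLD,
    window_days: Optional[int] = None,
    scoring_split: Optional[str] = None,
) -> PipelineResult:
    """Run every stage on one synthetic study.

    ``scoring_split`` restricts scoring/analysis to one split ("dev" or
    "test"); default scores all annotated notes.
    """
    cfg = cfg or ScenarioConfig()
    bundle = simulate_corpus(cfg, seed)
    catalog = bundle.catalog

    # adjudication / IRR
    irr_report = agreement.compute_irr_report(
        bundle.annotator_a, bundle.annotator_b, bundle.arbiter, catalog,
        bundle.notes)
    irr_averages = agreement.irr_study_averages(irr_report)

    # consensus reference and sparse-field exclusion
    reference = consensus_table(bundle)
    presence = presence_fractions(reference)
    retained, excluded = apply_field_exclusion(catalog, presence,
                                               cfg.min_presence_fraction)

    # strict-schema post-processing of raw payloads
    patient_by_note = dict(zip(bundle.notes["note_id"],
                               bundle.notes["patient_id"]))
    predictions = postprocess.postprocess_payloads(
        bundle.payloads, retained, period=cfg.period,
        patient_by_note=patient_by_note)

    ref = reference
    preds = predictions
    if scoring_split is not None:
        keep = set(bundle.notes.loc[bundle.notes["split"] == scoring_split,
                                    "note_id"])
        ref = ref[ref["note_id"].isin(keep)]
        preds = preds[preds["note_id"].isin(keep)]

    score_table = scoring.score_workflows(preds, ref, retained, buffers,
                                          design_buffer)
    f1_table = scoring.primary_f1(score_table, design_buffer)

    # driver analysis over the four Llama-style workflows
    retained_irr = irr_report[irr_report.field_id.isin(
        [s.field_id for s in retained])]
    design = drivers.build_design(f1_table, retained_irr, retained,
                                  workflows=cfg.workflows)
    anova = drivers.anova_f1(design)
    post = drivers.posthoc(design)

    extra = None
    bert_ids = set(f1_table.workflow_id) - set(cfg.workflows)
    if bert_ids:
        rows = []
        irr = retained_irr[retained_irr.split == "combined"].set_index(
            "field_id")["irr_f1"]
        sub = f1_table[f1_table.workflow_id.isin(bert_ids)]
        for r in sub.itertuples(index=False):
            rows.append((r.workflow_id, r.field_id, r.f1, "encoder", "none",
                         "n/a", float(irr[r.field_id])))
        extra = pd.DataFrame(rows, columns=["workflow_id", "field_id", "f1",
                                            "model_size", "prompt_style",
                                            "field_type", "irr_f1"])
    trend = drivers.trendlines(design, extra)

    recommendations = selector.recommend_fields(retained_irr,
                                                threshold=threshold)

    # timelines on the multi-note subcohort
    events, tl_index = simulate_timeline_events(cfg, seed)
    tl = timeline.build_timeline(events, tl_index,
                                 window_days=window_days or cfg.window_days,
                                 period=cfg.period)
    tl_summary, tl_hist = timeline.summarize_first_occurrences(tl)

    return PipelineResult(
        bundle=bundle, retained_catalog=retained, excluded_fields=excluded,
        irr_report=irr_report, irr_averages=irr_averages,
        predictions=predictions, score_table=score_table, f1_table=f1_table,
        design=design, anova=anova, posthoc=post, trend=trend,
        recommendations=recommendations, timeline_events=events,
        timeline_table=tl, timeline_summary=tl_summary, timeline_hist=tl_hist)
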