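"""Synthetic study generator.

Emulates the statistical structure of the evaluation study end to end: a
corpus of single-note patients with truth labels drawn from per-field
class priors over the catalog vocabularies; two annotators who each flip a
truth label to a uniformly chosen other allowed label at a per-field
disagreement rate, with a third (arbiter) abstractor; and per-workflow
extractor payloads whose probability of being correct rises linearly with
the field's measured IRR-F1, the model size, and chain-of-thought
prompting, serialized as JSON and corrupted at configurable rates
(malformed syntax, out-of-range integers, brand-name drugs, impossible
dates).  A separate stream generates multi-note label events for patient
timelines.

The generated notes are metadata plus extractor payloads, not prose: the
package evaluates extraction outputs, it does not perform NER on text.

Determinism: everything derives from one integer seed through named
substreams (truth, annotators, extractor, corruption, timeline), so
components can be varied independently while identical (config, seed)
pairs reproduce byte-identical bundles.

Accuracy model, per field f and workflow w::

    P(correct) = clip(a0 + a_irr * IRR_f + a_size * [70B]
                      + (a_prompt + prompt_irr_slope * (irr_center - IRR_f)) * [CoT]
                      + type_effects[type(f)],  0.05, 0.99)

where ``IRR_f`` is the IRR-F1 *measured* on the simulated annotators, so
that downstream regression recovers the injected coefficients without
errors-in-variables attenuation.  Incorrect labels are drawn uniformly
from the field's generator vocabulary excluding the truth (for dates, a
uniform in-period date).  The default ``prompt_irr_slope`` of zero gives a
constant prompt effect; :func:`crossing_scenario` enables the
prompt-by-difficulty interaction (and an encoder-style baseline) that
makes zero-shot and chain-of-thought trendlines cross at high IRR.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import agreement
from .drivers import LLAMA_WORKFLOWS, field_type_of, parse_workflow_id
from .io import RawPayload
from .postprocess import default_brand_map
from .schema import (DEFAULT_STUDY_PERIOD, UNSPECIFIED, FieldSpec,
                     StudyPeriod, builtin_catalog, catalog_by_id)

_STREAMS = {"patients": 0, "truth": 1, "annotator_a": 2, "annotator_b": 3,
            "extractor": 4, "corruption": 5, "timeline": 6, "split": 7,
            "calibration": 8}


def substream(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Named, independent random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_STREAMS[name], extra)))


# ---------------------------------------------------------------------------
# Defaults: class priors, IRR ladder, frozen disagreement rates
# ---------------------------------------------------------------------------

def default_class_priors() -> dict[str, dict[str, float]]:
    """Per-field label priors over the catalog vocabularies.

    Keys are canonical encoded values; integer fields use a coarse,
    clinically plausible support; drug regimens are canonical ingredient
    sets of common first-line combinations.
    """
    return {
        "mm_diagnosis": {"Yes": 0.60, "Likely": 0.08, "No": 0.05,
                         UNSPECIFIED: 0.27},
        "mm_status": {"Newly diagnosed": 0.40, "Relapsed": 0.25,
                      "Refractory": 0.12, "Remission": 0.23},
        "transplant_status": {"Eligible": 0.22, "Eligible but deferred": 0.08,
                              "Ineligible": 0.15, "Performed": 0.15,
                              UNSPECIFIED: 0.40},
        "ecog_score": {"0": 0.18, "1": 0.27, "2": 0.14, "3": 0.06, "4": 0.02,
                       "5": 0.01, UNSPECIFIED: 0.32},
        "plasmacytosis": {"0": 0.10, "5": 0.08, "10": 0.09, "20": 0.09,
                          "30": 0.08, "40": 0.06, "50": 0.05, "60": 0.04,
                          "70": 0.03, "80": 0.03, UNSPECIFIED: 0.35},
        "bone_lesion": {"Yes": 0.45, "No": 0.25, "Unrelated": 0.06,
                        UNSPECIFIED: 0.24},
        "emd_presence": {"Present": 0.18, "No": 0.42, UNSPECIFIED: 0.40},
        "emd_location": {"Paramedullary": 0.12, "Soft tissue": 0.14,
                         UNSPECIFIED: 0.74},
        "flt_regimen": {
            "bortezomib|dexamethasone|lenalidomide": 0.30,
            "daratumumab|dexamethasone|lenalidomide": 0.15,
            "carfilzomib|dexamethasone|lenalidomide": 0.08,
            "dexamethasone|lenalidomide": 0.07,
            "bortezomib|cyclophosphamide|dexamethasone": 0.05,
            UNSPECIFIED: 0.35,
        },
        "flt_response": {"Stringent Complete Response": 0.06,
                         "Complete Response": 0.12,
                         "Very Good Partial Response": 0.16,
                         "Partial Response": 0.15, "Minimal Response": 0.05,
                         "No Response": 0.06, "Progressive Disease": 0.10,
                         UNSPECIFIED: 0.30},
    }


#: Fraction of notes in which each date field carries a date at all.  FLT
#: response dates are deliberately sparse: the field is meant to fall under
#: the <10% presence exclusion, leaving 12 analyzable fields.
DEFAULT_DATE_PRESENCE = {"mm_diagnosis_date": 0.75, "flt_start_date": 0.55,
                         "flt_response_date": 0.04}

#: Difficulty ladder the default annotators are calibrated to (IRR-F1),
#: spanning 0.61-0.88 with mean ~0.74 over the 12 analyzed fields.  Each
#: 3-way field type carries roughly the same mean difficulty, so that
#: field type and difficulty act as separable performance drivers.
DEFAULT_IRR_TARGETS = {
    "mm_diagnosis": 0.86, "mm_status": 0.67, "mm_diagnosis_date": 0.80,
    "transplant_status": 0.70, "ecog_score": 0.88, "plasmacytosis": 0.61,
    "bone_lesion": 0.64, "emd_presence": 0.85, "emd_location": 0.62,
    "flt_regimen": 0.77, "flt_start_date": 0.68, "flt_response": 0.83,
    "flt_response_date": 0.70,
}

#: Per-field annotator flip rates, frozen from one run of
#: :func:`calibrate_disagreement` against DEFAULT_IRR_TARGETS at n=250.
DEFAULT_DISAGREEMENT_RATES = {
    "mm_diagnosis": 0.0838, "mm_status": 0.3514, "mm_diagnosis_date": 0.2031,
    "transplant_status": 0.2880, "ecog_score": 0.0490, "plasmacytosis": 0.3475,
    "bone_lesion": 0.3623, "emd_presence": 0.1474, "emd_location": 0.4019,
    "flt_regimen": 0.1883, "flt_start_date": 0.3375, "flt_response": 0.1471,
    "flt_response_date": 0.4277,
}


@dataclass(frozen=True)
class AccuracyCoeffs:
    """Linear coefficients of extractor correctness probability."""

    a0: float = -0.10
    a_irr: float = 1.0
    a_size: float = 0.13
    a_prompt: float = 0.08
    prompt_irr_slope: float = 0.0
    irr_center: float = 0.74
    type_effects: Mapping[str, float] = dc_field(
        default_factory=lambda: {"binary": 0.04, "numeric": 0.0,
                                 "categorical": -0.06})
    clip: tuple[float, float] = (0.05, 0.99)


@dataclass(frozen=True)
class CorruptionConfig:
    """Rates of the payload pathologies the post-processor must absorb."""

    malformed_json: float = 0.05
    out_of_range: float = 0.02
    brand_name: float = 0.15
    bad_date: float = 0.03
    #: relative weights of fence-wrapping, trailing commas (both repairable)
    #: and truncation (irreparable) among malformed payloads
    malformed_kind_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for r in (self.malformed_json, self.out_of_range, self.brand_name,
                  self.bad_date):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"corruption rate outside [0,1]: {r}")


@dataclass(frozen=True)
class BertCoeffs:
    """Encoder-baseline accuracy line (flatter in IRR than the LLMs)."""

    intercept: float = 0.24
    irr_slope: float = 0.55
    workflow_id: str = "BERT"


#: Timeline event-process parameters per (field, label):
#: (poisson rate per patient, mean offset days, sd of offset days).
DEFAULT_TIMELINE_PROCESS = {
    "mm_status": {"Newly diagnosed": (1.8, 0.0, 15.0),
                  "Relapsed": (0.5, 45.0, 60.0),
                  "Refractory": (0.3, 60.0, 60.0),
                  "Remission": (0.7, 75.0, 45.0)},
    "transplant_status": {"Eligible": (0.9, 20.0, 40.0),
                          "Eligible but deferred": (0.2, 40.0, 50.0),
                          "Ineligible": (0.3, 25.0, 50.0),
                          "Performed": (0.4, 85.0, 45.0)},
    "emd_presence": {"Present": (0.5, 5.0, 20.0),
                     "No": (1.2, 10.0, 50.0)},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the study design: 250 single-note patients split
    evenly into development and test sets, four Llama-style workflows,
    the field-difficulty ladder above, and size/prompt/IRR accuracy
    coefficients of 0.13 / 0.08 / 1.0.
    """

    n_patients: int = 250
    notes_per_patient: int = 1
    split_fraction: float = 0.5
    period: StudyPeriod = DEFAULT_STUDY_PERIOD
    class_priors: Optional[Mapping[str, Mapping[str, float]]] = None
    date_presence: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_DATE_PRESENCE))
    disagreement_rates: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_DISAGREEMENT_RATES))
    coeffs: AccuracyCoeffs = AccuracyCoeffs()
    corruption: CorruptionConfig = CorruptionConfig()
    workflows: tuple[str, ...] = LLAMA_WORKFLOWS
    bert: Optional[BertCoeffs] = None
    min_presence_fraction: float = 0.10
    n_timeline_patients: int = 200
    timeline_process: Mapping[str, Mapping[str, tuple]] = dc_field(
        default_factory=lambda: {f: dict(v)
                                 for f, v in DEFAULT_TIMELINE_PROCESS.items()})
    explicit_date_prob: float = 0.30
    bad_explicit_date_prob: float = 0.05
    window_days: int = 120

    def priors(self) -> dict[str, dict[str, float]]:
        out = default_class_priors()
        if self.class_priors:
            for fid, p in self.class_priors.items():
                out[fid] = dict(p)
        for fid, pri in out.items():
            total = sum(pri.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"priors for {fid} sum to {total}")
            if any(not 0.0 <= v <= 1.0 for v in pri.values()):
                raise ValueError(f"invalid probability in priors for {fid}")
        return out


def crossing_scenario(**overrides) -> ScenarioConfig:
    """Scenario with a prompt-by-difficulty interaction and encoder baseline.

    Zero-shot trendlines are steeper than chain-of-thought ones, so the
    ZSL and CoT fits (and the 8B vs encoder fits) cross inside the
    observed IRR range, around IRR-F1 0.8-0.85.
    """
    coeffs = AccuracyCoeffs(prompt_irr_slope=0.9)
    base = ScenarioConfig(coeffs=coeffs, bert=BertCoeffs())
    return replace(base, **overrides) if overrides else base


@dataclass
class GeneratedBundle:
    """Everything the downstream stages consume, plus generative truth."""

    config: ScenarioConfig
    seed: int
    catalog: list[FieldSpec]
    notes: pd.DataFrame          # note_id, patient_id, note_date, split
    index_dates: pd.DataFrame    # patient_id, index_date
    truth: pd.DataFrame          # label table, source="truth"
    annotator_a: pd.DataFrame
    annotator_b: pd.DataFrame
    arbiter: pd.DataFrame
    payloads: list[RawPayload]
    irr_by_field: pd.Series      # measured IRR-F1 used in the accuracy model
    accuracy: pd.DataFrame       # field x workflow true P(correct)


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def _draw_label(rng: np.random.Generator, priors: Mapping[str, float]) -> str:
    labels = list(priors)
    probs = np.array([priors[l] for l in labels], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _random_date(rng: np.random.Generator, period: StudyPeriod) -> dt.date:
    return period.start + dt.timedelta(days=int(rng.integers(0, period.n_days + 1)))


def _clip_to_period(d: dt.date, period: StudyPeriod) -> dt.date:
    return max(period.start, min(period.end, d))


def _truth_value(spec: FieldSpec, cfg: ScenarioConfig, priors, rng,
                 index_date: dt.date) -> str:
    if spec.value_type == "date":
        if rng.random() >= cfg.date_presence.get(spec.field_id, 0.5):
            return UNSPECIFIED
        if spec.field_id == "mm_diagnosis_date":
            d = index_date
        elif spec.field_id == "flt_start_date":
            d = index_date + dt.timedelta(days=int(rng.integers(0, 91)))
        else:  # flt_response_date
            d = index_date + dt.timedelta(days=int(rng.integers(30, 151)))
        return _clip_to_period(d, cfg.period).isoformat()
    return _draw_label(rng, priors[spec.field_id])


def field_vocabulary(spec: FieldSpec, priors) -> list[str]:
    """Generator vocabulary: the prior support (non-date fields)."""
    return list(priors[spec.field_id])


def _other_value(spec: FieldSpec, current: str, cfg: ScenarioConfig, priors,
                 rng: np.random.Generator) -> str:
    """Uniform draw from the field vocabulary excluding ``current``."""
    if spec.value_type == "date":
        if current != UNSPECIFIED and rng.random() < 0.3:
            return UNSPECIFIED
        d = _random_date(rng, cfg.period)
        return d.isoformat()
    vocab = [v for v in field_vocabulary(spec, priors) if v != current]
    if not vocab:
        return current
    return vocab[int(rng.integers(len(vocab)))]


def simulate_corpus(cfg: ScenarioConfig, seed: int) -> GeneratedBundle:
    """Generate the full bundle: notes, truth, annotators, payloads."""
    catalog = builtin_catalog()
    priors = cfg.priors()
    n_notes = cfg.n_patients * cfg.notes_per_patient

    rng_p = substream(seed, "patients")
    rng_t = substream(seed, "truth")
    rng_s = substream(seed, "split")

    margin = cfg.window_days + 240
    patient_rows, note_rows, truth_rows = [], [], []
    index_by_patient: dict[str, dt.date] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        idx = cfg.period.start + dt.timedelta(
            days=int(rng_p.integers(cfg.window_days, cfg.period.n_days - margin)))
        index_by_patient[pid] = idx
        patient_rows.append((pid, idx.isoformat()))

    note_ids = []
    for i, (pid, idx_iso) in enumerate(patient_rows):
        idx = dt.date.fromisoformat(idx_iso)
        for j in range(cfg.notes_per_patient):
            nid = f"N{len(note_ids) + 1:05d}"
            note_ids.append(nid)
            note_date = _clip_to_period(
                idx + dt.timedelta(days=int(rng_p.integers(-60, 61))), cfg.period)
            note_rows.append((nid, pid, note_date.isoformat()))
            for spec in catalog:
                val = _truth_value(spec, cfg, priors, rng_t, idx)
                truth_rows.append((nid, pid, spec.field_id, "truth", val))

    # random even split into development and test sets
    n_dev = int(round(n_notes * cfg.split_fraction))
    perm = rng_s.permutation(n_notes)
    split = np.array(["test"] * n_notes, dtype=object)
    split[perm[:n_dev]] = "dev"
    notes = pd.DataFrame(note_rows, columns=["note_id", "patient_id", "note_date"])
    notes["split"] = split

    truth = pd.DataFrame(truth_rows, columns=["note_id", "patient_id",
                                              "field_id", "source", "value"])
    index_dates = pd.DataFrame(patient_rows, columns=["patient_id", "index_date"])

    ann_a, ann_b, arbiter = simulate_annotators(
        truth, cfg.disagreement_rates, catalog, seed, cfg, priors)

    irr_rep = agreement.compute_irr_report(ann_a, ann_b, arbiter, catalog, notes)
    irr_by_field = (irr_rep[irr_rep.split == "combined"]
                    .set_index("field_id")["irr_f1"])

    payloads, accuracy = simulate_extractor(
        truth, cfg.workflows, irr_by_field, cfg, seed, catalog, priors)

    return GeneratedBundle(config=cfg, seed=seed, catalog=catalog, notes=notes,
                           index_dates=index_dates, truth=truth,
                           annotator_a=ann_a, annotator_b=ann_b,
                           arbiter=arbiter, payloads=payloads,
                           irr_by_field=irr_by_field, accuracy=accuracy)


# ---------------------------------------------------------------------------
# Annotators
# ---------------------------------------------------------------------------

def simulate_annotators(
    truth: pd.DataFrame,
    rates: Mapping[str, float],
    catalog: Sequence[FieldSpec],
    seed: int,
    cfg: Optional[ScenarioConfig] = None,
    priors=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two independent noisy annotators plus an arbiter equal to truth.

    Each annotator flips each truth label, independently and with the
    field's disagreement rate, to a uniformly chosen other allowed value.
    """
    cfg = cfg or ScenarioConfig()
    priors = priors if priors is not None else cfg.priors()
    by_id = catalog_by_id(catalog)
    for fid, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"disagreement rate outside [0,1] for {fid}: {r}")

    def one(source: str, stream: str) -> pd.DataFrame:
        rng = substream(seed, stream)
        rows = []
        for r in truth.itertuples(index=False):
            spec = by_id[r.field_id]
            val = r.value
            if rng.random() < rates.get(r.field_id, 0.0):
                val = _other_value(spec, val, cfg, priors, rng)
            rows.append((r.note_id, r.patient_id, r.field_id, source, val))
        return pd.DataFrame(rows, columns=["note_id", "patient_id", "field_id",
                                           "source", "value"])

    ann_a = one("annotator-A", "annotator_a")
    ann_b = one("annotator-B", "annotator_b")
    arbiter = truth.copy()
    arbiter["source"] = "arbiter"
    return ann_a, ann_b, arbiter


# ---------------------------------------------------------------------------
# Extractor payloads
# ---------------------------------------------------------------------------

def workflow_accuracy(
    irr_by_field: Mapping[str, float],
    workflows: Sequence[str],
    coeffs: AccuracyCoeffs,
    catalog: Sequence[FieldSpec],
    bert: Optional[BertCoeffs] = None,
) -> pd.DataFrame:
    """True P(correct) per field × workflow under the linear model."""
    lo, hi = coeffs.clip
    rows = {}
    for spec in catalog:
        irr = float(irr_by_field[spec.field_id])
        ftype = field_type_of(spec)
        row = {}
        for wf in workflows:
            size, prompt = parse_workflow_id(wf)
            acc = (coeffs.a0 + coeffs.a_irr * irr
                   + coeffs.a_size * (size == "70B")
                   + (coeffs.a_prompt
                      + coeffs.prompt_irr_slope * (coeffs.irr_center - irr))
                   * (prompt == "CoT")
                   + coeffs.type_effects.get(ftype, 0.0))
            row[wf] = float(np.clip(acc, lo, hi))
        if bert is not None:
            row[bert.workflow_id] = float(np.clip(
                bert.intercept + bert.irr_slope * irr, lo, hi))
        rows[spec.field_id] = row
    return pd.DataFrame(rows).T


def _payload_value(spec: FieldSpec, encoded: str):
    """JSON-side representation of a canonical value."""
    if encoded == UNSPECIFIED:
        return UNSPECIFIED
    if spec.value_type == "integer":
        return int(encoded)
    if spec.value_type == "drug_set":
        return sorted(encoded.split("|"))
    return encoded


_BAD_DATES = ("2021-02-30", "2021-13-01", "0000-00-00", "last spring")


def _corrupt_values(values: dict, catalog, corr: CorruptionConfig, rng,
                    reverse_brand: Mapping[str, str]) -> dict:
    out = dict(values)
    for spec in catalog:
        v = out.get(spec.field_id)
        if v == UNSPECIFIED or v is None:
            continue
        if spec.value_type == "integer" and rng.random() < corr.out_of_range:
            out[spec.field_id] = int(spec.numeric_range[1] + 1 + rng.integers(0, 900))
        elif spec.value_type == "date" and rng.random() < corr.bad_date:
            out[spec.field_id] = _BAD_DATES[int(rng.integers(len(_BAD_DATES)))]
        elif spec.value_type == "drug_set" and rng.random() < corr.brand_name:
            out[spec.field_id] = [reverse_brand.get(ing, ing).title()
                                  for ing in v]
    return out


def _malform(text: str, corr: CorruptionConfig, rng) -> str:
    w = np.array(corr.malformed_kind_weights, dtype=float)
    kind = rng.choice(3, p=w / w.sum())
    if kind == 0:    # markdown fences + prose: repairable on attempt 2
        return "Here is the extraction:\n```json\n" + text + "\n```"
    if kind == 1:    # trailing comma: repairable on attempt 3
        return text[:-1].rstrip() + ", }"
    return text[:max(1, len(text) - 5)]  # truncation: irreparable


def simulate_extractor(
    truth: pd.DataFrame,
    workflows: Sequence[str],
    irr_by_field: Mapping[str, float],
    cfg: ScenarioConfig,
    seed: int,
    catalog: Optional[Sequence[FieldSpec]] = None,
    priors=None,
) -> tuple[list[RawPayload], pd.DataFrame]:
    """Raw JSON payloads for every (note, workflow), with corruption.

    Returns ``(payloads, accuracy)`` where accuracy is the true
    field × workflow P(correct) matrix used for the draws.
    """
    catalog = list(catalog) if catalog is not None else builtin_catalog()
    priors = priors if priors is not None else cfg.priors()
    accuracy = workflow_accuracy(irr_by_field, workflows, cfg.coeffs, catalog,
                                 cfg.bert)
    reverse_brand = {}
    for brand, ing in default_brand_map().items():
        reverse_brand.setdefault(ing, brand)

    rng_e = substream(seed, "extractor")
    rng_c = substream(seed, "corruption")
    by_note = {nid: grp for nid, grp in truth.groupby("note_id", sort=True)}
    acc = {(fid, wf): float(accuracy.loc[fid, wf])
           for fid in accuracy.index for wf in accuracy.columns}

    payloads: list[RawPayload] = []
    all_workflows = list(accuracy.columns)
    for nid in sorted(by_note):
        grp = by_note[nid]
        truth_map = dict(zip(grp["field_id"], grp["value"]))
        for wf in all_workflows:
            values = {}
            for spec in catalog:
                tv = truth_map[spec.field_id]
                if rng_e.random() < acc[(spec.field_id, wf)]:
                    enc = tv
                else:
                    enc = _other_value(spec, tv, cfg, priors, rng_e)
                values[spec.field_id] = _payload_value(spec, enc)
            values = _corrupt_values(values, catalog, cfg.corruption, rng_c,
                                     reverse_brand)
            text = json.dumps(values, ensure_ascii=False)
            if rng_c.random() < cfg.corruption.malformed_json:
                text = _malform(text, cfg.corruption, rng_c)
            payloads.append(RawPayload(nid, wf, text))
    return payloads, accuracy


# ---------------------------------------------------------------------------
# Timeline event stream
# ---------------------------------------------------------------------------

def simulate_timeline_events(
    cfg: ScenarioConfig, seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-note label events for the timeline subcohort.

    Per patient and (field, label), event counts are Poisson and offsets
    from the index date are rounded normals with label-specific location
    and spread ("Newly diagnosed" and "EMD present" cluster at the index
    date; relapse/remission labels disperse later).  Offsets may fall
    outside the window; windowing is the timeline builder's job.
    """
    rng = substream(seed, "timeline")
    margin = cfg.window_days + 240
    ev_rows, idx_rows = [], []
    note_counter = 0
    for i in range(cfg.n_timeline_patients):
        pid = f"T{i + 1:04d}"
        idx = cfg.period.start + dt.timedelta(
            days=int(rng.integers(cfg.window_days, cfg.period.n_days - margin)))
        idx_rows.append((pid, idx.isoformat()))
        for fid, labels in cfg.timeline_process.items():
            for label, (lam, mu, sd) in labels.items():
                for _ in range(rng.poisson(lam)):
                    offset = int(round(rng.normal(mu, sd)))
                    note_date = _clip_to_period(
                        idx + dt.timedelta(days=offset), cfg.period)
                    note_counter += 1
                    nid = f"TN{note_counter:06d}"
                    extracted = None
                    if rng.random() < cfg.explicit_date_prob:
                        extracted = note_date.isoformat()
                        if rng.random() < cfg.bad_explicit_date_prob:
                            extracted = _BAD_DATES[int(rng.integers(len(_BAD_DATES)))]
                    ev_rows.append((pid, nid, fid, label, extracted,
                                    note_date.isoformat()))
    events = pd.DataFrame(ev_rows, columns=["patient_id", "note_id", "field_id",
                                            "label", "extracted_date",
                                            "note_date"])
    index_dates = pd.DataFrame(idx_rows, columns=["patient_id", "index_date"])
    return events, index_dates


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _simulate_field_irr(
    spec: FieldSpec, rate: float, cfg: ScenarioConfig, priors, n: int,
    rng: np.random.Generator, metric: str,
) -> float:
    # per-item index dates so date-field truths vary across items
    truth_vals = [
        _truth_value(spec, cfg, priors, rng, _random_date(rng, cfg.period))
        for _ in range(n)]

    def noisy():
        return [_other_value(spec, v, cfg, priors, rng)
                if rng.random() < rate else v for v in truth_vals]

    a, b = noisy(), noisy()
    if metric == "irr_f1":
        consensus = agreement.arbitrate(a, b, truth_vals)
        return agreement.irr_f1(a, b, consensus, spec)
    mat, m = agreement._alpha_matrix(a, b, spec)
    try:
        return agreement.krippendorff_alpha(mat, m)
    except ValueError:
        return float("nan")


def calibrate_disagreement(
    spec: FieldSpec,
    target: float,
    metric: str = "irr_f1",
    n: int = 125,
    reps: int = 32,
    iters: int = 20,
    seed: int = 0,
    cfg: Optional[ScenarioConfig] = None,
    priors=None,
) -> float:
    """Bisect the annotator flip rate so the expected statistic hits target.

    The expected IRR-F1 (or alpha) is estimated by Monte-Carlo averaging
    ``reps`` replicates at each candidate rate; the statistic decreases
    monotonically in the rate, so plain bisection on [0, 1] converges for
    targets within the attainable range.
    """
    cfg = cfg or ScenarioConfig()
    priors = priors if priors is not None else cfg.priors()

    def expected(rate: float, k: int) -> float:
        vals = []
        for r in range(reps):
            rng = substream(seed, "calibration", extra=k * reps + r)
            vals.append(_simulate_field_irr(spec, rate, cfg, priors, n, rng,
                                            metric))
        return float(np.nanmean(vals))

    lo, hi = 0.0, 1.0
    for k in range(1, iters + 1):
        mid = 0.5 * (lo + hi)
        if expected(mid, k) > target:
            lo = mid     # statistic too high -> need more disagreement
        else:
            hi = mid
    return 0.5 * (lo + hi)
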