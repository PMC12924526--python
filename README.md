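# mmcurate

Evaluation and selection of NLP workflows that abstract multiple-myeloma
(MM) clinical data fields from free-text provider notes.

Creating real-world oncology datasets from electronic health records
requires pulling fields like disease status, transplant eligibility, ECOG
score, or first-line-therapy regimens out of unstructured notes.  Manual
chart abstraction is the gold standard but expensive; large language
models promise automation but with unpredictable, field-dependent
accuracy.  `mmcurate` implements the statistical harness for deciding
*which* extraction workflow (small vs large LLM, zero-shot vs
chain-of-thought prompting, or a fine-tuned encoder) is adequate for
*which* field — using the inter-rater reliability of human annotators as
the measure of abstraction difficulty.

## What it computes

- **Field catalog & schema** — 13 MM data fields with closed vocabularies
  and ranges (binary/categorical/integer/date/drug-set values; the literal
  `Unspecified` denotes "not mentioned"), plus a `<10%` presence-based
  field-exclusion rule.
- **Agreement** — Krippendorff's α per field
  (α = 1 − D_o/D_e over the coincidence matrix; nominal, interval, or
  day-interval distance, pairwise deletion of missing values), and
  **IRR-F₁**: the mean macro-F₁ of each annotator against the arbitrated
  consensus (two independent annotators; disagreements resolved by a
  third).
- **Strict-schema post-processing** — raw extractor JSON is parsed,
  repaired (up to three deterministic transforms: plain parse; fence/prose
  stripping; trailing-comma and quote fixes), coerced to field
  vocabularies, date-validated against the study period, and drug brand
  names harmonized to ingredients; anything irreparable becomes
  `Unspecified` with a failure code.
- **Scoring** — macro-F₁ per field; buffer-tolerant weighted F₁ for date
  fields (a predicted date matches within ±7/30/60/90/180 days); Spearman
  ρ for numeric fields.
- **Driver analysis** — sequential (Type-I) ANOVA of per-(workflow, field)
  F₁ on model size, prompt style, IRR-F₁, and field type, with
  η² = SS_term/SS_total effect sizes; paired t-tests, OLS of F₁ on IRR-F₁,
  Tukey HSD on field type; per-workflow F₁-vs-IRR trendlines and their
  crossing points.
- **Workflow selector** — the decision rule: IRR-F₁ ≥ 0.8 ⇒ a small
  LLM/encoder with zero-shot prompting suffices; IRR-F₁ < 0.8 ⇒ a large
  LLM with chain-of-thought, or escalation to manual abstraction /
  fine-tuning when no large model is available.
- **Timelines** — per-patient label events within ±120 days of the index
  (diagnosis) date, with two-step timestamping (validated explicit date,
  else note date) and first-occurrence marking.
- **Synthetic study generator** — produces truth labels, disagreeing
  annotators calibrated to a per-field IRR-F₁ ladder, and corrupted
  extractor payloads whose correctness probability follows a linear model
  in IRR-F₁, model size, and prompting style, so the whole analysis can be
  exercised and validated end to end by parameter recovery.

## Worked example

```python
from mmcurate import ScenarioConfig, run_pipeline

result = run_pipeline(ScenarioConfig(), seed=7)
print(result.irr_averages.round(3).to_string(index=False))
print(result.anova.round(4).to_string(index=False))
print(result.posthoc["table"].round(4).to_string(index=False))
```

prints (trimmed):

```
   split  k_alpha  irr_f1
combined    0.435   0.741
    test    0.390   0.725

        term  df  sum_sq  mean_sq        F  eta_sq  p_value
  model_size   1  0.2231   0.2231 107.7352  0.1873      0.0
prompt_style   1  0.0897   0.0897  43.2888  0.0752      0.0
      irr_f1   1  0.6323   0.6323 305.2953  0.5307      0.0
  field_type   2  0.1594   0.0797  38.4914  0.1338      0.0
   Residuals  42  0.0870   0.0021      NaN  0.0730      NaN

                 driver  estimate  statistic  p_value          test
   model_size_70B_vs_8B    0.1364    11.9972    0.000 paired t-test
prompt_style_CoT_vs_ZSL    0.0864     8.9734    0.000 paired t-test
                 irr_f1    1.1939     7.2119    0.000           OLS
             field_type       NaN     3.3503    0.044 one-way ANOVA
```

Reading this: across 12 retained fields and four workflows
(8B/70B × ZSL/CoT), all four drivers are significant; switching from the
8B to the 70B model is worth about +0.14 F₁ on average — roughly twice the
chain-of-thought benefit (+0.09) — and a one-point increase in a field's
IRR-F₁ translates to about a one-point increase in workflow F₁.  These
recover the coefficients the generator injected (0.13, 0.08, and 1.0).
Per-field recommendations follow from the IRR threshold:

```
         field_id  irr_f1    recommended_model recommended_prompt
     mm_diagnosis   0.865 small-LLM-or-encoder                ZSL
        mm_status   0.656            large-LLM                CoT
mm_diagnosis_date   0.809 small-LLM-or-encoder                ZSL
transplant_status   0.721            large-LLM                CoT
```

The same pipeline is available from the shell:

```bash
mmcurate all --seed 7 --out runs/demo          # full pipeline + manifest
mmcurate simulate --seed 7 --out runs/bundle   # or stage by stage
mmcurate select --irr runs/demo/irr_report.csv --threshold 0.8 --out runs/sel
```

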