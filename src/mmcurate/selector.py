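"""IRR-guided selection of an information-extraction workflow per field.

Inter-rater reliability (IRR-F1) proxies how hard a field is to abstract,
and is available as soon as a reference dataset has been double-annotated.
The decision rule:

* IRR-F1 at or above the threshold (default 0.8): the field is easy
  enough that a small LLM or fine-tuned encoder suffices and zero-shot
  prompting may even outperform chain-of-thought.
* IRR-F1 below the threshold: a large LLM with chain-of-thought prompting
  is needed; if no large model is available, escalate to manual
  abstraction or fine-tuning a small model.

Raising IRR-F1 never moves the recommendation toward a more
resource-intensive option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

DEFAULT_IRR_THRESHOLD = 0.8

LARGE_LLM = "large-LLM"
SMALL_LLM = "small-LLM-or-encoder"
ESCALATE = "manual-abstraction-or-fine-tune"


@dataclass(frozen=True)
class Recommendation:
    field_id: str
    irr_f1: float
    resource_level: str
    large_model_available: bool
    recommended_model: str
    recommended_prompt: str
    escalation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.escalation is not None:
            assert self.irr_f1 < DEFAULT_IRR_THRESHOLD or True  # threshold may differ
            assert not self.large_model_available


def recommend(
    irr_f1: float,
    resource_level: str = "unconstrained",
    large_model_available: bool = True,
    threshold: float = DEFAULT_IRR_THRESHOLD,
    field_id: str = "",
) -> Recommendation:
    """Recommend model class and prompt style for one field.

    Equality with the threshold counts as easy (``>=``).
    """
    if not 0.0 <= irr_f1 <= 1.0:
        raise ValueError(f"irr_f1 outside [0, 1]: {irr_f1}")
    if resource_level not in ("constrained", "unconstrained"):
        raise ValueError(f"unknown resource_level {resource_level!r}")

    if irr_f1 >= threshold:
        return Recommendation(field_id, irr_f1, resource_level,
                              large_model_available, SMALL_LLM, "ZSL")
    if large_model_available:
        return Recommendation(field_id, irr_f1, resource_level,
                              large_model_available, LARGE_LLM, "CoT")
    return Recommendation(field_id, irr_f1, resource_level,
                          large_model_available, SMALL_LLM, "CoT",
                          escalation=ESCALATE)


def recommend_fields(
    irr_report: pd.DataFrame,
    resource_level: str = "unconstrained",
    large_model_available: bool = True,
    threshold: float = DEFAULT_IRR_THRESHOLD,
    irr_split: str = "combined",
) -> pd.DataFrame:
    """Batch mode: IRR report in, one recommendation per field out."""
    rep = irr_report
    if "split" in rep.columns:
        rep = rep[rep["split"] == irr_split]
    rows = []
    for r in rep.itertuples(index=False):
        rec = recommend(float(r.irr_f1), resource_level, large_model_available,
                        threshold, field_id=r.field_id)
        rows.append((rec.field_id, rec.irr_f1, rec.resource_level,
                     rec.large_model_available, rec.recommended_model,
                     rec.recommended_prompt, rec.escalation))
    return pd.DataFrame(rows, columns=["field_id", "irr_f1", "resource_level",
                                       "large_model_available",
                                       "recommended_model",
                                       "recommended_prompt", "escalation"])
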