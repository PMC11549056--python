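"""End-to-end screen analysis: counts -> QC -> scores -> classes -> census."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .classify import (
    ClassThresholds,
    DepletionQC,
    VariantClassification,
    class_census,
    classify,
    empirical_significance,
    essential_depletion_qc,
)
from .errors import BescanError
from .io import NULL_CONTROL_CATEGORIES, CountMatrix, GuideRecord
from .quant import ComparisonSpec, QCRules, ScoreTable, qc_filter, score_comparison


@dataclass
class ScreenAnalysis:
    drug: str
    scores_drug: ScoreTable
    scores_control: ScoreTable
    classifications: list[VariantClassification]
    census: pd.DataFrame
    depletion_qc: DepletionQC | None
    significance: pd.DataFrame | None
    qc: pd.DataFrame


def analyze_screen(
    library: Sequence[GuideRecord],
    counts: CountMatrix,
    drug: str,
    baseline_arm: str = "plasmid",
    rules: QCRules | None = None,
    thresholds: ClassThresholds | None = None,
    gate: Literal["resistance", "both", "none", "auto"] = "auto",
) -> ScreenAnalysis:
    """Run the full analysis for one drug of a screen.

    The drug-treated arm and the untreated control arm are each compared
    against the baseline (plasmid library by default, time zero via
    ``baseline_arm='t0'``). The empirical-null significance gate is applied
    when enough control guides are retained; ``gate='auto'`` silently skips
    it on small synthetic libraries whose scaled control set is below the
    minimum, ``gate='none'`` always skips it.
    """
    baseline = counts.sample_ids(arm=baseline_arm)
    if not baseline:
        raise BescanError(f"no samples in baseline arm {baseline_arm!r}")
    drug_samples = counts.sample_ids(arm="drug", drug=drug)
    ctrl_samples = counts.sample_ids(arm="control")
    if not drug_samples:
        raise BescanError(f"no drug-arm samples for {drug!r}")
    if not ctrl_samples:
        raise BescanError("no control-arm samples")

    qc = qc_filter(counts, library, rules)
    scores_drug = score_comparison(
        counts, library, ComparisonSpec(drug_samples, baseline, f"{drug}_vs_{baseline_arm}"), qc=qc
    )
    scores_control = score_comparison(
        counts, library, ComparisonSpec(ctrl_samples, baseline, f"control_vs_{baseline_arm}"), qc=qc
    )

    significance = None
    if gate != "none":
        cat = {g.guide_id: g.category for g in library}
        n_ctrl = sum(1 for g in scores_drug.retained if cat.get(g) in NULL_CONTROL_CATEGORIES)
        if n_ctrl >= 30:
            significance = empirical_significance(scores_drug, library)
        elif gate != "auto":
            significance = empirical_significance(scores_drug, library)  # raises with count

    classifications = classify(
        scores_drug,
        scores_control,
        thresholds,
        drug=drug,
        significance=significance,
        gate="both" if gate == "auto" else ("both" if gate == "none" else gate),
    )
    census = class_census(classifications, library)
    try:
        depletion = essential_depletion_qc(scores_control, library)
    except BescanError:
        depletion = None
    return ScreenAnalysis(
        drug=drug,
        scores_drug=scores_drug,
        scores_control=scores_control,
        classifications=classifications,
        census=census,
        depletion_qc=depletion,
        significance=significance,
        qc=qc,
    )
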