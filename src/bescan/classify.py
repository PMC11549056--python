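"""Four-class variant-phenotype calling from drug-arm and control-arm z-scores.

A guide is a resistance hit when its drug-arm z exceeds 2 with every
replicate above 1 (all inequalities strict). Hits split into:

* drug_addiction — also depleted without drug (control z < -2, reps < -1):
  fitness cost from oncogenic over-signaling, enriched only under drug;
* driver — also enriched without drug (control z > 2, reps > 1):
  constitutive proliferative advantage;
* canonical_resistance — a hit fulfilling neither of the above (typically
  disrupted drug binding).

Non-hits depleted only under drug (drug z < -2, reps < -1, control z > -2,
reps > -1) are sensitizing; everything else is control.

An empirical control-gRNA null (nontargeting + intergenic + nonessential-
splice guides) provides one-sided significance with Benjamini-Hochberg FDR
as a secondary gate on hit calls, at cutoffs P < 0.05 and FDR < 0.1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BescanError, FormatError
from .io import NULL_CONTROL_CATEGORIES, GuideRecord
from .quant import ScoreTable

VARIANT_CLASSES = ("drug_addiction", "canonical_resistance", "driver", "sensitizing", "control")
HIT_CLASSES = ("drug_addiction", "canonical_resistance", "driver", "sensitizing")


@dataclass
class ClassThresholds:
    z_hit: float = 2.0
    z_rep: float = 1.0
    z_dep: float = -2.0
    z_dep_rep: float = -1.0

    def __post_init__(self):
        if not (self.z_hit > self.z_rep > 0):
            raise FormatError("require z_hit > z_rep > 0")
        if not (self.z_dep < self.z_dep_rep < 0):
            raise FormatError("require z_dep < z_dep_rep < 0")


@dataclass
class VariantClassification:
    guide_id: str
    drug: str
    variant_class: str
    is_resistance_hit: bool
    criteria: dict = field(default_factory=dict)
    z_drug: float = float("nan")
    z_control: float = float("nan")
    p_empirical: float = float("nan")
    fdr: float = float("nan")


def classify_guide(
    z_d: float, reps_d: Sequence[float], z_c: float, reps_c: Sequence[float], th: ClassThresholds
) -> tuple[str, bool, dict]:
    """Class, hit flag and criterion booleans for one guide's z-scores.

    All threshold inequalities are strict; classes are mutually exclusive by
    construction (drug addiction and driver have disjoint control-arm
    conditions, canonical resistance is the residual hit class).
    """
    crit = {
        "drug_enriched": z_d > th.z_hit and all(r > th.z_rep for r in reps_d),
        "drug_depleted": z_d < th.z_dep and all(r < th.z_dep_rep for r in reps_d),
        "control_enriched": z_c > th.z_hit and all(r > th.z_rep for r in reps_c),
        "control_depleted": z_c < th.z_dep and all(r < th.z_dep_rep for r in reps_c),
        "control_not_depleted": z_c > th.z_dep and all(r > th.z_dep_rep for r in reps_c),
    }
    hit = crit["drug_enriched"]
    if hit and crit["control_depleted"]:
        cls = "drug_addiction"
    elif hit and crit["control_enriched"]:
        cls = "driver"
    elif hit:
        cls = "canonical_resistance"
    elif crit["drug_depleted"] and crit["control_not_depleted"]:
        cls = "sensitizing"
    else:
        cls = "control"
    return cls, hit, crit


def classify(
    scores_drug: ScoreTable,
    scores_control: ScoreTable,
    th: ClassThresholds | None = None,
    drug: str = "",
    significance: pd.DataFrame | None = None,
    gate: Literal["resistance", "both", "none"] = "both",
    p_cut: float = 0.05,
    fdr_cut: float = 0.1,
) -> list[VariantClassification]:
    """Assign one variant class per QC-retained guide.

    When ``significance`` (the output of :func:`empirical_significance`) is
    supplied, hit calls additionally require the empirical-null gate in the
    matching direction; ``gate`` selects whether it applies to resistance
    hits only, to sensitizing hits too, or not at all.
    """
    th = th or ClassThresholds()
    retained_d = set(scores_drug.retained)
    retained_c = set(scores_control.retained)
    if retained_d != retained_c:
        diff = retained_d ^ retained_c
        raise BescanError(
            f"drug and control score tables cover different retained guides "
            f"({len(diff)} mismatched, e.g. {sorted(diff)[:5]})"
        )
    out = []
    for g in scores_drug.retained:
        z_d, reps_d = scores_drug.z(g), scores_drug.rep_z(g)
        z_c, reps_c = scores_control.z(g), scores_control.rep_z(g)
        cls, hit, crit = classify_guide(z_d, reps_d, z_c, reps_c, th)
        p = fdr = float("nan")
        if significance is not None and g in significance.index:
            direction = "enrich" if z_d >= 0 else "deplete"
            p = float(significance.at[g, f"p_{direction}"])
            fdr = float(significance.at[g, f"fdr_{direction}"])
            gated = (
                (gate == "both" and cls in HIT_CLASSES)
                or (gate == "resistance" and hit)
            )
            if gated and not (p < p_cut and fdr < fdr_cut):
                crit["significance_gate"] = False
                cls, hit = "control", False
            elif gated:
                crit["significance_gate"] = True
        out.append(
            VariantClassification(
                guide_id=g,
                drug=drug,
                variant_class=cls,
                is_resistance_hit=hit,
                criteria=crit,
                z_drug=z_d,
                z_control=z_c,
                p_empirical=p,
                fdr=fdr,
            )
        )
    return out


def empirical_significance(
    scores: ScoreTable,
    library: Sequence[GuideRecord],
    min_controls: int = 30,
) -> pd.DataFrame:
    """One-sided empirical p-values against the control-guide null.

    p = (r + 1) / (n_ctrl + 1) with r = number of control z at least as
    extreme in the tested direction; BH FDR across targeting guides per
    direction.
    """
    cat = {g.guide_id: g.category for g in library}
    retained = scores.retained
    ctrl_z = np.array(
        [scores.z(g) for g in retained if cat.get(g) in NULL_CONTROL_CATEGORIES]
    )
    if len(ctrl_z) < min_controls:
        raise BescanError(
            f"need >= {min_controls} retained control guides for the empirical null, "
            f"got {len(ctrl_z)}"
        )
    targeting = [g for g in retained if cat.get(g) == "targeting"]
    z = np.array([scores.z(g) for g in targeting])
    n = len(ctrl_z)
    sorted_ctrl = np.sort(ctrl_z)
    # r_enrich: controls >= z ; r_deplete: controls <= z
    r_enrich = n - np.searchsorted(sorted_ctrl, z, side="left")
    r_deplete = np.searchsorted(sorted_ctrl, z, side="right")
    p_enrich = (r_enrich + 1) / (n + 1)
    p_deplete = (r_deplete + 1) / (n + 1)
    return pd.DataFrame(
        {
            "p_enrich": p_enrich,
            "fdr_enrich": stats.false_discovery_control(p_enrich, method="bh"),
            "p_deplete": p_deplete,
            "fdr_deplete": stats.false_discovery_control(p_deplete, method="bh"),
        },
        index=pd.Index(targeting, name="guide_id"),
    )


@dataclass
class DepletionQC:
    t: float
    p: float
    mean_nt: float
    mean_essential: float
    passed: bool


def essential_depletion_qc(
    scores_control: ScoreTable,
    library: Sequence[GuideRecord],
    alpha: float = 0.05,
) -> DepletionQC:
    """Editing-activity QC: essential-splice guides must deplete vs nontargeting.

    Equal-variance two-sided t-test of retained z-scores, with a directional
    verdict (essential mean below NT mean) at level ``alpha``.
    """
    cat = {g.guide_id: g.category for g in library}
    nt = [scores_control.z(g) for g in scores_control.retained if cat.get(g) == "nontargeting"]
    ess = [
        scores_control.z(g) for g in scores_control.retained if cat.get(g) == "essential_splice"
    ]
    if not nt or not ess:
        raise BescanError("both nontargeting and essential_splice guides are required")
    t, p = stats.ttest_ind(nt, ess, equal_var=True)
    mean_nt, mean_ess = float(np.mean(nt)), float(np.mean(ess))
    return DepletionQC(
        t=float(t),
        p=float(p),
        mean_nt=mean_nt,
        mean_essential=mean_ess,
        passed=bool(p < alpha and mean_ess < mean_nt),
    )


def class_census(
    classifications: Sequence[VariantClassification],
    library: Sequence[GuideRecord] | None = None,
) -> pd.DataFrame:
    """Per-drug counts of each class, total hits, and control-guide contamination.

    Contamination counts hit-scoring guides whose library category is not
    'targeting' — the screen's signal-to-noise diagnostic.
    """
    cat = {g.guide_id: g.category for g in library} if library else {}
    rows = []
    for drug in sorted({c.drug for c in classifications}):
        sub = [c for c in classifications if c.drug == drug]
        row = {"drug": drug}
        for cls in VARIANT_CLASSES:
            row[cls] = sum(c.variant_class == cls for c in sub)
        hits = [c for c in sub if c.variant_class in HIT_CLASSES]
        row["total_hits"] = len(hits)
        row["control_contamination"] = sum(
            cat.get(c.guide_id, "targeting") != "targeting" for c in hits
        )
        rows.append(row)
    return pd.DataFrame(rows)


def classification_frame(classifications: Sequence[VariantClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "guide_id": c.guide_id,
                "drug": c.drug,
                "variant_class": c.variant_class,
                "is_resistance_hit": c.is_resistance_hit,
                "z_drug": c.z_drug,
                "z_control": c.z_control,
                "p_empirical": c.p_empirical,
                "fdr": c.fdr,
            }
            for c in classifications
        ]
    )
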