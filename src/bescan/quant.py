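"""Guide quantification: RPM normalization, log2 fold changes, z-scores, QC.

The scoring follows the standard pooled-screen recipe: reads per million
with a +1 pseudocount applied after scaling (``count / colsum * 1e6 + 1``),
replicate RPMs averaged before the ratio, ``l2fc = log2(rpm_cond / rpm_base)``,
and ``z = (l2fc - mean(l2fc)) / sd(l2fc)`` standardized over all QC-retained
guides of the comparison (targeting and controls alike — the controls anchor
the null). The standard deviation is the sample sd (ddof=1).

QC exclusion rules:
  * multi_mapping — more than two perfect matches in the genome;
  * low_count — fewer than 100 raw reads in the plasmid or any time-zero sample;
  * replicate_discordant — >= 10-fold raw-count difference between replicates
    of an arm (off by default; enable for cell-line profiles that need it).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BescanError, DegenerateDistributionError, FormatError
from .io import CountMatrix, GuideRecord

QC_FLAGS = ("multi_mapping", "low_count", "replicate_discordant")


@dataclass
class QCRules:
    max_perfect_matches: int = 2
    min_count: int = 100
    max_replicate_ratio: float = 10.0
    replicate_rule_enabled: bool = False  # on for the MHH-ES-1-style profile


@dataclass
class ComparisonSpec:
    condition_samples: list[str]
    baseline_samples: list[str]
    label: str = ""

    def __post_init__(self):
        if not self.condition_samples or not self.baseline_samples:
            raise FormatError(f"comparison {self.label!r}: empty sample set")
        if set(self.condition_samples) & set(self.baseline_samples):
            raise FormatError(f"comparison {self.label!r}: condition and baseline overlap")


@dataclass
class ScoreTable:
    """Per-guide scores for one comparison.

    ``table`` is indexed by guide_id with columns rpm_condition, rpm_baseline,
    l2fc, z, l2fc_rep_<i>, z_rep_<i>, the QC flag booleans and ``excluded``.
    Flagged guides carry NaN z.
    """

    table: pd.DataFrame
    label: str
    mean_l2fc: float
    sd_l2fc: float
    rep_labels: list[str] = field(default_factory=list)

    @property
    def retained(self) -> pd.Index:
        return self.table.index[~self.table["excluded"]]

    def z(self, guide_id: str) -> float:
        return float(self.table.at[guide_id, "z"])

    def rep_z(self, guide_id: str) -> list[float]:
        return [float(self.table.at[guide_id, f"z_rep_{r}"]) for r in self.rep_labels]


def rpm_normalize(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Reads per million with +1 pseudocount applied after scaling."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise BescanError(f"zero total read count in sample(s) {zero}")
    return df / totals * 1e6 + 1


def log2_fold_change(
    rpm: pd.DataFrame, spec: ComparisonSpec
) -> tuple[pd.Series, pd.DataFrame]:
    """Average-first L2FC plus per-replicate values.

    Replicate RPMs are averaged within condition and baseline before the
    ratio. Per-replicate values pair the i-th condition sample with the i-th
    baseline sample when the two arms have the same replicate structure,
    otherwise each condition replicate is compared with the baseline average.
    """
    missing = [s for s in spec.condition_samples + spec.baseline_samples if s not in rpm.columns]
    if missing:
        raise FormatError(f"comparison {spec.label!r} references missing sample(s) {missing}")
    cond = rpm[spec.condition_samples]
    base = rpm[spec.baseline_samples]
    l2fc = np.log2(cond.mean(axis=1) / base.mean(axis=1))
    paired = len(spec.condition_samples) == len(spec.baseline_samples) > 1
    reps = {}
    for i, cs in enumerate(spec.condition_samples):
        denom = base[spec.baseline_samples[i]] if paired else base.mean(axis=1)
        reps[f"l2fc_rep_{i + 1}"] = np.log2(cond[cs] / denom)
    return l2fc, pd.DataFrame(reps, index=rpm.index)


def zscore(l2fc: pd.Series, retained: Sequence[str] | pd.Index) -> tuple[pd.Series, float, float]:
    """Standardize l2fc over the retained guides; returns (z, mean, sd)."""
    vals = l2fc.loc[list(retained)]
    if len(vals) < 3:
        raise BescanError(f"need >= 3 retained guides to standardize, got {len(vals)}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise DegenerateDistributionError("l2fc distribution has zero spread")
    return (vals - mean) / sd, mean, sd


def qc_filter(
    counts: CountMatrix, library: Sequence[GuideRecord], rules: QCRules | None = None
) -> pd.DataFrame:
    """Per-guide QC flags (boolean columns multi_mapping/low_count/replicate_discordant
    plus ``excluded``). Flag-only: order-independent and idempotent."""
    rules = rules or QCRules()
    pm = pd.Series({g.guide_id: g.perfect_match_count for g in library})
    df = pd.DataFrame(index=counts.counts.index)
    df["multi_mapping"] = (
        pm.reindex(df.index).fillna(0) > rules.max_perfect_matches
    )

    early = counts.sample_ids(arm="plasmid") + counts.sample_ids(arm="t0")
    if early:
        df["low_count"] = (counts.counts[early] < rules.min_count).any(axis=1)
    else:
        df["low_count"] = False

    discordant = pd.Series(False, index=df.index)
    if rules.replicate_rule_enabled:
        groups: dict[tuple, list[str]] = {}
        for s in counts.samples:
            groups.setdefault((s.arm, s.drug), []).append(s.sample_id)
        for cols in groups.values():
            if len(cols) < 2:
                continue
            sub = counts.counts[cols] + 1  # +1 guards zero denominators
            ratio = sub.max(axis=1) / sub.min(axis=1)
            discordant |= ratio >= rules.max_replicate_ratio
    df["replicate_discordant"] = discordant
    df["excluded"] = df[list(QC_FLAGS)].any(axis=1)
    return df


def score_comparison(
    counts: CountMatrix,
    library: Sequence[GuideRecord],
    spec: ComparisonSpec,
    rules: QCRules | None = None,
    qc: pd.DataFrame | None = None,
) -> ScoreTable:
    """Full counts -> RPM -> L2FC -> z pipeline for one comparison."""
    if qc is None:
        qc = qc_filter(counts, library, rules)
    rpm = rpm_normalize(counts)
    l2fc, reps = log2_fold_change(rpm, spec)
    retained = qc.index[~qc["excluded"]]
    z, mean, sd = zscore(l2fc, retained)

    out = pd.DataFrame(index=counts.counts.index)
    out["rpm_condition"] = rpm[spec.condition_samples].mean(axis=1)
    out["rpm_baseline"] = rpm[spec.baseline_samples].mean(axis=1)
    out["l2fc"] = l2fc
    out["z"] = z.reindex(out.index)  # NaN for excluded guides
    rep_labels = []
    for col in reps.columns:
        out[col] = reps[col]
        rep_no = col.split("_")[-1]
        rep_labels.append(rep_no)
        zr, _, _ = zscore(reps[col], retained)
        out[f"z_rep_{rep_no}"] = zr.reindex(out.index)
    out = out.join(qc[list(QC_FLAGS) + ["excluded"]])
    return ScoreTable(table=out, label=spec.label, mean_l2fc=mean, sd_l2fc=sd, rep_labels=rep_labels)


def score_table_to_frame(st: ScoreTable) -> pd.DataFrame:
    df = st.table.reset_index(names="guide_id")
    df.insert(1, "comparison", st.label)
    return df
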