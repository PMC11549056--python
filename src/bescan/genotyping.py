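"""Amplicon-sequencing verification of installed edits.

Variants from edited-sample amplicons pass when read depth exceeds 1,000
and variant allele frequency exceeds 0.1 (both strict). Variants that also
pass those filters in the matched unedited sample are background (pre-
existing in the cell line) and are removed outright. Passing SNVs on one
amplicon are phased as co-occurring (single-clone assumption) and
translated jointly into a protein genotype such as ``L390S/S391P``; a guide
is verified when at least one passing variant is nonsynonymous.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .edits import NONSYNONYMOUS_CLASSES, PredictedEdit, TranscriptModel, classify_changes
from .errors import FormatError

_DNA = frozenset("ACGT")


@dataclass
class AmpliconVariant:
    """One SNV call from amplicon sequencing (1-based locus coordinate)."""

    amplicon_id: str
    pos: int
    ref: str
    alt: str
    depth: int
    vaf: float
    sample_kind: str  # edited | unedited
    guide_id: str

    def __post_init__(self):
        if not 0 <= self.vaf <= 1:
            raise FormatError(f"{self.amplicon_id}:{self.pos}: VAF must be in [0,1]")
        if self.depth < 0:
            raise FormatError(f"{self.amplicon_id}:{self.pos}: negative depth")
        if self.ref == self.alt:
            raise FormatError(f"{self.amplicon_id}:{self.pos}: ref equals alt")
        if self.sample_kind not in ("edited", "unedited"):
            raise FormatError(f"unknown sample_kind {self.sample_kind!r}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt) and {self.ref, self.alt} <= _DNA


@dataclass
class VariantFilter:
    min_depth: int = 1000  # strict: depth must exceed this
    min_vaf: float = 0.1   # strict: VAF must exceed this


@dataclass
class GuideGenotype:
    guide_id: str
    passing_variants: list[AmpliconVariant]
    protein_genotype: str
    consequence_class: str
    in_window_median_vaf: float
    verdict: str  # verified_nonsynonymous | not_verified
    per_variant: list[tuple[tuple[int, str, str], str, str]] = field(default_factory=list)
    concordant_with_prediction: bool | None = None


def filter_variants(
    variants: Sequence[AmpliconVariant], rules: VariantFilter | None = None
) -> list[AmpliconVariant]:
    """Keep variants with depth > min_depth and VAF > min_vaf (strict). Idempotent."""
    rules = rules or VariantFilter()
    return [v for v in variants if v.depth > rules.min_depth and v.vaf > rules.min_vaf]


def subtract_background(
    edited: Sequence[AmpliconVariant],
    unedited: Sequence[AmpliconVariant],
    rules: VariantFilter | None = None,
) -> list[AmpliconVariant]:
    """Drop edited variants whose (pos, ref, alt) also passes filters in unedited DNA."""
    background = {v.key for v in filter_variants(unedited, rules)}
    return [v for v in edited if v.key not in background]


def protein_genotype(
    passing: Sequence[AmpliconVariant],
    model: TranscriptModel,
    predicted: PredictedEdit | None = None,
) -> GuideGenotype:
    """Translate co-occurring passing SNVs into a joint protein genotype.

    Indels are annotated and skipped with a warning. Alongside the joint
    (phased) genotype, each variant's solo consequence is reported so the
    per-variant interpretation is never lost.
    """
    snvs = []
    for v in passing:
        if v.is_snv:
            snvs.append(v)
        else:
            warnings.warn(
                f"skipping non-SNV variant {v.ref}>{v.alt} at {v.pos} on {v.amplicon_id}"
            )
    guide_id = snvs[0].guide_id if snvs else (passing[0].guide_id if passing else "")
    changes = sorted((v.pos - 1, v.ref, v.alt) for v in snvs)
    joint_str, joint_cls = classify_changes(model, changes) if changes else ("", "none")
    per_variant = []
    any_nonsyn = False
    for v in snvs:
        s, c = classify_changes(model, [(v.pos - 1, v.ref, v.alt)])
        per_variant.append((v.key, s, c))
        if c in NONSYNONYMOUS_CLASSES:
            any_nonsyn = True

    if predicted is not None and predicted.window_positions:
        window = {p + 1 for p in predicted.window_positions}  # to 1-based
        win_vafs = [v.vaf for v in snvs if v.pos in window]
    else:
        win_vafs = [v.vaf for v in snvs]
    median_vaf = float(np.median(win_vafs)) if win_vafs else float("nan")

    concordant = None
    if predicted is not None:
        concordant = (
            joint_str == predicted.protein_consequence
            and joint_cls == predicted.consequence_class
        )
    return GuideGenotype(
        guide_id=guide_id,
        passing_variants=list(snvs),
        protein_genotype=joint_str,
        consequence_class=joint_cls,
        in_window_median_vaf=median_vaf,
        verdict="verified_nonsynonymous" if any_nonsyn else "not_verified",
        per_variant=per_variant,
        concordant_with_prediction=concordant,
    )


def genotype_guides(
    edited: Sequence[AmpliconVariant],
    unedited: Sequence[AmpliconVariant],
    models: dict[str, TranscriptModel],
    predicted: dict[str, PredictedEdit] | None = None,
    rules: VariantFilter | None = None,
) -> list[GuideGenotype]:
    """Per-guide verification pipeline: filter, subtract background, translate."""
    predicted = predicted or {}
    by_guide: dict[str, list[AmpliconVariant]] = {}
    for v in edited:
        by_guide.setdefault(v.guide_id, []).append(v)
    un_by_guide: dict[str, list[AmpliconVariant]] = {}
    for v in unedited:
        un_by_guide.setdefault(v.guide_id, []).append(v)
    out = []
    for guide_id in sorted(by_guide):
        passing = filter_variants(by_guide[guide_id], rules)
        passing = subtract_background(passing, un_by_guide.get(guide_id, []), rules)
        gg = protein_genotype(passing, models[guide_id], predicted.get(guide_id))
        gg.guide_id = guide_id
        out.append(gg)
    return out


def verification_summary(genotypes: Sequence[GuideGenotype]) -> dict:
    """Editing-efficiency summary: verified count and median in-window VAF."""
    verified = [g for g in genotypes if g.verdict == "verified_nonsynonymous"]
    vafs = [g.in_window_median_vaf for g in verified if np.isfinite(g.in_window_median_vaf)]
    return {
        "n_guides": len(genotypes),
        "n_verified": len(verified),
        "median_in_window_vaf": float(np.median(vafs)) if vafs else float("nan"),
    }


# -- on-disk formats ---------------------------------------------------------

_VARIANT_COLUMNS = ["amplicon_id", "pos", "ref", "alt", "depth", "vaf", "sample_kind", "guide_id"]


def read_variant_table(path: str | Path) -> list[AmpliconVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    for col in _VARIANT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"variant table missing required column {col!r}")
    return [
        AmpliconVariant(
            amplicon_id=str(r.amplicon_id),
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            depth=int(r.depth),
            vaf=float(r.vaf),
            sample_kind=str(r.sample_kind),
            guide_id=str(r.guide_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_variant_table(variants: Sequence[AmpliconVariant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "amplicon_id": v.amplicon_id,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "depth": v.depth,
                "vaf": v.vaf,
                "sample_kind": v.sample_kind,
                "guide_id": v.guide_id,
            }
            for v in variants
        ],
        columns=_VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_variant_vcf(path: str | Path, sample_kind: str = "edited") -> list[AmpliconVariant]:
    """Read a VCF v4.2 subset: CHROM as amplicon id, INFO DP and VAF, ID as guide id.

    Only SNV records are kept; indels are skipped with a warning.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    out = []
    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else ""
        if len(rec.REF) != 1 or len(alt) != 1:
            warnings.warn(f"skipping non-SNV VCF record at {rec.CHROM}:{rec.POS}")
            continue
        out.append(
            AmpliconVariant(
                amplicon_id=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                depth=int(rec.INFO.get("DP", 0)),
                vaf=float(rec.INFO.get("VAF", 0.0)),
                sample_kind=sample_kind,
                guide_id=str(rec.ID or rec.CHROM),
            )
        )
    return out


def write_variant_vcf(variants: Sequence[AmpliconVariant], path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        lines.append(
            f"{v.amplicon_id}\t{v.pos}\t{v.guide_id}\t{v.ref}\t{v.alt}\t.\t.\t"
            f"DP={v.depth};VAF={v.vaf:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def genotype_frame(genotypes: Sequence[GuideGenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "guide_id": g.guide_id,
                "protein_genotype": g.protein_genotype,
                "consequence_class": g.consequence_class,
                "n_passing": len(g.passing_variants),
                "in_window_median_vaf": g.in_window_median_vaf,
                "verdict": g.verdict,
                "concordant_with_prediction": g.concordant_with_prediction,
            }
            for g in genotypes
        ]
    )
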