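"""Cross-drug variant function map and benchmarking.

Verified protein variants (from amplicon genotyping) are crossed with every
screened drug to build a variant x drug matrix of phenotype classes. From
the matrix, alternative therapies are suggested (drugs whose cell is
control or sensitizing, sensitizing first; drug-addiction rows carry a
drug-holiday note) and the map is benchmarked against a curated list of
known drug-response variants at amino-acid-position granularity.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .classify import HIT_CLASSES, VariantClassification
from .errors import BescanError
from .genotyping import GuideGenotype
from .io import GuideRecord

UNTESTED = "untested"

_POSITION_RE = re.compile(r"[A-Z*](\d+)[A-Z*]")


def consequence_positions(consequence: str) -> list[int]:
    """Amino-acid positions named in a consequence string like 'L390S/S391P'."""
    return [int(m) for m in _POSITION_RE.findall(consequence or "")]


@dataclass
class CuratedVariant:
    gene: str
    protein_position: int
    consequence: str
    drug: str
    reported_effect: str  # resistance | sensitivity

    def __post_init__(self):
        if self.protein_position < 1:
            raise BescanError("protein_position must be >= 1")
        if self.reported_effect not in ("resistance", "sensitivity"):
            raise BescanError(f"unknown reported_effect {self.reported_effect!r}")


@dataclass
class VariantDrugMatrix:
    """Rows: verified variants keyed 'GENE consequence'; columns: drugs; cells: class."""

    table: pd.DataFrame
    variant_guides: dict[str, list[str]] = field(default_factory=dict)
    variant_gene: dict[str, str] = field(default_factory=dict)
    conflicts: list[dict] = field(default_factory=list)


def build_map(
    classifications_by_drug: dict[str, Sequence[VariantClassification]],
    genotypes: Sequence[GuideGenotype],
    library: Sequence[GuideRecord],
) -> VariantDrugMatrix:
    """Assemble the variant x drug class matrix from verified genotypes.

    Multiple guides installing the same protein variant are merged per drug
    by majority class, ties broken by the strongest |z_drug|; every
    disagreement is recorded in ``conflicts`` rather than silently dropped.
    """
    gene_of = {g.guide_id: (g.gene or "") for g in library}
    verified = [g for g in genotypes if g.verdict == "verified_nonsynonymous"]
    variant_guides: dict[str, list[str]] = {}
    variant_gene: dict[str, str] = {}
    for g in verified:
        gene = gene_of.get(g.guide_id, "")
        key = f"{gene} {g.protein_genotype}".strip()
        variant_guides.setdefault(key, []).append(g.guide_id)
        variant_gene[key] = gene
    drugs = sorted(classifications_by_drug)
    class_of: dict[str, dict[str, VariantClassification]] = {
        d: {c.guide_id: c for c in cls} for d, cls in classifications_by_drug.items()
    }
    rows, conflicts = {}, []
    for key, guides in variant_guides.items():
        row = {}
        for d in drugs:
            found = [class_of[d][g] for g in guides if g in class_of[d]]
            if not found:
                row[d] = UNTESTED
                continue
            votes = pd.Series([c.variant_class for c in found]).value_counts()
            if len(votes) > 1:
                top = votes[votes == votes.max()].index
                if len(top) > 1:
                    winner = max(
                        (c for c in found if c.variant_class in set(top)),
                        key=lambda c: abs(c.z_drug),
                    ).variant_class
                else:
                    winner = votes.idxmax()
                conflicts.append(
                    {
                        "variant": key,
                        "drug": d,
                        "classes": {c.guide_id: c.variant_class for c in found},
                        "resolved": winner,
                    }
                )
                row[d] = winner
            else:
                row[d] = votes.index[0]
        if all(v == UNTESTED for v in row.values()):
            warnings.warn(f"variant {key!r} was not screened against any drug")
        rows[key] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=drugs)
    table.index.name = "variant"
    return VariantDrugMatrix(
        table=table, variant_guides=variant_guides, variant_gene=variant_gene, conflicts=conflicts
    )


@dataclass
class AlternativeSuggestion:
    variant: str
    drugs: list[str]
    drug_holiday_candidate: bool


def suggest_alternatives(matrix: VariantDrugMatrix, variant: str) -> AlternativeSuggestion:
    """Drugs the variant remains sensitive to: sensitizing cells first, then control."""
    if variant not in matrix.table.index:
        raise BescanError(f"unknown variant {variant!r}")
    row = matrix.table.loc[variant]
    sensitizing = [d for d in row.index if row[d] == "sensitizing"]
    control = [d for d in row.index if row[d] == "control"]
    holiday = bool((row == "drug_addiction").any())
    return AlternativeSuggestion(
        variant=variant, drugs=sensitizing + control, drug_holiday_candidate=holiday
    )


@dataclass
class ConcordanceResult:
    fraction: float  # matched / curated entries reachable by the screen
    fraction_all: float  # matched / all curated entries
    n_matched: int
    n_reachable: int
    n_curated: int
    per_variant: pd.DataFrame = field(default_factory=pd.DataFrame)
    novel: list[tuple[str, int, str]] = field(default_factory=list)


def concordance(
    matrix: VariantDrugMatrix,
    curated: Sequence[CuratedVariant],
    exact_substitution: bool = False,
) -> ConcordanceResult:
    """Benchmark the screen map against curated known drug-response variants.

    Matching is at (gene, amino-acid position, drug) granularity by default;
    ``exact_substitution`` additionally requires the consequence string to
    contain the curated substitution. The headline fraction uses curated
    entries within the screen's tested space (gene screened at that position,
    drug in the panel); the all-entries fraction is reported alongside.
    Screen variant-drug effects with no curated counterpart are listed as novel.
    """
    if not curated:
        raise BescanError("curated list is empty")
    # screen effects: (gene, position, drug) -> set of classes
    screen_effects: dict[tuple[str, int, str], set[str]] = {}
    screened_positions: dict[str, set[int]] = {}
    for variant in matrix.table.index:
        gene = matrix.variant_gene.get(variant, "")
        consequence = variant[len(gene):].strip() if gene else variant
        positions = consequence_positions(consequence)
        screened_positions.setdefault(gene, set()).update(positions)
        for drug in matrix.table.columns:
            cls = matrix.table.at[variant, drug]
            if cls == UNTESTED:
                continue
            for pos in positions:
                entry = screen_effects.setdefault((gene, pos, drug), set())
                if exact_substitution:
                    entry.add(f"{cls}|{consequence}")
                else:
                    entry.add(cls)

    rows, matched, reachable = [], 0, 0
    for cv in curated:
        in_space = (
            cv.protein_position in screened_positions.get(cv.gene, set())
            and cv.drug in matrix.table.columns
        )
        classes = screen_effects.get((cv.gene, cv.protein_position, cv.drug), set())
        if exact_substitution:
            classes = {
                c.split("|")[0] for c in classes if cv.consequence in c.split("|", 1)[1]
            }
        if cv.reported_effect == "resistance":
            hit = bool(classes & {"canonical_resistance", "drug_addiction", "driver"})
        else:
            hit = "sensitizing" in classes
        if in_space:
            reachable += 1
            matched += hit
        rows.append(
            {
                "gene": cv.gene,
                "position": cv.protein_position,
                "drug": cv.drug,
                "reported_effect": cv.reported_effect,
                "in_tested_space": in_space,
                "concordant": hit if in_space else pd.NA,
            }
        )
    curated_keys = {(cv.gene, cv.protein_position, cv.drug) for cv in curated}
    novel = sorted(
        (g, p, d)
        for (g, p, d), classes in screen_effects.items()
        if (g, p, d) not in curated_keys and classes & set(HIT_CLASSES)
    )
    return ConcordanceResult(
        fraction=matched / reachable if reachable else float("nan"),
        fraction_all=matched / len(curated),
        n_matched=matched,
        n_reachable=reachable,
        n_curated=len(curated),
        per_variant=pd.DataFrame(rows),
        novel=novel,
    )


def read_curated(path) -> list[CuratedVariant]:
    df = pd.read_csv(path, sep="\t")
    return [
        CuratedVariant(
            gene=str(r.gene),
            protein_position=int(r.protein_position),
            consequence=str(r.consequence),
            drug=str(r.drug),
            reported_effect=str(r.reported_effect),
        )
        for r in df.itertuples(index=False)
    ]
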