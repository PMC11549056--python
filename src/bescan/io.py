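"""Readers and writers for screen tables.

All on-disk tables are tab-separated UTF-8 with mandatory headers. Sample
metadata lives in a sidecar table keyed by ``sample_id`` rather than being
encoded in count-matrix column names, because screen samples carry several
attributes at once (arm, replicate, editor, cell line, drug).

Unknown columns in library and metadata tables are preserved on round trip.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

GUIDE_CATEGORIES = frozenset(
    {"targeting", "nontargeting", "intergenic", "essential_splice", "nonessential_splice"}
)
CONTROL_CATEGORIES = frozenset(
    {"nontargeting", "intergenic", "essential_splice", "nonessential_splice"}
)
#: control categories used to build the empirical null ("nonessential" controls)
NULL_CONTROL_CATEGORIES = frozenset({"nontargeting", "intergenic", "nonessential_splice"})

ARMS = frozenset({"plasmid", "t0", "control", "drug"})
EDITORS = frozenset({"CBE", "ABE"})

_DNA = frozenset("ACGT")


@dataclass
class GuideRecord:
    """One library gRNA with its annotation and control category."""

    guide_id: str
    protospacer: str
    pam: str
    gene: str | None
    category: str
    editor: str
    predicted_consequence: str | None = None
    perfect_match_count: int = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.protospacer) != 20 or not set(self.protospacer) <= _DNA:
            raise FormatError(
                f"guide {self.guide_id}: protospacer must be a 20-nt ACGT string, "
                f"got {self.protospacer!r}"
            )
        if len(self.pam) != 3 or not set(self.pam) <= _DNA:
            raise FormatError(f"guide {self.guide_id}: PAM must be 3 nt, got {self.pam!r}")
        if self.category not in GUIDE_CATEGORIES:
            raise FormatError(
                f"guide {self.guide_id}: unknown category {self.category!r} "
                f"(expected one of {sorted(GUIDE_CATEGORIES)})"
            )
        if self.editor not in EDITORS:
            raise FormatError(f"guide {self.guide_id}: unknown editor {self.editor!r}")
        if self.category in {"nontargeting", "intergenic"} and self.gene:
            raise FormatError(
                f"guide {self.guide_id}: {self.category} controls must not carry a gene"
            )
        if self.perfect_match_count < 0:
            raise FormatError(f"guide {self.guide_id}: perfect_match_count must be >= 0")


@dataclass
class SampleMeta:
    """Screen sample: one sequenced arm/replicate."""

    sample_id: str
    arm: str
    replicate: int
    cell_line: str
    editor: str
    drug: str | None = None

    def __post_init__(self):
        if self.arm not in ARMS:
            raise FormatError(f"sample {self.sample_id}: unknown arm {self.arm!r}")
        if (self.arm == "drug") != (self.drug is not None):
            raise FormatError(
                f"sample {self.sample_id}: drug must be set iff arm is 'drug' "
                f"(arm={self.arm!r}, drug={self.drug!r})"
            )
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Integer gRNA x sample read counts plus sample metadata."""

    counts: pd.DataFrame  # index guide_id, columns sample_id
    samples: list[SampleMeta]

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_id in metadata")
        if list(self.counts.columns) != ids:
            missing = set(self.counts.columns) ^ set(ids)
            raise FormatError(f"count columns and sample metadata disagree: {sorted(missing)}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicated guide_id rows: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts")
        # replicate ids unique within (arm, drug, editor)
        seen: dict[tuple, set] = {}
        for s in self.samples:
            key = (s.arm, s.drug, s.editor)
            reps = seen.setdefault(key, set())
            if s.replicate in reps:
                raise FormatError(
                    f"duplicate replicate {s.replicate} within arm={s.arm}, drug={s.drug}"
                )
            reps.add(s.replicate)

    @property
    def guides(self) -> list[str]:
        return list(self.counts.index)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def sample_ids(self, arm: str | None = None, drug: str | None = None) -> list[str]:
        """Sample ids filtered by arm and (for drug arms) drug name."""
        out = []
        for s in self.samples:
            if arm is not None and s.arm != arm:
                continue
            if drug is not None and s.drug != drug:
                continue
            out.append(s.sample_id)
        return out


_LIBRARY_COLUMNS = [
    "guide_id",
    "protospacer",
    "pam",
    "gene",
    "category",
    "editor",
    "predicted_consequence",
    "perfect_match_count",
]


def read_library(path: str | Path) -> list[GuideRecord]:
    """Read a guide library annotation TSV into GuideRecords.

    Required columns: guide_id, protospacer, pam, gene, category, editor,
    predicted_consequence, perfect_match_count. Extra columns are kept in
    ``GuideRecord.extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _LIBRARY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"library table missing required column {col!r}")
    extra_cols = [c for c in df.columns if c not in _LIBRARY_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            rec = GuideRecord(
                guide_id=d["guide_id"],
                protospacer=d["protospacer"].upper(),
                pam=d["pam"].upper(),
                gene=d["gene"] or None,
                category=d["category"],
                editor=d["editor"],
                predicted_consequence=d["predicted_consequence"] or None,
                perfect_match_count=int(d["perfect_match_count"]),
                extra={c: d[c] for c in extra_cols},
            )
        except FormatError as e:
            raise FormatError(f"library row {i + 2}: {e}") from e
        records.append(rec)
    return records


def write_library(records: Iterable[GuideRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "guide_id": r.guide_id,
            "protospacer": r.protospacer,
            "pam": r.pam,
            "gene": r.gene or "",
            "category": r.category,
            "editor": r.editor,
            "predicted_consequence": r.predicted_consequence or "",
            "perfect_match_count": r.perfect_match_count,
        }
        row.update(r.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "arm", "replicate", "cell_line", "editor", "drug"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"sample metadata missing required column {col!r}")
    return [
        SampleMeta(
            sample_id=d.sample_id,
            arm=d.arm,
            replicate=int(d.replicate),
            cell_line=d.cell_line,
            editor=d.editor,
            drug=d.drug or None,
        )
        for d in df.itertuples(index=False)
    ]


def read_counts(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a guide x sample count TSV plus its sample-metadata sidecar."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "guide_id":
        raise FormatError("counts table must have 'guide_id' as its first column")
    df = df.set_index("guide_id")
    meta = read_sample_meta(meta_path)
    by_id = {s.sample_id: s for s in meta}
    unmatched = [c for c in df.columns if c not in by_id]
    if unmatched:
        raise FormatError(f"count columns without sample metadata: {unmatched}")
    samples = [by_id[c] for c in df.columns]
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError("counts must be numeric")
    if (vals < 0).any():
        raise FormatError("negative counts")
    return CountMatrix(counts=df.astype(np.int64), samples=samples)


def write_counts(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    cm.counts.rename_axis("guide_id").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "arm": s.arm,
                "replicate": s.replicate,
                "cell_line": s.cell_line,
                "editor": s.editor,
                "drug": s.drug or "",
            }
            for s in cm.samples
        ]
    ).to_csv(meta_path, sep="\t", index=False)


def write_results(table: pd.DataFrame, path: str | Path, json_path: str | Path | None = None) -> None:
    """Write a result table as TSV with stable column order and fixed float precision.

    Floats are written with 12 significant digits so a re-read reproduces the
    table to well within 1e-9.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if json_path is not None:
        df.to_json(json_path, orient="records", indent=1)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file (QC thresholds, class thresholds, ...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a YAML mapping")
    return cfg


def category_tally(records: Sequence[GuideRecord]) -> pd.Series:
    """Count guides per category (library composition check)."""
    return pd.Series([r.category for r in records]).value_counts()
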