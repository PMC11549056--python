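"""Perturb-seq-derived per-variant scores.

Cells are linked to the guide (and hence the installed variant) they carry.
Four read-outs quantify how far a variant pushes the transcriptome:

* energy distance between a variant's cells and nontargeting (NT) cells,
  E = 2 E||x-y|| - E||x-x'|| - E||y-y'|| over Euclidean distances, reported
  raw and as the normalized coefficient E / (2 E||x-y||) in [0, 1];
* a chi-squared test for cell-cycle phase occupancy shifts between control
  and drug-resistant cells;
* a transcriptional-impact ranking of variants by normalized energy
  distance from pooled NT cells;
* a progression-free-survival (PFS) outcome score: the Spearman rank
  correlation between a variant's differential-expression signature and a
  treatment-responder reference signature, with per-class two-sided
  Wilcoxon rank-sum comparison against NT guides.

Expression is consumed already log-normalized; cycle phases and DE
signatures are inputs (a naive mean-difference signature builder is
provided for synthetic data).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist

from .errors import BescanError, DegenerateDistributionError

PHASES = ("G1", "S", "G2M")


@dataclass
class SignatureVector:
    """Per-variant differential-expression signature aligned to a gene list."""

    genes: list[str]
    logfc: np.ndarray

    def __post_init__(self):
        self.logfc = np.asarray(self.logfc, dtype=float)
        if len(self.genes) != len(self.logfc):
            raise BescanError("genes and logfc must align")
        if len(set(self.genes)) != len(self.genes):
            raise BescanError("signature gene list contains duplicates")

    def as_series(self) -> pd.Series:
        return pd.Series(self.logfc, index=self.genes)


@dataclass
class EnergyDistanceResult:
    raw: float
    normalized: float


@dataclass
class OutcomeScore:
    guide_id: str
    rho: float
    variant_class: str
    group_p: float = float("nan")


def _as_matrix(cells) -> np.ndarray:
    a = cells.to_numpy() if isinstance(cells, pd.DataFrame) else np.asarray(cells, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def energy_distance(cells_a, cells_b) -> EnergyDistanceResult:
    """Energy distance between two cell populations in the same gene space.

    Means are taken over all ordered pairs (the V-statistic estimator, whose
    within-sample diagonal terms are zero), so the distance is non-negative
    and exactly zero when the two samples are identical multisets; a
    singleton sample's within-term is zero. The normalized coefficient
    divides by twice the mean cross distance, giving a scale-free statistic
    in [0, 1] (0 for identical distributions, 1 for non-overlapping point
    masses).
    """
    if isinstance(cells_a, pd.DataFrame) and isinstance(cells_b, pd.DataFrame):
        if list(cells_a.columns) != list(cells_b.columns):
            raise BescanError("cell populations are in different gene spaces")
    a, b = _as_matrix(cells_a), _as_matrix(cells_b)
    if a.shape[1] != b.shape[1]:
        raise BescanError(
            f"gene-space mismatch: {a.shape[1]} vs {b.shape[1]} dimensions"
        )
    if len(a) < 1 or len(b) < 1:
        raise BescanError("each population needs at least one cell")
    cross = float(cdist(a, b).mean())
    within_a = float(2.0 * pdist(a).sum() / len(a) ** 2) if len(a) > 1 else 0.0
    within_b = float(2.0 * pdist(b).sum() / len(b) ** 2) if len(b) > 1 else 0.0
    raw = 2 * cross - within_a - within_b
    normalized = raw / (2 * cross) if cross > 0 else 0.0
    return EnergyDistanceResult(raw=raw, normalized=normalized)


def cell_cycle_shift(
    phases_control, phases_resistant, phases: tuple[str, ...] = PHASES
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-squared on the 2 x n_phase contingency of group vs phase.

    Phases absent from both groups are dropped (df adjusts) with a warning.
    """
    ctrl = pd.Series(list(phases_control))
    res = pd.Series(list(phases_resistant))
    if len(ctrl) == 0 or len(res) == 0:
        raise BescanError("both groups must be non-empty")
    table = pd.DataFrame(
        {
            "control": ctrl.value_counts().reindex(phases, fill_value=0),
            "resistant": res.value_counts().reindex(phases, fill_value=0),
        }
    ).T
    empty = table.columns[(table.sum(axis=0) == 0)]
    if len(empty):
        warnings.warn(f"dropping phase(s) absent everywhere: {list(empty)}")
        table = table.drop(columns=empty)
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    props = table.div(table.sum(axis=1), axis=0)
    summary = pd.concat({"count": table, "proportion": props}, axis=0)
    return float(stat), float(p), summary


def pfs_outcome_score(
    signature: SignatureVector, reference: SignatureVector, min_shared: int = 10
) -> float:
    """Spearman rho of the signature against the reference over shared genes."""
    shared = [g for g in signature.genes if g in set(reference.genes)]
    if len(shared) < min_shared:
        raise BescanError(f"only {len(shared)} shared genes; need >= {min_shared}")
    x = signature.as_series().loc[shared].to_numpy()
    y = reference.as_series().loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDistributionError("constant vector: Spearman correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def pfs_outcome_scores(
    signatures: dict[str, SignatureVector],
    reference: SignatureVector,
    classes: dict[str, str],
    nt_class: str = "nontargeting",
    min_shared: int = 10,
) -> list[OutcomeScore]:
    """Per-guide PFS scores with per-class Wilcoxon rank-sum comparison vs NT guides."""
    scores = [
        OutcomeScore(
            guide_id=g,
            rho=pfs_outcome_score(sig, reference, min_shared),
            variant_class=classes.get(g, "control"),
        )
        for g, sig in signatures.items()
    ]
    nt_rhos = [s.rho for s in scores if s.variant_class == nt_class]
    for cls in {s.variant_class for s in scores} - {nt_class}:
        rhos = [s.rho for s in scores if s.variant_class == cls]
        if nt_rhos and rhos:
            _, p = stats.ranksums(rhos, nt_rhos)
            for s in scores:
                if s.variant_class == cls:
                    s.group_p = float(p)
    return scores


def impact_rank(
    cells_by_guide: dict[str, "pd.DataFrame | np.ndarray"],
    nt_cells,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Rank guides by normalized energy distance from pooled NT cells (rank 1 = largest)."""
    rows = []
    for g, cells in cells_by_guide.items():
        m = _as_matrix(cells)
        if len(m) < min_cells:
            warnings.warn(f"guide {g} has {len(m)} cells (< {min_cells}); excluded")
            continue
        ed = energy_distance(m, nt_cells)
        rows.append({"guide_id": g, "energy_distance": ed.raw, "normalized_ed": ed.normalized})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values("normalized_ed", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def mean_difference_signatures(
    expression: pd.DataFrame, guide_of_cell: pd.Series, nt_guides: set[str]
) -> dict[str, SignatureVector]:
    """Naive per-guide DE signatures: mean expression difference vs pooled NT cells.

    Intended for synthetic data; real differential expression should come
    from an upstream single-cell DE procedure.
    """
    nt_mask = guide_of_cell.isin(nt_guides)
    if not nt_mask.any():
        raise BescanError("no NT cells to build signatures against")
    nt_mean = expression.loc[nt_mask.index[nt_mask]].mean(axis=0)
    out = {}
    for g, cells in guide_of_cell.groupby(guide_of_cell):
        logfc = expression.loc[cells.index].mean(axis=0) - nt_mean
        out[g] = SignatureVector(genes=list(expression.columns), logfc=logfc.to_numpy())
    return out
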