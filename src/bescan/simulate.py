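"""Synthetic screens, genotyping tables and perturb-seq matrices.

The generators reproduce the statistical structure the analysis assumes so
every stage is testable without external data:

* ``simulate_screen`` — a tiling library with the study's control categories
  (57 NT / 168 intergenic / 87 nonessential-splice / 316 essential-splice at
  full scale, scaled proportionally), negative-binomial counts over plasmid,
  time-zero, control-arm and drug-arm samples with two replicates, planted
  guide effects for the four variant classes, and planted QC failures;
* ``simulate_genotyping`` — amplicon variant tables for 45 guides built on
  toy transcripts, with Beta-distributed in-window VAFs (high-efficiency
  profile, median ~= 0.92), Poisson depths, planted failures and planted
  background variants duplicated into the unedited table;
* ``simulate_perturbseq`` — Gaussian log-expression with class-specific mean
  shifts on disjoint pathway-proxy gene blocks (MAPK-proxy up in resistance
  classes, strongest plus JAK-proxy down in drug addiction), class-specific
  cell-cycle phase multinomials, naive DE signatures and a treatment-
  responder reference signature (MAPK-proxy down).

All generators are pure functions of the config: the same seed reproduces
bitwise-identical output. Truth tables carry the planted ground truth so
downstream confusion matrices never re-derive it.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .edits import EditorSpec, PredictedEdit, TranscriptModel, predict_edits, revcomp
from .errors import AmbiguousTargetError, BescanError, TargetNotFoundError
from .genotyping import AmpliconVariant
from .io import CountMatrix, GuideRecord, SampleMeta
from .sc_scores import SignatureVector

FULL_LIBRARY_SIZE = 22_816
FULL_CONTROL_COUNTS = {
    "nontargeting": 57,
    "intergenic": 168,
    "nonessential_splice": 87,
    "essential_splice": 316,
}
TARGET_GENES = [f"GENE{i:02d}" for i in range(1, 12)]  # 11 mutagenized genes

DEFAULT_EFFECTS = {
    "drug_addiction": (3.0, -3.0),
    "canonical_resistance": (3.0, 0.0),
    "driver": (3.0, 3.0),
    "sensitizing": (-3.0, 0.0),
    "essential_splice": (-3.0, -3.0),
}
DEFAULT_PLANTED = {
    "drug_addiction": 10,
    "canonical_resistance": 30,
    "driver": 24,
    "sensitizing": 111,
}
DEFAULT_QC_FAILURES = {"multi_mapping": 20, "low_count": 10, "replicate_discordant": 10}

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    n_guides: int = 2000
    control_counts: dict | None = None  # None -> FULL_CONTROL_COUNTS scaled by n_guides
    nb_mean: float = 500.0
    nb_dispersion: float = 0.1
    depth_per_sample: float | None = None  # informational; defaults to n_guides * nb_mean
    effects: dict = dfield(default_factory=lambda: dict(DEFAULT_EFFECTS))
    planted_counts: dict = dfield(default_factory=lambda: dict(DEFAULT_PLANTED))
    qc_failures: dict = dfield(default_factory=lambda: dict(DEFAULT_QC_FAILURES))
    replicates: int = 2
    drug: str = "drugA"
    cell_line: str = "SYN-1"
    editor: str = "ABE"
    # genotyping profile
    n_genotyped: int = 45
    n_genotype_failures: int = 2
    n_background: int = 3
    vaf_beta: tuple[float, float] = (8.0, 1.0)
    amplicon_depth: float = 5000.0
    # perturb-seq profile
    sc_genes: int = 200
    cells_per_guide: int = 50
    guides_per_class: int = 10

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise BescanError("nb_dispersion must be > 0")
        if self.replicates < 2:
            raise BescanError("need >= 2 replicates for per-replicate criteria")

    def scaled_control_counts(self) -> dict:
        if self.control_counts is not None:
            return dict(self.control_counts)
        scale = self.n_guides / FULL_LIBRARY_SIZE
        return {k: max(1, round(v * scale)) for k, v in FULL_CONTROL_COUNTS.items()}


# ---------------------------------------------------------------------------
# proliferation screen
# ---------------------------------------------------------------------------

@dataclass
class SimScreen:
    library: list[GuideRecord]
    counts: CountMatrix
    truth: pd.DataFrame  # index guide_id: planted_class, category, qc flag booleans


def _nb(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial in mean-dispersion form: var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _random_protospacers(rng: np.random.Generator, n: int) -> list[str]:
    seen, out = set(), []
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), size=20))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def simulate_screen(cfg: SimConfig) -> SimScreen:
    rng = np.random.default_rng([cfg.seed, 1])
    controls = cfg.scaled_control_counts()
    n_controls = sum(controls.values())
    n_targeting = cfg.n_guides - n_controls
    n_planted = sum(cfg.planted_counts.values())
    n_qc = sum(cfg.qc_failures.values())
    if n_targeting < n_planted + n_qc:
        raise BescanError(
            f"{cfg.n_guides} guides cannot hold {n_controls} controls + "
            f"{n_planted} planted effects + {n_qc} planted QC failures"
        )

    categories: list[str] = []
    for cat, n in controls.items():
        categories += [cat] * n
    categories += ["targeting"] * n_targeting

    guide_ids = [f"g{i:05d}" for i in range(cfg.n_guides)]
    protos = _random_protospacers(rng, cfg.n_guides)
    library, genes = [], []
    splice_counter = 0
    for i, cat in enumerate(categories):
        if cat == "targeting":
            gene = TARGET_GENES[i % len(TARGET_GENES)]
        elif cat in ("essential_splice", "nonessential_splice"):
            splice_counter += 1
            gene = f"{'ESS' if cat == 'essential_splice' else 'NONESS'}{splice_counter:03d}"
        else:
            gene = None
        genes.append(gene)
        library.append(
            GuideRecord(
                guide_id=guide_ids[i],
                protospacer=protos[i],
                pam="".join(rng.choice(list("ACGT"))) + "G" + "".join(rng.choice(list("ACGT"))),
                gene=gene,
                category=cat,
                editor=cfg.editor,
                perfect_match_count=1,
            )
        )

    # plant classes and QC failures on disjoint random targeting guides
    targeting_idx = [i for i, c in enumerate(categories) if c == "targeting"]
    pool = rng.permutation(targeting_idx)
    planted_class = np.array(["null"] * cfg.n_guides, dtype=object)
    for i, cat in enumerate(categories):
        if cat != "targeting":
            planted_class[i] = cat
    cursor = 0
    for cls in ("drug_addiction", "canonical_resistance", "driver", "sensitizing"):
        n = cfg.planted_counts.get(cls, 0)
        for j in pool[cursor : cursor + n]:
            planted_class[j] = cls
        cursor += n
    qc_flags = {flag: np.zeros(cfg.n_guides, dtype=bool) for flag in DEFAULT_QC_FAILURES}
    for flag in ("multi_mapping", "low_count", "replicate_discordant"):
        n = cfg.qc_failures.get(flag, 0)
        for j in pool[cursor : cursor + n]:
            qc_flags[flag][j] = True
            if flag == "multi_mapping":
                library[j].perfect_match_count = 3
        cursor += n

    # planted fold changes per arm
    l2fc_drug = np.zeros(cfg.n_guides)
    l2fc_ctrl = np.zeros(cfg.n_guides)
    for i in range(cfg.n_guides):
        eff = cfg.effects.get(planted_class[i])
        if eff is not None:
            l2fc_drug[i], l2fc_ctrl[i] = eff

    plasmid_mean = np.full(cfg.n_guides, cfg.nb_mean)
    plasmid_mean[qc_flags["low_count"]] = 30.0  # planted low-abundance dropouts

    samples, columns = [], {}
    samples.append(
        SampleMeta("plasmid", "plasmid", 1, cfg.cell_line, cfg.editor)
    )
    plasmid = _nb(rng, plasmid_mean, cfg.nb_dispersion)
    columns["plasmid"] = plasmid
    # cells inherit the actual plasmid pool composition: arm counts are NB
    # around a plasmid-proportional mean scaled by the planted fold change
    base_mean = plasmid.astype(float)
    for rep in range(1, cfg.replicates + 1):
        sid = f"t0_r{rep}"
        samples.append(SampleMeta(sid, "t0", rep, cfg.cell_line, cfg.editor))
        columns[sid] = _nb(rng, base_mean, cfg.nb_dispersion)
    for rep in range(1, cfg.replicates + 1):
        sid = f"control_r{rep}"
        samples.append(SampleMeta(sid, "control", rep, cfg.cell_line, cfg.editor))
        counts = _nb(rng, base_mean * 2.0**l2fc_ctrl, cfg.nb_dispersion)
        if rep == cfg.replicates:
            # plant replicate discordance by 20-fold down-sampling in one replicate
            mask = qc_flags["replicate_discordant"]
            counts = counts.copy()
            counts[mask] = rng.binomial(counts[mask], 0.05)
        columns[sid] = counts
    for rep in range(1, cfg.replicates + 1):
        sid = f"drug_r{rep}"
        samples.append(SampleMeta(sid, "drug", rep, cfg.cell_line, cfg.editor, drug=cfg.drug))
        columns[sid] = _nb(rng, base_mean * 2.0**l2fc_drug, cfg.nb_dispersion)

    counts_df = pd.DataFrame(columns, index=pd.Index(guide_ids, name="guide_id"), dtype=np.int64)
    truth = pd.DataFrame(
        {
            "planted_class": planted_class,
            "category": categories,
            "gene": genes,
            "l2fc_drug": l2fc_drug,
            "l2fc_control": l2fc_ctrl,
            **{f"planted_{k}": v for k, v in qc_flags.items()},
        },
        index=pd.Index(guide_ids, name="guide_id"),
    )
    return SimScreen(
        library=library, counts=CountMatrix(counts=counts_df, samples=samples), truth=truth
    )


# ---------------------------------------------------------------------------
# toy transcripts and guide discovery (shared by tests and genotyping sim)
# ---------------------------------------------------------------------------

def random_transcript(
    rng: np.random.Generator,
    gene: str = "TOY",
    n_codons: int = 30,
    n_introns: int = 1,
    strand: str = "+",
    utr5: int = 6,
    utr3: int = 6,
) -> TranscriptModel:
    """A random toy locus with a valid intron/exon structure and CDS.

    The CDS is ATG + random non-stop codons + stop; introns carry canonical
    GT...AG dinucleotides.
    """
    cds = "ATG" + "".join(rng.choice(_CODONS, size=n_codons - 2)) + "TAA"
    transcript = (
        "".join(rng.choice(list("ACGT"), size=utr5))
        + cds
        + "".join(rng.choice(list("ACGT"), size=utr3))
    )
    # split the transcript at interior points into n_introns + 1 exon pieces
    if n_introns > 0:
        cuts = sorted(rng.choice(np.arange(1, len(transcript)), size=n_introns, replace=False))
    else:
        cuts = []
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(transcript[prev:c])
        prev = c
    pieces.append(transcript[prev:])
    locus_parts, exons, pos = [], [], 0
    for i, piece in enumerate(pieces):
        if i > 0:
            intron = "GT" + "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 15)))) + "AG"
            locus_parts.append(intron)
            pos += len(intron)
        exons.append((pos, pos + len(piece)))
        locus_parts.append(piece)
        pos += len(piece)
    locus = "".join(locus_parts)
    if strand == "-":
        L = len(locus)
        locus = revcomp(locus)
        exons = [(L - e, L - s) for s, e in reversed(exons)]
    return TranscriptModel(
        gene=gene,
        chrom_seq=locus,
        exons=exons,
        strand=strand,
        cds_start_codon_offset=utr5,
        cds_end_offset=utr5 + len(cds),
    )


def scan_guides(
    model: TranscriptModel, spec: EditorSpec, pam_rule: str = "NGN"
) -> list[tuple[str, PredictedEdit]]:
    """All uniquely mapping guides on a locus with their predicted max-edit alleles."""
    out, seen = [], set()
    seq = model.chrom_seq
    candidates = [seq[i : i + 20] for i in range(len(seq) - 22)]
    candidates += [revcomp(seq[i + 3 : i + 23]) for i in range(len(seq) - 22)]
    for proto in candidates:
        if proto in seen or len(set(proto) - set("ACGT")) > 0 or len(proto) != 20:
            continue
        seen.add(proto)
        try:
            pe = predict_edits(proto, model, spec, pam_rule)
        except (TargetNotFoundError, AmbiguousTargetError):
            continue
        out.append((proto, pe))
    return out


# ---------------------------------------------------------------------------
# amplicon genotyping
# ---------------------------------------------------------------------------

@dataclass
class SimGenotyping:
    edited: list[AmpliconVariant]
    unedited: list[AmpliconVariant]
    truth: pd.DataFrame  # index guide_id: should_verify, planted_vaf, has_background
    models: dict[str, TranscriptModel]
    predicted: dict[str, PredictedEdit]


def _missense_target(rng: np.random.Generator, spec: EditorSpec, gene: str):
    """Toy transcript + guide whose max-edit allele is missense."""
    for _ in range(200):
        model = random_transcript(rng, gene=gene, n_codons=int(rng.integers(20, 40)))
        hits = [
            (p, pe)
            for p, pe in scan_guides(model, spec)
            if pe.consequence_class == "missense"
        ]
        if hits:
            proto, pe = hits[int(rng.integers(len(hits)))]
            return model, proto, pe
    raise BescanError("could not construct a missense toy target")  # pragma: no cover


def simulate_genotyping(cfg: SimConfig, spec: EditorSpec | None = None) -> SimGenotyping:
    rng = np.random.default_rng([cfg.seed, 2])
    spec = spec or EditorSpec(editor="CBE")
    n = cfg.n_genotyped
    n_fail = cfg.n_genotype_failures
    a, b = cfg.vaf_beta
    edited, unedited = [], []
    models, predicted, rows = {}, {}, []
    background_guides = set(rng.choice(np.arange(n - n_fail), size=cfg.n_background, replace=False))
    for i in range(n):
        gid = f"amp{i:03d}"
        model, proto, pe = _missense_target(rng, spec, gene=f"GENE{i % 7:02d}")
        models[gid], predicted[gid] = model, pe
        failing = i >= n - n_fail
        fail_mode = ("low_depth", "low_vaf")[i % 2] if failing else ""
        vaf = float(rng.beta(a, b)) if not failing else 0.0
        for pos0, ref, alt in pe.genomic_changes:
            if fail_mode == "low_depth":
                depth, v = int(rng.poisson(500)), float(rng.beta(a, b))
            elif fail_mode == "low_vaf":
                depth, v = int(rng.poisson(cfg.amplicon_depth)), float(rng.uniform(0.01, 0.08))
            else:
                depth, v = int(rng.poisson(cfg.amplicon_depth)), vaf
            edited.append(
                AmpliconVariant(gid, pos0 + 1, ref, alt, depth, v, "edited", gid)
            )
        if i in background_guides:
            # a pre-existing cell-line variant seen in both edited and unedited DNA
            window = set(pe.window_positions)
            cand = [
                p
                for p in range(len(model.chrom_seq))
                if p not in window and all(p != c[0] for c in pe.genomic_changes)
            ]
            p0 = int(rng.choice(cand))
            ref = model.chrom_seq[p0]
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            for kind, bucket in (("edited", edited), ("unedited", unedited)):
                bucket.append(
                    AmpliconVariant(
                        gid, p0 + 1, ref, alt, int(rng.poisson(cfg.amplicon_depth)),
                        0.3, kind, gid,
                    )
                )
        rows.append(
            {
                "guide_id": gid,
                "should_verify": not failing,
                "planted_vaf": vaf if not failing else float("nan"),
                "fail_mode": fail_mode,
                "has_background": i in background_guides,
            }
        )
    truth = pd.DataFrame(rows).set_index("guide_id")
    return SimGenotyping(
        edited=edited, unedited=unedited, truth=truth, models=models, predicted=predicted
    )


# ---------------------------------------------------------------------------
# perturb-seq
# ---------------------------------------------------------------------------

@dataclass
class SimPerturbSeq:
    expression: pd.DataFrame  # cells x genes, log-normalized scale
    cells: pd.DataFrame  # cell_id, guide_id, variant_class, cycle_phase
    signatures: dict[str, SignatureVector]
    reference: SignatureVector
    truth: pd.DataFrame  # per-guide planted class and shift magnitudes


# pathway-proxy gene blocks and planted mean shifts (log-expression units)
_SC_CLASSES = {
    # class: (MAPK-proxy shift, JAK-proxy shift, S-phase enrichment)
    "nontargeting": (0.0, 0.0, False),
    "control": (0.0, 0.0, False),
    "canonical_resistance": (1.0, 0.0, True),
    "driver": (1.0, 0.0, True),
    "drug_addiction": (2.0, -1.5, True),
}
_PHASE_BASE = (0.60, 0.25, 0.15)  # G1, S, G2M
_PHASE_RESISTANT = (0.40, 0.45, 0.15)


def simulate_perturbseq(cfg: SimConfig) -> SimPerturbSeq:
    rng = np.random.default_rng([cfg.seed, 3])
    g = cfg.sc_genes
    if g < 80:
        raise BescanError("sc_genes must be >= 80 to hold the pathway blocks")
    genes = [f"gene{j:04d}" for j in range(g)]
    mapk = slice(0, 40)
    jak = slice(40, 80)

    rows_expr, rows_meta, truth_rows = [], [], []
    guide_names = {}
    for cls, (d_mapk, d_jak, s_enriched) in _SC_CLASSES.items():
        for k in range(cfg.guides_per_class):
            gid = f"{cls}_{k:02d}"
            guide_names[gid] = cls
            mu = np.zeros(g)
            mu[mapk] = d_mapk
            mu[jak] = d_jak
            phases = _PHASE_RESISTANT if s_enriched else _PHASE_BASE
            n_cells = cfg.cells_per_guide
            expr = rng.normal(mu, 1.0, size=(n_cells, g))
            phase_draw = rng.choice(["G1", "S", "G2M"], size=n_cells, p=phases)
            for c in range(n_cells):
                rows_expr.append(expr[c])
                rows_meta.append(
                    {
                        "cell_id": f"{gid}_c{c:03d}",
                        "guide_id": gid,
                        "variant_class": cls,
                        "cycle_phase": phase_draw[c],
                    }
                )
            truth_rows.append(
                {"guide_id": gid, "variant_class": cls, "mapk_shift": d_mapk, "jak_shift": d_jak}
            )
    cells = pd.DataFrame(rows_meta).set_index("cell_id")
    expression = pd.DataFrame(
        np.vstack(rows_expr), index=cells.index, columns=genes
    )

    nt_mask = cells["guide_id"].str.startswith("nontargeting")
    nt_mean = expression.loc[nt_mask].mean(axis=0)
    signatures = {
        gid: SignatureVector(
            genes=genes,
            logfc=(expression.loc[cells["guide_id"] == gid].mean(axis=0) - nt_mean).to_numpy(),
        )
        for gid in guide_names
    }
    ref = np.zeros(g)
    ref[mapk] = -1.0  # responders: MAPK programme suppressed by treatment
    ref[jak] = 0.5    # responders: JAK-STAT / antigen presentation restored
    ref += rng.normal(0, 0.05, size=g)  # break ties off the pathway blocks
    reference = SignatureVector(genes=genes, logfc=ref)
    return SimPerturbSeq(
        expression=expression,
        cells=cells,
        signatures=signatures,
        reference=reference,
        truth=pd.DataFrame(truth_rows).set_index("guide_id"),
    )
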