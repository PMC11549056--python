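"""Base-editor consequence prediction.

A cytidine base editor (CBE) converts C>T and an adenine base editor (ABE)
converts A>G within an activity window of the protospacer, by convention
nucleotides 4-9 counting from the 5' (PAM-distal) end. Given a guide, a
locus sequence with an exon model, and an editor, this module locates the
PAM-adjacent target site, converts every editable base in the window (the
max-edit allele, which amplicon sequencing shows is the typical outcome at
high editing efficiency), and translates the result into a protein or
splice consequence such as ``L390S/S391P`` or ``M1V``.

Coordinates are 0-based half-open internally; protein positions are 1-based.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import AmbiguousTargetError, FormatError, TargetNotFoundError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CONSEQUENCE_CLASSES = (
    "synonymous", "missense", "stop_gained", "start_lost",
    "splice_donor", "splice_acceptor", "utr", "intronic", "none",
)

NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "stop_gained", "start_lost", "splice_donor", "splice_acceptor"}
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches_pam(seq: str, rule: str) -> bool:
    if len(seq) != len(rule):
        return False
    return all(base in IUPAC[sym] for base, sym in zip(seq, rule.upper()))


@dataclass
class EditorSpec:
    """Editor chemistry and activity window.

    Window positions are 1-based within the protospacer, position 1 at the
    PAM-distal end, inclusive bounds. Defaults cover nucleotides 4-9.
    """

    editor: str = "CBE"
    window_start: int = 4
    window_end: int = 9

    def __post_init__(self):
        if self.editor not in ("CBE", "ABE"):
            raise FormatError(f"unknown editor {self.editor!r}")
        if not (1 <= self.window_start <= self.window_end <= 20):
            raise FormatError("editing window must satisfy 1 <= start <= end <= 20")

    @property
    def base_from(self) -> str:
        return "C" if self.editor == "CBE" else "A"

    @property
    def base_to(self) -> str:
        return "T" if self.editor == "CBE" else "G"


@dataclass
class TranscriptModel:
    """A gene locus with exon structure and CDS placement.

    ``exons`` are 0-based half-open intervals on ``chrom_seq`` in genomic
    order. ``cds_start_codon_offset`` locates the A of the start codon in
    spliced-transcript coordinates (strand-aware); ``cds_end_offset`` is the
    half-open end of the CDS in the same coordinates (defaults to transcript
    end).
    """

    gene: str
    chrom_seq: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    cds_start_codon_offset: int = 0
    cds_end_offset: int | None = None

    def __post_init__(self):
        self.chrom_seq = self.chrom_seq.upper()
        if self.strand not in "+-":
            raise FormatError("strand must be '+' or '-'")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.chrom_seq)):
                raise FormatError(f"exon ({s},{e}) outside locus")
            if s < prev_end:
                raise FormatError("exons must be sorted and non-overlapping")
            prev_end = e
        cds = self.cds(self.chrom_seq)
        if len(cds) == 0 or len(cds) % 3 != 0:
            raise FormatError("spliced CDS length must be a positive multiple of 3")
        if cds[:3] != "ATG":
            raise FormatError(f"CDS must start with ATG, got {cds[:3]}")

    # -- coordinate helpers -------------------------------------------------
    def spliced(self, seq: str | None = None) -> str:
        seq = self.chrom_seq if seq is None else seq
        joined = "".join(seq[s:e] for s, e in self.exons)
        return revcomp(joined) if self.strand == "-" else joined

    def cds(self, seq: str | None = None) -> str:
        t = self.spliced(seq)
        end = len(t) if self.cds_end_offset is None else self.cds_end_offset
        return t[self.cds_start_codon_offset : end]

    def protein(self, seq: str | None = None) -> str:
        return str(Seq(self.cds(seq)).translate())

    def exonic_positions(self) -> set[int]:
        return {p for s, e in self.exons for p in range(s, e)}

    def cds_genomic_positions(self) -> set[int]:
        """Genomic positions whose spliced-transcript coordinate lies in the CDS."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        end = self.cds_end_offset
        if end is None:
            end = sum(e - s for s, e in self.exons)
        out, t = set(), 0
        for s, e in order:
            for g in (range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)):
                if self.cds_start_codon_offset <= t < end:
                    out.add(g)
                t += 1
        return out

    def splice_sites(self) -> list[tuple[str, set[int]]]:
        """Canonical 2-bp donor/acceptor dinucleotide positions, strand-aware.

        Donor = first two intron bases after an exon in transcript order (GT);
        acceptor = last two intron bases before an exon (AG).
        """
        sites: list[tuple[str, set[int]]] = []
        if len(self.exons) < 2:
            return sites
        for i, (s, e) in enumerate(self.exons):
            if self.strand == "+":
                if i < len(self.exons) - 1:
                    sites.append(("splice_donor", {e, e + 1}))
                if i > 0:
                    sites.append(("splice_acceptor", {s - 2, s - 1}))
            else:
                # transcript order runs right-to-left across the locus
                if i > 0:
                    sites.append(("splice_donor", {s - 2, s - 1}))
                if i < len(self.exons) - 1:
                    sites.append(("splice_acceptor", {e, e + 1}))
        return sites


@dataclass
class PredictedEdit:
    """Window edits for one guide and their predicted consequence."""

    guide_id: str
    edited_positions: list[int]  # 1-based protospacer positions
    genomic_changes: list[tuple[int, str, str]]  # (+)-strand locus (pos0, ref, alt)
    protein_consequence: str
    consequence_class: str
    window_positions: list[int] = field(default_factory=list)  # genomic, 0-based
    site: tuple[int, str] | None = None  # (locus offset, strand)


def find_target_site(
    protospacer: str, model: TranscriptModel, pam_rule: str = "NGN"
) -> tuple[int, str]:
    """Locate a protospacer + PAM in the locus on either strand.

    Returns (0-based offset of the protospacer's 5'-most locus base on the +
    strand, strand). Protospacer position 1 is PAM-distal: on '+' sites it is
    the returned offset; on '-' sites it is offset+19.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20 or not set(protospacer) <= set("ACGT"):
        raise FormatError("protospacer must be a 20-nt ACGT string")
    seq = model.chrom_seq
    npam = len(pam_rule)
    hits: list[tuple[int, str]] = []
    # + strand: PAM immediately 3' of the protospacer
    start = 0
    while (i := seq.find(protospacer, start)) != -1:
        if _matches_pam(seq[i + 20 : i + 20 + npam], pam_rule):
            hits.append((i, "+"))
        start = i + 1
    # - strand: locus shows the reverse complement; PAM lies 5' of the match
    rc = revcomp(protospacer)
    start = 0
    while (i := seq.find(rc, start)) != -1:
        pam = revcomp(seq[i - npam : i]) if i >= npam else ""
        if _matches_pam(pam, pam_rule):
            hits.append((i, "-"))
        start = i + 1
    if not hits:
        raise TargetNotFoundError(
            f"protospacer {protospacer} has no {pam_rule}-adjacent match in {model.gene}"
        )
    if len(hits) > 1:
        raise AmbiguousTargetError(
            f"protospacer {protospacer} matches {model.gene} at {len(hits)} sites: {hits}",
            sites=hits,
        )
    return hits[0]


def _protospacer_genomic_pos(site: tuple[int, str], i: int) -> int:
    """Genomic position of protospacer position i (1-based, PAM-distal = 1)."""
    off, strand = site
    return off + i - 1 if strand == "+" else off + 20 - i


def classify_changes(
    model: TranscriptModel, changes: list[tuple[int, str, str]]
) -> tuple[str, str]:
    """Consequence (protein string, class) for a set of (+)-strand substitutions.

    The class is the most severe consequence touched, in the order splice >
    start-lost > stop-gained > missense > synonymous > UTR > intronic.
    """
    if not changes:
        return "", "none"
    seq = list(model.chrom_seq)
    for pos, ref, alt in changes:
        if seq[pos] != ref:
            raise FormatError(f"reference mismatch at {pos}: locus has {seq[pos]}, change says {ref}")
        seq[pos] = alt
    mutated = "".join(seq)

    splice_class = None
    for kind, positions in model.splice_sites():
        if positions & {pos for pos, _, _ in changes}:
            if splice_class is None or kind == "splice_donor":
                splice_class = kind

    ref_protein = model.protein()
    alt_protein = model.protein(mutated)
    diffs = [
        (i + 1, r, a)
        for i, (r, a) in enumerate(zip(ref_protein, alt_protein))
        if r != a
    ]
    # truncate the report at a gained stop: downstream residues are vacuous
    for k, (_, _, a) in enumerate(diffs):
        if a == "*":
            diffs = diffs[: k + 1]
            break
    protein_str = "/".join(f"{r}{p}{a}" for p, r, a in diffs)

    if splice_class is not None:
        return protein_str, splice_class
    if diffs:
        if diffs[0][0] == 1 and ref_protein[0] == "M":
            return protein_str, "start_lost"
        if any(a == "*" for _, _, a in diffs):
            return protein_str, "stop_gained"
        return protein_str, "missense"

    cds_pos = model.cds_genomic_positions()
    exonic = model.exonic_positions()
    touched = {pos for pos, _, _ in changes}
    if touched & cds_pos:
        return "", "synonymous"
    if touched & exonic:
        return "", "utr"
    return "", "intronic"


def predict_edits(
    protospacer: str,
    model: TranscriptModel,
    spec: EditorSpec,
    pam_rule: str = "NGN",
    guide_id: str | None = None,
) -> PredictedEdit:
    """Predict the max-edit allele for a guide: every editable window base converted."""
    site = find_target_site(protospacer, model, pam_rule)
    _, strand = site
    protospacer = protospacer.upper()
    editable = [
        i
        for i in range(spec.window_start, spec.window_end + 1)
        if protospacer[i - 1] == spec.base_from
    ]
    changes = [_change_at(site, i, spec) for i in editable]
    changes.sort()
    protein_str, cls = classify_changes(model, changes)
    window = sorted(
        _protospacer_genomic_pos(site, i)
        for i in range(spec.window_start, spec.window_end + 1)
    )
    return PredictedEdit(
        guide_id=guide_id or protospacer,
        edited_positions=editable,
        genomic_changes=changes,
        protein_consequence=protein_str,
        consequence_class=cls,
        window_positions=window,
        site=site,
    )


def _change_at(site: tuple[int, str], i: int, spec: EditorSpec) -> tuple[int, str, str]:
    g = _protospacer_genomic_pos(site, i)
    if site[1] == "+":
        return (g, spec.base_from, spec.base_to)
    comp = str.maketrans("ACGT", "TGCA")
    return (g, spec.base_from.translate(comp), spec.base_to.translate(comp))


def enumerate_alleles(
    protospacer: str,
    model: TranscriptModel,
    spec: EditorSpec,
    pam_rule: str = "NGN",
    guide_id: str | None = None,
    max_combinations: int = 8,
) -> list[PredictedEdit]:
    """All nonempty subsets of editable window bases, deduplicated by consequence.

    Supports interpretation of partially edited amplicon alleles. Refuses
    k > max_combinations editable bases (2^k - 1 alleles) unless raised.
    """
    site = find_target_site(protospacer, model, pam_rule)
    protospacer = protospacer.upper()
    editable = [
        i
        for i in range(spec.window_start, spec.window_end + 1)
        if protospacer[i - 1] == spec.base_from
    ]
    if len(editable) > max_combinations:
        raise FormatError(
            f"{len(editable)} editable bases gives {2 ** len(editable) - 1} alleles; "
            f"raise max_combinations to enumerate"
        )
    out: list[PredictedEdit] = []
    seen: set[str] = set()
    window = sorted(
        _protospacer_genomic_pos(site, i)
        for i in range(spec.window_start, spec.window_end + 1)
    )
    for r in range(1, len(editable) + 1):
        for subset in itertools.combinations(editable, r):
            changes = sorted(_change_at(site, i, spec) for i in subset)
            protein_str, cls = classify_changes(model, changes)
            key = f"{cls}|{protein_str}"
            if key in seen:
                continue
            seen.add(key)
            out.append(
                PredictedEdit(
                    guide_id=guide_id or protospacer,
                    edited_positions=list(subset),
                    genomic_changes=changes,
                    protein_consequence=protein_str,
                    consequence_class=cls,
                    window_positions=window,
                    site=site,
                )
            )
    return out
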