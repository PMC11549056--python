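"""Edit-consequence prediction against an independent re-translation oracle."""
import numpy as np
import pytest

from bescan.edits import (
    EditorSpec,
    TranscriptModel,
    enumerate_alleles,
    find_target_site,
    predict_edits,
    revcomp,
)
from bescan.errors import AmbiguousTargetError, FormatError, TargetNotFoundError
from bescan.simulate import random_transcript, scan_guides

# -- independent oracle: explicit codon table, slice-and-translate ----------

_ORACLE_CODONS = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_aas):
    _ORACLE_CODONS[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _a

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_translate(cds: str) -> str:
    return "".join(_ORACLE_CODONS[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


def oracle_spliced(model: TranscriptModel, seq: str) -> str:
    t = "".join(seq[s:e] for s, e in model.exons)
    if model.strand == "-":
        t = "".join(_RC[b] for b in reversed(t))
    return t


def oracle_consequence(model: TranscriptModel, changes):
    """Full re-translation of the mutated spliced CDS, independent decision code."""
    seq = list(model.chrom_seq)
    for pos, ref, alt in changes:
        assert seq[pos] == ref
        seq[pos] = alt
    mutated = "".join(seq)
    end = model.cds_end_offset
    off = model.cds_start_codon_offset

    def cds_of(s):
        t = oracle_spliced(model, s)
        return t[off : len(t) if end is None else end]

    ref_p = oracle_translate(cds_of(model.chrom_seq))
    alt_p = oracle_translate(cds_of(mutated))
    diffs = [(i + 1, r, a) for i, (r, a) in enumerate(zip(ref_p, alt_p)) if r != a]
    for k, (_, _, a) in enumerate(diffs):
        if a == "*":
            diffs = diffs[: k + 1]
            break
    protein = "/".join(f"{r}{p}{a}" for p, r, a in diffs)

    touched = {p for p, _, _ in changes}
    splice = None
    for kind, positions in model.splice_sites():
        if positions & touched:
            if splice is None or kind == "splice_donor":
                splice = kind
    if splice:
        return protein, splice
    if diffs:
        if diffs[0][0] == 1 and ref_p[0] == "M":
            return protein, "start_lost"
        if any(a == "*" for _, _, a in diffs):
            return protein, "stop_gained"
        return protein, "missense"
    if not changes:
        return "", "none"
    cds_ref = cds_of(model.chrom_seq)
    cds_alt = cds_of(mutated)
    if cds_ref != cds_alt:
        return "", "synonymous"
    if oracle_spliced(model, model.chrom_seq) != oracle_spliced(model, mutated):
        return "", "utr"
    return "", "intronic"


def _single_exon(cds_and_utr3: str, utr5: str = "", cds_len: int | None = None):
    seq = utr5 + cds_and_utr3
    return TranscriptModel(
        gene="TOY",
        chrom_seq=seq,
        exons=[(0, len(seq))],
        strand="+",
        cds_start_codon_offset=len(utr5),
        cds_end_offset=len(utr5) + (cds_len if cds_len is not None else len(cds_and_utr3)),
    )


class TestFindTargetSite:
    def _model(self, locus):
        return _single_exon("ATGAAATAA" + locus, cds_len=9)

    def test_plus_strand_match_with_agg_pam(self):
        proto = "TACGTACGTTACGATCGATC"
        model = self._model(proto + "AGGTTTTTTT")
        pos, strand = find_target_site(proto, model)
        assert (pos, strand) == (9, "+")

    def test_both_strands_ambiguous(self):
        proto = "TACGTACGTTACGATCGATC"
        locus = proto + "AGGTTTT" + "CCT" + revcomp(proto) + "TTTT"
        with pytest.raises(AmbiguousTargetError) as e:
            find_target_site(proto, self._model(locus))
        assert len(e.value.sites) == 2

    def test_no_pam_not_found(self):
        proto = "TACGTACGTTACGATCGATC"
        model = self._model(proto + "TATTTTTTTT")  # TAT fails NGN
        with pytest.raises(TargetNotFoundError):
            find_target_site(proto, model)


class TestPredictEdits:
    def test_no_editable_base_is_none(self):
        # window 4-9 of this guide has no C
        proto = "TTTAAAGGTTACGATCGATC"
        model = _single_exon("ATGAAATAA" + proto + "AGGTTTTTT", cds_len=9)
        pe = predict_edits(proto, model, EditorSpec("CBE"))
        assert pe.consequence_class == "none"
        assert pe.genomic_changes == [] and pe.edited_positions == []

    def test_double_missense_joined(self):
        # CDS ATG CCA CGC AAA TAG: window C's hit codons 2 and 3
        cds = "ATGCCACGCAAATAG"
        model = _single_exon(cds + "GGGTTTGGATCC", cds_len=len(cds))
        proto = model.chrom_seq[:20]
        pe = predict_edits(proto, model, EditorSpec("CBE"))
        expected_changes = [(3, "C", "T"), (4, "C", "T"), (6, "C", "T"), (8, "C", "T")]
        assert pe.genomic_changes == expected_changes
        oracle_p, oracle_c = oracle_consequence(model, expected_changes)
        assert pe.protein_consequence == oracle_p == "P2L/R3C"
        assert pe.consequence_class == oracle_c == "missense"

    def test_start_lost_m1v(self):
        # ABE window position 6 is the A of the start codon
        cds = "ATGCTGAAATAG"
        model = _single_exon(cds + "CGGTGGGTCCGGAT", utr5="TTTTT", cds_len=len(cds))
        proto = model.chrom_seq[:20]
        pe = predict_edits(proto, model, EditorSpec("ABE"))
        assert pe.protein_consequence == "M1V"
        assert pe.consequence_class == "start_lost"

    def test_splice_donor_disruption_found_by_scan(self):
        """ABE guides hitting a donor GT classify splice_donor; oracle agrees."""
        rng = np.random.default_rng(5)
        found = 0
        for _ in range(30):
            model = random_transcript(rng, n_codons=20, n_introns=2)
            for proto, pe in scan_guides(model, EditorSpec("ABE")):
                if pe.consequence_class != "splice_donor":
                    continue
                donor_pos = set().union(
                    *(p for k, p in model.splice_sites() if k == "splice_donor")
                )
                assert {c[0] for c in pe.genomic_changes} & donor_pos
                assert oracle_consequence(model, pe.genomic_changes)[1] == "splice_donor"
                found += 1
            if found >= 3:
                break
        assert found >= 3

    def test_synonymous_only_never_none(self):
        # only editable C is the wobble base of codon 3: AAC -> AAT (N3N)
        cds = "ATGAAAAACTAG"
        model = _single_exon(cds + "TGGATCGATGGT", cds_len=len(cds))
        proto = model.chrom_seq[:20]
        pe = predict_edits(proto, model, EditorSpec("CBE"))
        assert pe.edited_positions == [9]
        assert pe.consequence_class == "synonymous"
        assert pe.protein_consequence == ""


class TestEnumerateAlleles:
    def _two_codon_model(self):
        # editable C's in codons 2 (ACA->ATA) and 3 (CGG->TGG)
        cds = "ATGACACGGAAATAG"
        model = _single_exon(cds + "TGGTTGGTTAA", cds_len=len(cds))
        return model, model.chrom_seq[:20]

    def test_two_editable_gives_three_alleles(self):
        model, proto = self._two_codon_model()
        alleles = enumerate_alleles(proto, model, EditorSpec("CBE"))
        assert len(alleles) == 3
        assert {a.protein_consequence for a in alleles} == {"T2I", "R3W", "T2I/R3W"}

    def test_zero_editable_gives_empty(self):
        proto = "TTTAAAGGTTACGATCGATC"
        model = _single_exon("ATGAAATAA" + proto + "AGGTTTTTT", cds_len=9)
        assert enumerate_alleles(proto, model, EditorSpec("CBE")) == []

    def test_matches_brute_force_on_random_targets(self):
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(40):
            model = random_transcript(rng, n_codons=18, n_introns=1)
            for proto, pe in scan_guides(model, EditorSpec("CBE")):
                k = len(pe.edited_positions)
                if not 1 <= k <= 3:
                    continue
                alleles = enumerate_alleles(proto, model, EditorSpec("CBE"))
                # brute force: every nonempty subset, consequence via oracle
                import itertools

                seen = set()
                expected = []
                for r in range(1, k + 1):
                    for sub in itertools.combinations(pe.genomic_changes, r):
                        p, c = oracle_consequence(model, sorted(sub))
                        if (c, p) not in seen:
                            seen.add((c, p))
                            expected.append((c, p))
                got = [(a.consequence_class, a.protein_consequence) for a in alleles]
                assert sorted(got) == sorted(expected)
                checked += 1
            if checked >= 25:
                break
        assert checked >= 25

    def test_refuses_large_k(self):
        proto = "CCCCCCCCCAAAAAAAAAAA"  # 9 editable C's with a full-length window
        model = _single_exon("ATGAAATAA" + proto + "AGGATTTCAGGA", cds_len=9)
        spec = EditorSpec("CBE", window_start=1, window_end=20)
        with pytest.raises(FormatError, match="max_combinations"):
            enumerate_alleles(proto, model, spec)
        assert len(enumerate_alleles(proto, model, spec, max_combinations=9)) >= 1

    def test_max_edit_equals_maximal_enumerated(self):
        model, proto = self._two_codon_model()
        pe = predict_edits(proto, model, EditorSpec("CBE"))
        alleles = enumerate_alleles(proto, model, EditorSpec("CBE"))
        maximal = max(alleles, key=lambda a: len(a.edited_positions))
        assert (pe.protein_consequence, pe.consequence_class) == (
            maximal.protein_consequence,
            maximal.consequence_class,
        )


def mirror_model(model: TranscriptModel) -> TranscriptModel:
    """Reverse-complement the locus and flip every annotation."""
    L = len(model.chrom_seq)
    return TranscriptModel(
        gene=model.gene,
        chrom_seq=revcomp(model.chrom_seq),
        exons=[(L - e, L - s) for s, e in reversed(model.exons)],
        strand="-" if model.strand == "+" else "+",
        cds_start_codon_offset=model.cds_start_codon_offset,
        cds_end_offset=model.cds_end_offset,
    )


class TestStrandSymmetry:
    def test_consequences_invariant_under_mirror(self):
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(60):
            model = random_transcript(
                rng, n_codons=int(rng.integers(15, 30)), n_introns=int(rng.integers(0, 3)),
                strand=rng.choice(["+", "-"]),
            )
            mirrored = mirror_model(model)
            for proto, pe in scan_guides(model, EditorSpec("CBE"))[:5]:
                pe2 = predict_edits(proto, mirrored, EditorSpec("CBE"))
                assert pe2.protein_consequence == pe.protein_consequence
                assert pe2.consequence_class == pe.consequence_class
                checked += 1
            if checked >= 60:
                break
        assert checked >= 60
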