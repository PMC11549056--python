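"""Predict base-editing consequences for a guide on a toy transcript.

A cytidine base editor converts C>T within protospacer positions 4-9
(PAM-distal numbering). The max-edit allele converts every editable window
base at once; enumerate_alleles lists every partial-editing outcome.
"""
from bescan import EditorSpec, TranscriptModel, enumerate_alleles, predict_edits

# single-exon locus: CDS ATG CCA CGC AAA TAG followed by 3' sequence with a PAM
cds = "ATGCCACGCAAATAG"
model = TranscriptModel(
    gene="TOY",
    chrom_seq=cds + "GGGTTTGGATCC",
    exons=[(0, 27)],
    strand="+",
    cds_start_codon_offset=0,
    cds_end_offset=len(cds),
)
protospacer = model.chrom_seq[:20]
spec = EditorSpec(editor="CBE")  # window 4-9 by default

edit = predict_edits(protospacer, model, spec)
print(f"guide {protospacer} (CBE, window {spec.window_start}-{spec.window_end})")
print(f"editable window positions: {edit.edited_positions}")
print("genomic changes (+ strand, 0-based):", edit.genomic_changes)
print(f"max-edit consequence: {edit.protein_consequence} ({edit.consequence_class})")

print("\nAll distinct partial-editing alleles:")
for allele in enumerate_alleles(protospacer, model, spec):
    positions = ",".join(map(str, allele.edited_positions))
    print(f"  positions {positions:8s} -> {allele.protein_consequence or '(silent)'}"
          f" [{allele.consequence_class}]")

# The four window C's hit codons 2 and 3 simultaneously, giving the combined
# double-missense label P2L/R3C; partial alleles give the single-codon variants.
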