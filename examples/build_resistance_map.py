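"""Assemble a cross-drug variant function map and suggest alternative therapies.

Given per-drug variant classifications and amplicon-verified protein
genotypes, the map crosses every verified variant with every screened drug.
Canonical resistance is typically drug-specific (disrupted drug binding);
drug-addiction variants resist many inhibitors but suggest drug holidays.
"""
from bescan import CuratedVariant, GuideRecord, build_map, concordance, suggest_alternatives
from bescan.classify import VariantClassification
from bescan.genotyping import GuideGenotype

DRUGS = ["trametinib", "dabrafenib+cetuximab", "pictilisib", "sotorasib"]

library = [
    GuideRecord(f"g{i}", "A" * 20, "AGG", gene, "targeting", "ABE")
    for i, gene in enumerate(["MAP2K1", "MAP2K2", "PIK3CA"])
]
genotypes = [
    GuideGenotype("g0", [], "L115P", "missense", 0.95, "verified_nonsynonymous"),
    GuideGenotype("g1", [], "Y134H", "missense", 0.97, "verified_nonsynonymous"),
    GuideGenotype("g2", [], "E545K", "missense", 0.88, "verified_nonsynonymous"),
]

# per-drug classes as the proliferation screens called them
calls = {
    "g0": {"trametinib": "canonical_resistance"},              # MEK inhibitor binding site
    "g1": {d: "drug_addiction" for d in DRUGS[:3]},            # broad, costly without drug
    "g2": {"pictilisib": "control", "trametinib": "driver",    # PI3K driver, cross-resistant
           "dabrafenib+cetuximab": "driver", "sotorasib": "driver"},
}
classifications = {
    drug: [
        VariantClassification(
            guide_id=g, drug=drug, variant_class=calls[g].get(drug, "control"),
            is_resistance_hit=calls[g].get(drug, "control")
            in {"drug_addiction", "canonical_resistance", "driver"},
            z_drug=3.0,
        )
        for g in calls
    ]
    for drug in DRUGS
}

m = build_map(classifications, genotypes, library)
print("variant x drug map:")
print(m.table.to_string())

for variant in m.table.index:
    s = suggest_alternatives(m, variant)
    note = "  [drug-holiday candidate]" if s.drug_holiday_candidate else ""
    print(f"\n{variant}: alternatives -> {', '.join(s.drugs) or '(none)'}{note}")

curated = [
    CuratedVariant("MAP2K1", 115, "L115P", "trametinib", "resistance"),
    CuratedVariant("MAP2K2", 134, "Y134H", "trametinib", "resistance"),
    CuratedVariant("PIK3CA", 545, "E545K", "sotorasib", "resistance"),
    CuratedVariant("MAP2K1", 115, "L115P", "sotorasib", "resistance"),
]
res = concordance(m, curated)
print(
    f"\nconcordance with the curated list: {res.n_matched}/{res.n_reachable} reachable "
    f"entries ({100 * res.fraction:.1f}%); novel screen effects: {res.novel}"
)
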