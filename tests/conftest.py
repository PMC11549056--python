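import numpy as np
import pandas as pd
import pytest

from bescan.io import CountMatrix, GuideRecord, SampleMeta


def make_library(spec: dict[str, int], editor: str = "ABE") -> list[GuideRecord]:
    """Build a library with the given {category: n} composition."""
    rng = np.random.default_rng(7)
    records, i = [], 0
    for category, n in spec.items():
        for _ in range(n):
            if category == "targeting":
                gene = "GENE01"
            elif category.endswith("_splice"):
                gene = f"SPL{i:04d}"
            else:
                gene = None
            records.append(
                GuideRecord(
                    guide_id=f"g{i:04d}",
                    protospacer="".join(rng.choice(list("ACGT"), size=20)),
                    pam="AGG",
                    gene=gene,
                    category=category,
                    editor=editor,
                )
            )
            i += 1
    return records


def make_counts(
    guides: list[str],
    columns: dict[str, list[int]],
    arms: dict[str, tuple[str, int, str | None]],
) -> CountMatrix:
    """CountMatrix from explicit columns; arms maps sample_id -> (arm, rep, drug)."""
    samples = [
        SampleMeta(sid, arm, rep, "HT-29", "ABE", drug)
        for sid, (arm, rep, drug) in arms.items()
    ]
    df = pd.DataFrame(columns, index=pd.Index(guides, name="guide_id"))
    return CountMatrix(counts=df[list(arms)], samples=samples)


@pytest.fixture
def small_screen():
    """8 guides x 5 samples with plasmid, t0 and two-replicate arms."""
    guides = [f"g{i}" for i in range(8)]
    rng = np.random.default_rng(11)
    cols = {
        "plasmid": list(rng.integers(200, 800, size=8)),
        "t0_r1": list(rng.integers(200, 800, size=8)),
        "control_r1": list(rng.integers(200, 800, size=8)),
        "control_r2": list(rng.integers(200, 800, size=8)),
        "drug_r1": list(rng.integers(200, 800, size=8)),
        "drug_r2": list(rng.integers(200, 800, size=8)),
    }
    arms = {
        "plasmid": ("plasmid", 1, None),
        "t0_r1": ("t0", 1, None),
        "control_r1": ("control", 1, None),
        "control_r2": ("control", 2, None),
        "drug_r1": ("drug", 1, "trametinib"),
        "drug_r2": ("drug", 2, "trametinib"),
    }
    counts = make_counts(guides, cols, arms)
    library = [
        GuideRecord(
            guide_id=g,
            protospacer="ACGT" * 5,
            pam="AGG",
            gene="GENE01",
            category="targeting",
            editor="ABE",
        )
        for g in guides
    ]
    return library, counts
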