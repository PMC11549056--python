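"""Variant-class calling, empirical null, depletion QC and census."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bescan.classify import (
    ClassThresholds,
    VariantClassification,
    class_census,
    classify,
    classify_guide,
    empirical_significance,
    essential_depletion_qc,
)
from bescan.errors import BescanError
from bescan.quant import ScoreTable
from conftest import make_library


def make_score_table(z: dict[str, float], reps: dict[str, tuple], label="cmp") -> ScoreTable:
    guides = list(z)
    df = pd.DataFrame(index=pd.Index(guides, name="guide_id"))
    df["rpm_condition"] = 100.0
    df["rpm_baseline"] = 100.0
    df["l2fc"] = [z[g] for g in guides]
    df["z"] = [z[g] for g in guides]
    for i in range(2):
        df[f"l2fc_rep_{i + 1}"] = [reps[g][i] for g in guides]
        df[f"z_rep_{i + 1}"] = [reps[g][i] for g in guides]
    for flag in ("multi_mapping", "low_count", "replicate_discordant", "excluded"):
        df[flag] = False
    return ScoreTable(table=df, label=label, mean_l2fc=0.0, sd_l2fc=1.0, rep_labels=["1", "2"])


class TestClassifyGuide:
    TH = ClassThresholds()

    @pytest.mark.parametrize(
        "z_d,reps_d,z_c,reps_c,expected",
        [
            (2.5, (1.2, 1.3), 0.1, (0.2, 0.0), "canonical_resistance"),
            (2.2, (1.1, 1.5), -2.5, (-1.5, -1.2), "drug_addiction"),
            (2.3, (1.4, 1.2), 2.4, (1.3, 1.1), "driver"),
            (-2.4, (-1.3, -1.2), -0.5, (-0.4, -0.3), "sensitizing"),
            (2.5, (0.9, 1.3), 0.0, (0.0, 0.0), "control"),  # replicate criterion fails
            (2.0, (1.5, 1.5), 0.0, (0.0, 0.0), "control"),  # strict inequality at 2
            (-2.0, (-1.5, -1.5), 0.0, (0.0, 0.0), "control"),  # strict at -2
        ],
    )
    def test_threshold_rules(self, z_d, reps_d, z_c, reps_c, expected):
        cls, hit, _ = classify_guide(z_d, reps_d, z_c, reps_c, self.TH)
        assert cls == expected
        assert hit == (expected in {"canonical_resistance", "drug_addiction", "driver"})

    def test_exhaustive_truth_table(self):
        """Agreement with a literal restatement of the rules over all sign patterns.

        z values sweep {0, +/-1.5, +/-2.5} for the drug and control averages;
        replicates are either consistent with the average or have one weak
        replicate at magnitude 0.9 (below the per-replicate threshold).
        """

        def oracle(zd, rd, zc, rc):
            hit = zd > 2 and all(r > 1 for r in rd)
            if hit and zc < -2 and all(r < -1 for r in rc):
                return "drug_addiction"
            if hit and zc > 2 and all(r > 1 for r in rc):
                return "driver"
            if hit:
                return "canonical_resistance"
            if (
                zd < -2
                and all(r < -1 for r in rd)
                and zc > -2
                and all(r > -1 for r in rc)
            ):
                return "sensitizing"
            return "control"

        magnitudes = [0.0, 1.5, 2.5, -1.5, -2.5]

        def rep_patterns(z):
            yield (z, z)
            weak = 0.9 if z >= 0 else -0.9
            yield (z, weak)

        seen = set()
        for zd, zc in itertools.product(magnitudes, magnitudes):
            for rd in rep_patterns(zd):
                for rc in rep_patterns(zc):
                    got, _, _ = classify_guide(zd, rd, zc, rc, self.TH)
                    assert got == oracle(zd, rd, zc, rc), (zd, rd, zc, rc)
                    seen.add(got)
        assert seen == {
            "drug_addiction", "canonical_resistance", "driver", "sensitizing", "control"
        }

    def test_monotone_in_drug_z(self):
        """Raising z_drug in lockstep never turns a control call sensitizing."""
        for z in np.linspace(0, 4, 41):
            cls, _, _ = classify_guide(z, (z, z), 0.0, (0.0, 0.0), self.TH)
            assert cls in {"control", "canonical_resistance"}
            if z > 2:
                assert cls == "canonical_resistance"


class TestClassify:
    def test_partition_one_class_per_guide(self):
        z_d = {"a": 2.5, "b": -2.5, "c": 0.0}
        reps_d = {"a": (1.5, 1.5), "b": (-1.5, -1.5), "c": (0.0, 0.0)}
        z_c = {"a": 0.0, "b": 0.0, "c": 0.0}
        reps_c = {g: (0.0, 0.0) for g in z_c}
        out = classify(make_score_table(z_d, reps_d), make_score_table(z_c, reps_c))
        assert [c.variant_class for c in out] == ["canonical_resistance", "sensitizing", "control"]
        assert len(out) == 3  # every retained guide classified exactly once

    def test_mismatched_guide_sets_error(self):
        t1 = make_score_table({"a": 0.0, "b": 0.0}, {"a": (0, 0), "b": (0, 0)})
        t2 = make_score_table({"a": 0.0}, {"a": (0, 0)})
        with pytest.raises(BescanError, match="different retained guides"):
            classify(t1, t2)

    def test_significance_gate_demotes_hits(self):
        z_d = {f"g{i}": 0.0 for i in range(3)}
        z_d["hit"] = 2.5
        reps_d = {g: (z, z) for g, z in z_d.items()}
        z_c = {g: 0.0 for g in z_d}
        reps_c = {g: (0.0, 0.0) for g in z_d}
        sig_fail = pd.DataFrame(
            {"p_enrich": [0.5], "fdr_enrich": [0.9], "p_deplete": [0.9], "fdr_deplete": [0.9]},
            index=pd.Index(["hit"], name="guide_id"),
        )
        out = classify(
            make_score_table(z_d, reps_d), make_score_table(z_c, reps_c),
            significance=sig_fail,
        )
        assert {c.guide_id: c.variant_class for c in out}["hit"] == "control"
        sig_pass = sig_fail.copy()
        sig_pass.loc["hit"] = [0.002, 0.01, 0.9, 0.9]
        out = classify(
            make_score_table(z_d, reps_d), make_score_table(z_c, reps_c),
            significance=sig_pass,
        )
        assert {c.guide_id: c.variant_class for c in out}["hit"] == "canonical_resistance"


class TestEmpiricalSignificance:
    def _tables(self, n_ctrl=400, z_target=10.0):
        rng = np.random.default_rng(0)
        z = {f"ctrl{i}": float(v) for i, v in enumerate(rng.normal(size=n_ctrl))}
        z["t1"] = z_target
        reps = {g: (v, v) for g, v in z.items()}
        st_ = make_score_table(z, reps)
        lib = make_library({"nontargeting": n_ctrl, "targeting": 1})
        # align names: library ids g0000.. -> rename score table index
        mapping = dict(zip(list(z), [r.guide_id for r in lib[:-1]] + [lib[-1].guide_id]))
        st_.table.index = [mapping[g] for g in st_.table.index]
        return st_, lib

    def test_rank_formula_extreme(self):
        st_, lib = self._tables()
        sig = empirical_significance(st_, lib)
        target = [r.guide_id for r in lib if r.category == "targeting"][0]
        assert sig.at[target, "p_enrich"] == pytest.approx(1 / 401, abs=1e-12)

    def test_median_z_is_half(self):
        st_, lib = self._tables(z_target=0.0)
        sig = empirical_significance(st_, lib)
        target = [r.guide_id for r in lib if r.category == "targeting"][0]
        assert sig.at[target, "p_enrich"] == pytest.approx(0.5, abs=0.05)

    def test_too_few_controls_reports_count(self):
        st_, lib = self._tables(n_ctrl=10)
        with pytest.raises(BescanError, match="got 10"):
            empirical_significance(st_, lib)

    def test_bh_textbook_example(self):
        # independent BH arithmetic: q_i = min_{j>=i} p_j * n / j
        p = np.array([0.001, 0.02, 0.9])
        q = stats.false_discovery_control(p, method="bh")
        assert np.allclose(q, [0.003, 0.03, 0.9], atol=1e-12)


class TestDepletionQC:
    def _table(self, nt_vals, ess_vals):
        z = {f"nt{i}": v for i, v in enumerate(nt_vals)}
        z.update({f"es{i}": v for i, v in enumerate(ess_vals)})
        reps = {g: (v, v) for g, v in z.items()}
        st_ = make_score_table(z, reps)
        lib = make_library({"nontargeting": len(nt_vals), "essential_splice": len(ess_vals)})
        ids = [r.guide_id for r in lib]
        st_.table.index = ids
        return st_, lib

    def test_separated_groups_pass(self):
        rng = np.random.default_rng(42)
        st_, lib = self._table(rng.normal(0, 1, 100), rng.normal(-2, 1, 100))
        res = essential_depletion_qc(st_, lib)
        assert res.p < 1e-10 and res.passed

    def test_identical_groups_null(self):
        st_, lib = self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = essential_depletion_qc(st_, lib)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)
        assert not res.passed

    def test_wrong_direction_fails(self):
        rng = np.random.default_rng(43)
        st_, lib = self._table(rng.normal(-2, 1, 100), rng.normal(0, 1, 100))
        res = essential_depletion_qc(st_, lib)
        assert res.p < 1e-10 and not res.passed  # essential mean ABOVE NT mean


class TestCensus:
    def _cls(self, guide, klass, drug="trametinib"):
        return VariantClassification(
            guide_id=guide, drug=drug, variant_class=klass,
            is_resistance_hit=klass in {"drug_addiction", "canonical_resistance", "driver"},
        )

    def test_planted_counts_and_zero_contamination(self):
        lib = make_library({"targeting": 200, "nontargeting": 5})
        targeting = [r.guide_id for r in lib if r.category == "targeting"]
        planted = (
            [("drug_addiction", 10), ("canonical_resistance", 30), ("driver", 24),
             ("sensitizing", 111)]
        )
        out, i = [], 0
        for klass, n in planted:
            for _ in range(n):
                out.append(self._cls(targeting[i], klass))
                i += 1
        out += [self._cls(g, "control") for g in targeting[i:]]
        census = class_census(out, lib)
        row = census.iloc[0]
        assert (
            row.drug_addiction, row.canonical_resistance, row.driver, row.sensitizing
        ) == (10, 30, 24, 111)
        assert row.total_hits == 175 and row.control_contamination == 0

    def test_no_hits_all_zero(self):
        lib = make_library({"targeting": 3})
        out = [self._cls(r.guide_id, "control") for r in lib]
        row = class_census(out, lib).iloc[0]
        assert row.total_hits == 0 and row.control_contamination == 0

    def test_forced_nt_hit_counts_as_contamination(self):
        lib = make_library({"targeting": 2, "nontargeting": 1})
        nt = [r.guide_id for r in lib if r.category == "nontargeting"][0]
        out = [self._cls(nt, "canonical_resistance")]
        out += [self._cls(r.guide_id, "control") for r in lib if r.guide_id != nt]
        assert class_census(out, lib).iloc[0].control_contamination == 1
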