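import numpy as np
import pytest

from relapse_evo.actionability_report import (
    ActionabilityRecord,
    ClinicalRecord,
    assign_subtype,
    cohort_actionability_summary,
    correlate,
    default_actionability_table,
    default_clinical_table,
    default_rules,
    flag_actionable,
    paired_comparison,
    read_actionability_table,
    summarize_clinical,
    write_actionability_table,
)
from relapse_evo.io_formats import FormatError

from oracles import oracle_signed_rank_p


class TestClinicalFixture:
    def test_ten_patients(self):
        records = default_clinical_table()
        assert len(records) == 10
        assert [r.patient_id for r in records] == [f"BC{i:02d}" for i in range(1, 11)]

    def test_median_age(self):
        summary = summarize_clinical(default_clinical_table())
        assert summary["median_age"] == 47
        assert summary["age_range"] == (27, 72)

    def test_subtype_fractions(self):
        summary = summarize_clinical(default_clinical_table())
        fr = summary["subtype_fractions_pct"]
        assert fr["Luminal A-like"] == 50.0
        assert fr["Luminal B-like"] == 10.0
        assert fr["HER2-enriched"] == 10.0
        assert fr["Triple negative"] == 10.0
        assert fr["missing"] == 20.0

    def test_grade2_fraction_among_graded(self):
        summary = summarize_clinical(default_clinical_table())
        assert summary["grade2_fraction_pct"] == 77.8
        assert summary["n_graded"] == 9

    def test_relapse_interval_range(self):
        summary = summarize_clinical(default_clinical_table())
        assert summary["relapse_months_range"] == (6.0, 107.0)

    def test_all_missing_grade(self):
        records = [
            ClinicalRecord("p1", 50, None, "+", "+", "-", None, None),
            ClinicalRecord("p2", 60, None, "+", "-", "-", None, None),
        ]
        assert summarize_clinical(records)["grade2_fraction_pct"] is None


class TestSubtypeLegend:
    def test_legend_rules(self):
        base = dict(grade=None, subtype_label=None, relapse_months=None)
        assert assign_subtype(ClinicalRecord("p", 50, er="+", pr="-", her2="-", **base)) == "Luminal A-like"
        assert assign_subtype(ClinicalRecord("p", 50, er="-", pr="+", her2="+", **base)) == "Luminal B-like"
        assert assign_subtype(ClinicalRecord("p", 50, er="-", pr="-", her2="+", **base)) == "HER2-enriched"
        assert assign_subtype(ClinicalRecord("p", 50, er="-", pr="-", her2="-", **base)) == "Triple negative"

    def test_missing_her2_gives_missing_subtype(self):
        rec = ClinicalRecord("p", 50, None, "-", "-", None, None, None)
        assert assign_subtype(rec) is None

    def test_fixture_labels_consistent_with_legend(self):
        for rec in default_clinical_table():
            derived = assign_subtype(rec)
            if rec.subtype_label is not None:
                assert derived == rec.subtype_label


class TestActionabilityFixture:
    def test_thirteen_rows(self):
        records = default_actionability_table()
        assert len(records) == 13

    def test_cohort_summary_is_45_pct(self):
        records = default_actionability_table()
        assert cohort_actionability_summary(records, n_lesions=20) == pytest.approx(45.0)

    def test_three_hrd_relapse_lesions(self):
        records = default_actionability_table()
        hrd_relapse = {
            r.sample_id for r in records if r.biomarker == "HRD" and r.lesion == "relapse"
        }
        assert len(hrd_relapse) == 3

    def test_bc03_brca2_ccf(self):
        (row,) = [
            r
            for r in default_actionability_table()
            if r.sample_id == "BC03" and "BRCA2" in r.alteration
        ]
        assert row.ccf == pytest.approx(0.943)
        assert row.classification == "Branch"

    def test_hrd_rows_carry_na(self):
        for r in default_actionability_table():
            if r.biomarker == "HRD":
                assert r.clone is None and r.ccf is None and r.classification is None

    def test_hrd_record_with_clone_rejected(self):
        with pytest.raises(FormatError, match="N/A"):
            ActionabilityRecord("s", "relapse", "HRD", "x", "Clone 1", 0.5, "Trunk")


class TestFlagActionable:
    def test_rule_hit_and_hrd_record(self):
        records = flag_actionable(
            "BC05",
            "relapse",
            [
                {"gene": "PIK3CA", "kind": "mutation", "clone": "Clone 1", "ccf": 1.0, "classification": "Trunk"},
                {"gene": "GATA3", "kind": "mutation", "clone": "Clone 2", "ccf": 0.5, "classification": "Branch"},
            ],
            default_rules(),
            hrd_phenotype=True,
        )
        assert len(records) == 2  # GATA3 has no rule
        assert records[0].alteration == "PIK3CA mutation"
        assert records[1].biomarker == "HRD"
        assert records[1].alteration == "(HRD score >= 42)"

    def test_biallelic_brca_description(self):
        (rec,) = flag_actionable(
            "BC07", "primary", [], default_rules(), True, biallelic_brca_gene="BRCA2"
        )
        assert rec.alteration == "Bi-allelic BRCA2"

    def test_empty_inputs(self):
        import pandas as pd

        empty_rules = pd.DataFrame(columns=["gene", "alteration", "level"])
        assert flag_actionable("s", "primary", [], empty_rules, False) == []

    def test_unknown_rule_gene_warns(self):
        with pytest.warns(UserWarning, match="unknown gene"):
            flag_actionable(
                "s", "primary", [], default_rules(), False, known_genes=frozenset({"TP53"})
            )

    def test_table2_closure(self, tmp_path):
        """Reconstruct inputs from the fixture, re-flag, re-emit: identical."""
        fixture = default_actionability_table()
        rules = default_rules()
        regenerated = []
        lesions = sorted({(r.sample_id, r.lesion) for r in fixture})
        for sample_id, lesion in lesions:
            rows = [r for r in fixture if (r.sample_id, r.lesion) == (sample_id, lesion)]
            alterations = [
                {
                    "gene": r.alteration.split()[0],
                    "kind": r.alteration.split()[1],
                    "clone": r.clone,
                    "ccf": r.ccf,
                    "classification": r.classification,
                }
                for r in rows
                if r.biomarker == "OncoKB"
            ]
            hrd_rows = [r for r in rows if r.biomarker == "HRD"]
            brca = None
            if hrd_rows and hrd_rows[0].alteration.startswith("Bi-allelic"):
                brca = hrd_rows[0].alteration.split()[-1]
            regenerated.extend(
                flag_actionable(
                    sample_id, lesion, alterations, rules, bool(hrd_rows), brca
                )
            )
        p1, p2 = tmp_path / "fixture.tsv", tmp_path / "regen.tsv"
        write_actionability_table(sorted(fixture, key=lambda r: (r.sample_id, r.lesion, r.biomarker, r.alteration)), p1)
        write_actionability_table(sorted(regenerated, key=lambda r: (r.sample_id, r.lesion, r.biomarker, r.alteration)), p2)
        assert p1.read_text() == p2.read_text()
        back = read_actionability_table(p2)
        assert len(back) == 13

    def test_summary_edge_cases(self):
        assert cohort_actionability_summary([], 20) == 0.0
        records = [
            ActionabilityRecord(f"s{i}", "primary", "HRD", "x", None, None, None)
            for i in range(4)
        ]
        assert cohort_actionability_summary(records, 4) == 100.0
        with pytest.raises(ValueError):
            cohort_actionability_summary([], 0)


class TestPairedComparison:
    def test_uniform_shift_minimal_p(self):
        primary = list(range(10))
        relapse = [x + 1 for x in primary]
        w, p = paired_comparison(primary, relapse, alternative="greater")
        assert p == pytest.approx(1 / 1024)
        assert p == pytest.approx(oracle_signed_rank_p(np.array(relapse) - np.array(primary)))

    def test_identical_vectors_error(self):
        with pytest.raises(ValueError, match="zero"):
            paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_enumeration_oracle_random(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            primary = rng.normal(0, 1, n)
            relapse = primary + rng.normal(0.3, 1, n)
            if np.any(relapse == primary):
                continue
            _, p = paired_comparison(primary, relapse, alternative="greater")
            assert p == pytest.approx(
                oracle_signed_rank_p(relapse - primary, "greater")
            )

    def test_antisymmetry_against_oracle(self):
        rng = np.random.default_rng(22)
        primary = rng.normal(0, 1, 8)
        relapse = primary + rng.normal(0, 1, 8)
        _, p_greater = paired_comparison(primary, relapse, "greater")
        _, p_less = paired_comparison(primary, relapse, "less")
        # both one-sided tails overlap exactly on the point mass at W_obs
        assert p_greater == pytest.approx(oracle_signed_rank_p(relapse - primary, "greater"))
        assert p_less == pytest.approx(oracle_signed_rank_p(relapse - primary, "less"))
        assert p_greater + p_less >= 1.0 - 1e-12

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(23)
        primary = rng.normal(0, 1, 30)
        relapse = primary + np.abs(rng.normal(1, 0.1, 30))
        _, p = paired_comparison(primary, relapse, "greater")
        assert p < 1e-4

    def test_too_short(self):
        with pytest.raises(ValueError, match="3 pairs"):
            paired_comparison([1.0], [2.0])


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_near_zero(self):
        rng = np.random.default_rng(24)
        x, y = rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)
        r, _ = correlate(x, y)
        assert abs(r) < 0.1

    def test_affine_invariance(self):
        rng = np.random.default_rng(25)
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 0.5, 50)
        r1, _ = correlate(x, y)
        r2, _ = correlate(3 * x + 7, -0.0 + 10 * y)
        assert r1 == pytest.approx(r2)
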