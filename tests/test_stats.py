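"""Cohort statistics against closed-form and enumeration oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from pairconcord.concordance import classify_pair
from pairconcord.model import Cohort, PatientPair, SampleRole, VariantClass
from pairconcord import stats as cstats
from tests.conftest import make_variant


def small_cohort(gene_patients, n_patients=10, scope=SampleRole.PRIMARY):
    """Cohort with given {gene: [patient indices]} mutated in the scoped sample."""
    patients = [
        PatientPair(
            patient_id=f"P{i}",
            primary_sample_id=f"P{i}-P",
            metastatic_sample_id=f"P{i}-M",
        )
        for i in range(n_patients)
    ]
    variants = []
    pos = 1
    for gene, idxs in gene_patients.items():
        for i in idxs:
            variants.append(
                make_variant(gene=gene, patient_id=f"P{i}", sample_role=scope, pos=pos)
            )
            pos += 1
    return Cohort(variants=variants, patients=patients)


class TestGeneFrequencies:
    def test_patient_counted_once_despite_two_variants(self):
        cohort = small_cohort({"APC": [0, 0, 1]})
        table = cstats.gene_frequencies(cohort, SampleRole.PRIMARY)
        assert table.rows["APC"] == (2, 0.2)

    def test_denominator_is_scoped_patients(self):
        cohort = small_cohort({"APC": [0]}, n_patients=4)
        cohort.patients[3].metastatic_sample_id = None  # primary-only singleton
        table = cstats.gene_frequencies(cohort, SampleRole.METASTATIC)
        assert table.n_patients == 3

    def test_empty_scope_rejected(self):
        cohort = small_cohort({"APC": [0]}, n_patients=2)
        for p in cohort.patients:
            p.metastatic_sample_id = None
        with pytest.raises(ValueError):
            cstats.gene_frequencies(cohort, SampleRole.METASTATIC)

    def test_ranked_breaks_ties_alphabetically(self):
        cohort = small_cohort({"TP53": [0], "APC": [1], "KRAS": [0, 1]})
        assert [g for g, _, _ in cstats.gene_frequencies(cohort, SampleRole.PRIMARY).ranked()] == [
            "KRAS",
            "APC",
            "TP53",
        ]


def ztest_oracle(x1, n1, x2, n2):
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    return 2 * sps.norm.sf(abs(p1 - p2) / se)


def freq_table(name, n, rows):
    return cstats.GeneFrequencyTable(name, n, {g: (x, x / n) for g, x in rows.items()})


class TestCompareFrequencies:
    def test_identical_tables_give_p_one(self):
        t = freq_table("a", 100, {"APC": 60, "TP53": 50})
        out = cstats.compare_frequencies(t, t)
        assert all(p == 1.0 for _, _, p in out.values())

    def test_matches_ztest_oracle_on_reference_counts(self):
        # AMER1-style counts: 19/223 vs 49/1134
        ta = freq_table("tcga", 223, {"AMER1": 19})
        tb = freq_table("mskcc", 1134, {"AMER1": 49})
        (_, _, p) = cstats.compare_frequencies(ta, tb)["AMER1"]
        assert p == pytest.approx(ztest_oracle(19, 223, 49, 1134), rel=1e-9)

    def test_tp53_reference_cohorts_strongly_differ(self):
        ta = freq_table("tcga", 223, {"TP53": 120})
        tb = freq_table("mskcc", 1134, {"TP53": 818})
        (fa, fb, p) = cstats.compare_frequencies(ta, tb)["TP53"]
        assert round(fa, 2) == 0.54 and round(fb, 2) == 0.72
        assert p < 0.0001

    def test_symmetry(self):
        ta = freq_table("a", 100, {"APC": 30})
        tb = freq_table("b", 200, {"APC": 90})
        (fa, fb, p) = cstats.compare_frequencies(ta, tb)["APC"]
        (fb2, fa2, p2) = cstats.compare_frequencies(tb, ta)["APC"]
        assert (fa, fb) == (fa2, fb2)
        assert p == pytest.approx(p2, rel=1e-12)

    def test_absent_gene_policy(self):
        ta = freq_table("a", 100, {"APC": 30, "AMER1": 9})
        tb = freq_table("b", 100, {"APC": 35})
        assert "AMER1" in cstats.compare_frequencies(ta, tb, assume_zero=True)
        assert "AMER1" not in cstats.compare_frequencies(ta, tb, assume_zero=False)


def vaf_classifications(pairs_vafs, gene="TP53"):
    out = []
    for i, (pv, mv) in enumerate(pairs_vafs):
        prim = make_variant(gene=gene, patient_id=f"P{i}", pos=100 + i, vaf=pv)
        met = make_variant(
            gene=gene, patient_id=f"P{i}", pos=100 + i, vaf=mv, sample_role=SampleRole.METASTATIC
        )
        out.append(classify_pair([prim], [met], patient_id=f"P{i}"))
    return out


class TestPairedVafTest:
    def test_equal_vafs_give_p_one(self):
        cmp = cstats.paired_vaf_test(vaf_classifications([(0.2, 0.2), (0.3, 0.3)]), "TP53")
        assert cmp.p_value == 1.0 and cmp.mean_shift == 0.0

    def test_constant_nonzero_difference_edge(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            cmp = cstats.paired_vaf_test(
                vaf_classifications([(0.1, 0.2)] * 5), "TP53"
            )
        assert 0 < cmp.p_value <= np.finfo(float).eps
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(3)
        pv = rng.uniform(0.1, 0.4, size=12)
        mv = np.clip(pv + rng.normal(0.05, 0.05, size=12), 0, 1)
        cmp = cstats.paired_vaf_test(vaf_classifications(list(zip(pv, mv))), "TP53")
        d = mv - pv
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        assert cmp.p_value == pytest.approx(p, rel=1e-9)
        assert cmp.n_variant_pairs == 12

    def test_too_few_pairs_raises_naming_gene(self):
        with pytest.raises(ValueError, match="KRAS"):
            cstats.paired_vaf_test(vaf_classifications([(0.2, 0.3)]), "KRAS")


class TestComposition:
    def test_all_nonsense(self):
        vs = [
            make_variant(pos=i, variant_class=VariantClass.NONSENSE_SNV) for i in range(1, 4)
        ]
        comp = cstats.variant_type_composition(vs)
        assert comp["all"] == {VariantClass.NONSENSE_SNV: 1.0}

    def test_truncating_mixture_fractions(self):
        vs = (
            [make_variant(gene="APC", pos=i, variant_class=VariantClass.NONSENSE_SNV) for i in range(1, 73)]
            + [make_variant(gene="APC", pos=i, ref="A", alt="-", variant_class=VariantClass.INDEL) for i in range(100, 126)]
            + [make_variant(gene="APC", pos=i, variant_class=VariantClass.SPLICE_SITE) for i in range(200, 202)]
        )
        comp = cstats.variant_type_composition(vs, by_gene=True)["APC"]
        assert comp[VariantClass.NONSENSE_SNV] == pytest.approx(0.72)
        assert comp[VariantClass.INDEL] == pytest.approx(0.26)
        assert comp[VariantClass.SPLICE_SITE] == pytest.approx(0.02)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_scope_rejected(self):
        with pytest.raises(ValueError):
            cstats.variant_type_composition([])

    def test_compare_composition_matches_ztest_oracle(self):
        a = [make_variant(pos=i + 1, ref="A", alt="-", variant_class=VariantClass.INDEL) for i in range(41)] + [
            make_variant(pos=i) for i in range(100, 159)
        ]
        b = [make_variant(pos=i, ref="A", alt="-", variant_class=VariantClass.INDEL) for i in range(200, 226)] + [
            make_variant(pos=i) for i in range(300, 374)
        ]
        fa, fb, p = cstats.compare_composition(a, b, VariantClass.INDEL)
        assert fa == pytest.approx(0.41)
        assert fb == pytest.approx(0.26)
        assert p == pytest.approx(ztest_oracle(41, 100, 26, 100), rel=1e-9)


class TestHotspots:
    def test_single_variant(self):
        vs = [make_variant(gene="PIK3CA", protein_change="p.H1047R")]
        assert cstats.hotspot_table(vs, "PIK3CA") == {1047: (1, 1.0)}

    def test_hotspot_fractions(self):
        vs = [make_variant(gene="TP53", pos=i + 1, protein_change="p.R175H") for i in range(16)] + [
            make_variant(gene="TP53", pos=100 + i, protein_change=f"p.G{200 + i}V") for i in range(84)
        ]
        table = cstats.hotspot_table(vs, "TP53")
        assert table[175] == (16, pytest.approx(0.16))

    def test_three_letter_hgvs_and_fs_parse(self):
        assert cstats.protein_position("p.His1047Arg") == 1047
        assert cstats.protein_position("p.K123fs") == 123
        assert cstats.protein_position("p.R213*") == 213

    def test_malformed_protein_goes_to_unknown_bucket(self):
        vs = [
            make_variant(gene="TP53", pos=1, protein_change="p.R175H"),
            make_variant(gene="TP53", pos=2, protein_change="garbled"),
        ]
        table = cstats.hotspot_table(vs, "TP53")
        assert table[175] == (1, 1.0)
        assert table["unknown"][0] == 1


def fisher_oracle(table):
    """Exhaustive hypergeometric-sum oracle for the two-sided Fisher test."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    observed = pmf[support == a][0]
    return float(pmf[pmf <= observed * (1 + 1e-12)].sum())


class TestAssociations:
    def test_fisher_on_sparse_table_matches_oracle(self):
        table = np.array([[3, 99], [4, 12]])
        test, p = cstats.contingency_test(table)
        assert test == "fisher"
        assert p == pytest.approx(fisher_oracle(table), rel=1e-9)
        assert p == pytest.approx(0.01, abs=0.005)

    def test_dense_table_uses_chi_square(self):
        test, p = cstats.contingency_test(np.array([[40, 60], [60, 40]]))
        assert test == "chi2"
        chi2 = sps.chi2_contingency([[40, 60], [60, 40]], correction=False)
        assert p == pytest.approx(chi2.pvalue, rel=1e-12)

    def test_zero_margin_gives_p_one(self):
        assert cstats.contingency_test(np.array([[0, 0], [5, 7]]))[1] == 1.0

    def test_single_level_covariate_skipped(self, caplog):
        import logging

        cohort = small_cohort({"APC": [0, 1]})
        for p in cohort.patients:
            p.clinical["grade"] = "2"
        with caplog.at_level(logging.WARNING):
            results = cstats.association_tests(cohort, ["APC"], ["grade"])
        assert results == []
        assert any("grade" in r.message for r in caplog.records)

    def test_contingency_counts_patients(self):
        cohort = small_cohort({"SMAD4": [0, 1, 2]}, n_patients=8)
        for i, p in enumerate(cohort.patients):
            p.clinical["msi"] = "MSI_H" if i < 2 else "MSS"
        (res,) = cstats.association_tests(cohort, ["SMAD4"], ["msi"])
        assert res.table.sum() == 8
        assert res.table[1].sum() == 3  # mutated row


def survival_cohort(times_events_by_status, recurrence=None):
    patients, variants = [], []
    i = 0
    for status, rows in times_events_by_status.items():
        for t, e in rows:
            pid = f"P{i}"
            patients.append(
                PatientPair(
                    patient_id=pid,
                    primary_sample_id=f"{pid}-P",
                    metastatic_sample_id=f"{pid}-M",
                    os_days=t,
                    os_event=e,
                    recurrence_days=None if recurrence is None else recurrence[i],
                )
            )
            if status == "mutant":
                variants.append(make_variant(gene="FBXW7", patient_id=pid, pos=500 + i))
            i += 1
    return Cohort(variants=variants, patients=patients)


class TestSurvival:
    def test_km_matches_hand_computed_product_limit(self):
        # deaths at t=1 and t=2, censor at 1.5: S(1)=2/3, S(2)=2/3*(1-1/1)=0
        cohort = survival_cohort({"wild": [(1, True), (1.5, False), (2, True)]})
        s = cstats.survival_summary(cohort, "FBXW7")
        times, surv = s.km_by_status["wild_type"]
        by_t = dict(zip(times, surv))
        assert by_t[1.0] == pytest.approx(2 / 3)
        assert by_t[2.0] == pytest.approx(0.0)

    def test_group_without_deaths_has_flat_curve(self):
        cohort = survival_cohort(
            {"mutant": [(5, False), (8, False)], "wild": [(1, True), (2, True), (3, False)]}
        )
        s = cstats.survival_summary(cohort, "FBXW7")
        _, surv = s.km_by_status["mutant"]
        assert (surv == 1.0).all()
        assert s.logrank_p is not None

    def test_too_few_events_rejected(self):
        cohort = survival_cohort({"wild": [(1, True), (2, False)]})
        with pytest.raises(ValueError, match="events"):
            cstats.survival_summary(cohort, "FBXW7")

    def test_recurrence_ranksum_matches_scipy_oracle(self):
        rec = [100.0, 150.0, 120.0, 300.0, 280.0, 320.0, 290.0]
        cohort = survival_cohort(
            {"mutant": [(500, True)] * 3, "wild": [(600, True)] * 4}, recurrence=rec
        )
        s = cstats.survival_summary(cohort, "FBXW7")
        expected = sps.mannwhitneyu(rec[:3], rec[3:], alternative="two-sided").pvalue
        assert s.recurrence_p == pytest.approx(float(expected), rel=1e-12)
        assert s.median_recurrence_by_status["mutant"] == 120.0

    def test_logrank_type_one_error_calibrated_under_equal_hazards(self):
        # mutation status independent of survival: the log-rank emitted by
        # survival_summary should reject at ~ the nominal 5% level
        rng = np.random.default_rng(29)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            t = rng.exponential(300, size=60)
            c = rng.uniform(50, 900, size=60)
            mutant = rng.random(60) < 0.5
            groups = {"mutant": [], "wild": []}
            for ti, ci, m in zip(t, c, mutant):
                groups["mutant" if m else "wild"].append((min(ti, ci), bool(ti <= ci)))
            if not groups["mutant"] or not groups["wild"]:
                continue
            s = cstats.survival_summary(survival_cohort(groups), "FBXW7")
            rejections += s.logrank_p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
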