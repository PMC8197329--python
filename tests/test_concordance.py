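"""Pair matching and concordance statistics against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from pairconcord.concordance import (
    VariantKey,
    classify_pair,
    concordance_report,
    stratified_concordance_test,
)
from pairconcord.filtering import apply_filter, kept_variants
from pairconcord.model import Cohort, SampleRole
from pairconcord.pipeline import classify_cohort_pairs
from pairconcord.simulate import (
    SimulationParams,
    expected_gene_concordance,
    generate,
)
from tests.conftest import make_variant


def pair_variants(patient_id, primary_positions, metastatic_positions, gene="TP53"):
    prim = [
        make_variant(gene=gene, patient_id=patient_id, pos=p, sample_role=SampleRole.PRIMARY)
        for p in primary_positions
    ]
    met = [
        make_variant(gene=gene, patient_id=patient_id, pos=p, sample_role=SampleRole.METASTATIC)
        for p in metastatic_positions
    ]
    return prim, met


def brute_force_buckets(primary, metastatic):
    """Quadratic-scan oracle for the set-algebra classification."""
    shared, prim_only, met_only = set(), set(), set()
    for v in primary:
        if any(VariantKey.of(v) == VariantKey.of(w) for w in metastatic):
            shared.add(VariantKey.of(v))
        else:
            prim_only.add(VariantKey.of(v))
    for w in metastatic:
        if not any(VariantKey.of(w) == VariantKey.of(v) for v in primary):
            met_only.add(VariantKey.of(w))
    return shared, prim_only, met_only


class TestClassifyPair:
    def test_set_algebra_example(self):
        prim, met = pair_variants("P1", [1, 2], [2, 3])
        cls = classify_pair(prim, met)
        assert [v.pos for (v, _) in cls.shared] == [2]
        assert [v.pos for v in cls.primary_only] == [1]
        assert [v.pos for v in cls.metastatic_only] == [3]

    def test_identical_lists_all_shared(self):
        prim, met = pair_variants("P1", [5, 6, 7], [5, 6, 7])
        cls = classify_pair(prim, met)
        assert cls.n_shared == 3 and cls.n_discordant == 0
        assert cls.concordance == 1.0

    def test_duplicate_key_within_sample_rejected(self):
        prim, _ = pair_variants("P1", [1, 1], [])
        with pytest.raises(ValueError, match="duplicate key"):
            classify_pair(prim, [])

    def test_matches_brute_force_oracle_on_small_cohorts(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n_p, n_m = rng.integers(0, 7, size=2)
            prim, met = pair_variants(
                "P1",
                rng.choice(20, size=n_p, replace=False) + 1,
                rng.choice(20, size=n_m, replace=False) + 1,
            )
            cls = classify_pair(prim, met, patient_id="P1")
            shared, prim_only, met_only = brute_force_buckets(prim, met)
            assert {VariantKey.of(v) for v, _ in cls.shared} == shared
            assert {VariantKey.of(v) for v in cls.primary_only} == prim_only
            assert {VariantKey.of(v) for v in cls.metastatic_only} == met_only

    def test_conservation_every_event_in_exactly_one_bucket(self):
        prim, met = pair_variants("P1", [1, 2, 3], [3, 4])
        cls = classify_pair(prim, met)
        keys = (
            [VariantKey.of(v) for v, _ in cls.shared]
            + [VariantKey.of(v) for v in cls.primary_only]
            + [VariantKey.of(v) for v in cls.metastatic_only]
        )
        assert len(keys) == len(set(keys)) == 4

    def test_symmetry_swapping_samples_swaps_private_buckets(self):
        prim, met = pair_variants("P1", [1, 2, 3], [3, 4])
        fwd = classify_pair(prim, met)
        # swap: feed metastatic variants as "primary" and vice versa
        rev = classify_pair(met, prim)
        assert fwd.n_shared == rev.n_shared
        assert len(fwd.primary_only) == len(rev.metastatic_only)
        assert len(fwd.metastatic_only) == len(rev.primary_only)


class TestConcordanceReport:
    def test_single_pair_single_shared_variant_counting_convention(self):
        prim, met = pair_variants("P1", [1], [1])
        report = concordance_report([classify_pair(prim, met)])
        assert report.mean_pair_concordance == 1.0
        assert report.mean_concordant_per_pair == 2.0
        assert report.mean_discordant_per_pair == 0.0

    def test_marginals_reconcile_with_buckets(self):
        classifications = [
            classify_pair(*pair_variants("P1", [1, 2], [2, 3]), patient_id="P1"),
            classify_pair(*pair_variants("P2", [5], [5]), patient_id="P2"),
            classify_pair(*pair_variants("P3", [], []), patient_id="P3"),
        ]
        report = concordance_report(classifications)
        assert report.n_variants == report.n_shared + report.n_discordant == 4
        assert sum(g.n_total for g in report.per_gene.values()) == report.n_variants
        assert sum(g.n_total for g in report.per_class.values()) == report.n_variants
        # zero-variant pair excluded from the pair mean but counted in n_pairs
        assert report.n_pairs == 3
        assert report.mean_pair_concordance == pytest.approx((1 / 3 + 1.0) / 2)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_report([])

    def test_per_gene_concordance_recovers_generator_parameter(self):
        params = SimulationParams(seed=23)
        res = generate(params)
        kept = kept_variants(apply_filter(res.cohort.variants))
        cohort = Cohort(variants=kept, patients=res.cohort.patients)
        report = concordance_report(classify_cohort_pairs(cohort))
        for gene in ("APC", "TP53", "KRAS"):
            gc = report.per_gene[gene]
            p = expected_gene_concordance(params, gene)
            # exact central binomial interval around the generator setting
            assert sps.binomtest(gc.n_shared, gc.n_total, p).pvalue > 0.01


def ztest_oracle(x1, n1, x2, n2):
    """Independently coded pooled two-proportion z-test."""
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return 2 * sps.norm.sf(abs(z))


def report_from_counts(n_shared, n_primary_only, n_metastatic_only, n_pairs=1):
    """Build a report whose pooled bucket counts are exactly as given."""
    classifications = []
    for i in range(n_pairs):
        take = lambda total: total // n_pairs + (1 if i < total % n_pairs else 0)
        s = take(n_shared)
        po = take(n_primary_only)
        mo = take(n_metastatic_only)
        base = i * 1000 + 1
        prim, met = pair_variants(
            f"P{i}",
            list(range(base, base + s)) + list(range(base + 500, base + 500 + po)),
            list(range(base, base + s)) + list(range(base + 700, base + 700 + mo)),
        )
        classifications.append(classify_pair(prim, met, patient_id=f"P{i}"))
    return concordance_report(classifications)


class TestStratifiedTest:
    def test_identical_proportions_give_p_one(self):
        reports = {
            "synchronous": report_from_counts(90, 5, 5),
            "metachronous": report_from_counts(90, 5, 5),
        }
        props, p = stratified_concordance_test(reports, "concordance")
        assert p == 1.0
        assert props["synchronous"] == props["metachronous"] == 0.9

    def test_matches_hand_coded_ztest_on_92_vs_86_of_100(self):
        reports = {
            "synchronous": report_from_counts(92, 4, 4),
            "metachronous": report_from_counts(86, 7, 7),
        }
        props, p = stratified_concordance_test(reports, "concordance")
        assert props["synchronous"] == pytest.approx(0.92)
        assert p == pytest.approx(ztest_oracle(92, 100, 86, 100), rel=1e-9)

    def test_primary_only_fraction_statistic(self):
        reports = {
            "a": report_from_counts(90, 4, 6),
            "b": report_from_counts(80, 11, 9),
        }
        props, p = stratified_concordance_test(reports, "primary_only_fraction")
        assert props["a"] == pytest.approx(0.04)
        assert props["b"] == pytest.approx(0.11)
        assert p == pytest.approx(ztest_oracle(4, 100, 11, 100), rel=1e-9)

    def test_requires_two_nonempty_strata(self):
        r = report_from_counts(10, 1, 1)
        with pytest.raises(ValueError):
            stratified_concordance_test({"a": r}, "concordance")
        with pytest.raises(ValueError):
            stratified_concordance_test({"a": r, "b": r, "c": r}, "concordance")
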