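import math

import numpy as np
import pytest

from varburden.core import DNVRecord
from varburden.dnv import (
    classify_consequence,
    classify_records,
    cohort_rate_comparison,
    count_by_gene_class,
    dnv_gene_tests,
    filter_dnvs,
    finalize_dnv_p,
    poisson_class_tail,
    poisson_recurrence_test,
    severity_weighted_test,
)


def rec(gene, term, maf=0.0, sample="t1", severity=None, cohort="cohort0"):
    return DNVRecord(
        sample_id=sample,
        gene_id=gene,
        consequence_term=term,
        severity=severity,
        population_maf=maf,
        cohort_id=cohort,
    )


class TestClassification:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("stop_gained", "PTV"),
            ("splice_acceptor", "PTV"),
            ("splice_donor", "PTV"),
            ("frameshift", "PTV"),
            ("initiator_codon", "PTV"),
            ("start_lost", "PTV"),
            ("conserved_exon_terminus", "PTV"),
            ("stop_lost", "missense"),
            ("missense", "missense"),
            ("inframe_deletion", "missense"),
            ("inframe_insertion", "missense"),
            ("coding_sequence", "missense"),
            ("protein_altering", "missense"),
            ("synonymous", "silent"),
            ("intron", "unclassified"),
        ],
    )
    def test_mapping(self, term, expected):
        assert classify_consequence(term) == expected

    def test_variant_suffix_tolerated(self):
        assert classify_consequence("missense_variant") == "missense"

    def test_empty_term_error(self):
        with pytest.raises(ValueError):
            classify_consequence("")

    def test_classify_records_fills_class(self):
        out = classify_records([rec("G", "stop_gained")])
        assert out[0].variant_class == "PTV"


class TestMafFilter:
    def test_above_threshold_excluded(self):
        assert filter_dnvs([rec("G", "missense", maf=0.02)]) == []

    def test_zero_retained(self):
        assert len(filter_dnvs([rec("G", "missense", maf=0.0)])) == 1

    def test_boundary_retained(self):
        # exclusion is strictly > 0.01
        assert len(filter_dnvs([rec("G", "missense", maf=0.01)])) == 1


class TestCohortRateComparison:
    def test_symmetric_counts(self):
        p = cohort_rate_comparison(
            {"a": {"PTV": 10}, "b": {"PTV": 10}}, {"a": 100, "b": 100}
        )
        assert p["PTV"] == pytest.approx(1.0)

    def test_eight_vs_two(self):
        # two-sided binomial(10, 0.5): 2 * P(X <= 2) = 112/1024
        p = cohort_rate_comparison(
            {"a": {"PTV": 8}, "b": {"PTV": 2}}, {"a": 100, "b": 100}
        )
        assert p["PTV"] == pytest.approx(112 / 1024)

    def test_zero_counts(self):
        p = cohort_rate_comparison({"a": {}, "b": {"PTV": 0}}, {"a": 10, "b": 10})
        assert p.get("PTV", 1.0) == 1.0

    def test_zero_probands_error(self):
        with pytest.raises(ValueError):
            cohort_rate_comparison({"a": {}, "b": {}}, {"a": 0, "b": 10})

    def test_unequal_exposure(self):
        p = cohort_rate_comparison(
            {"a": {"PTV": 20}, "b": {"PTV": 10}}, {"a": 200, "b": 100}
        )
        assert p["PTV"] == pytest.approx(1.0, abs=0.2)


class TestPoissonTail:
    def test_small_lambda_three_observed(self):
        lam = 2 * 2_489 * 1e-6
        expected = 1.0 - math.exp(-lam) * (1 + lam + lam**2 / 2)
        assert poisson_class_tail(3, lam) == pytest.approx(expected, rel=1e-6)
        assert poisson_class_tail(3, lam) == pytest.approx(2.06e-8, rel=0.01)

    def test_zero_observed(self):
        assert poisson_class_tail(0, 5.0) == 1.0

    def test_unit_lambda_one_observed(self):
        assert poisson_class_tail(1, 1.0) == pytest.approx(1 - math.exp(-1), rel=1e-9)


class TestRecurrenceTest:
    RATES = {"G": {"PTV": 1e-6, "missense": 3e-6, "silent": 1e-6}}

    def test_two_class_bonferroni(self):
        observed = {"G": {"PTV": 3}}
        p = poisson_recurrence_test(observed, self.RATES, n_trios=2_489)
        lam_ptv = 2 * 2_489 * 1e-6
        lam_ns = 2 * 2_489 * 4e-6
        expected = min(
            1.0, 2 * min(poisson_class_tail(3, lam_ptv), poisson_class_tail(3, lam_ns))
        )
        assert p["G"] == pytest.approx(expected)

    def test_missing_rate_flagged_p1(self):
        p = poisson_recurrence_test({"X": {"PTV": 5}}, self.RATES, n_trios=100)
        assert p["X"] == 1.0

    def test_zero_observed_p1(self):
        p = poisson_recurrence_test({"G": {}}, self.RATES, n_trios=100)
        assert p["G"] == 1.0

    def test_invalid_trios(self):
        with pytest.raises(ValueError):
            poisson_recurrence_test({}, self.RATES, n_trios=0)

    def test_type_i_calibration_null(self):
        # null simulation across 18,272 synthetic genes
        rng = np.random.default_rng(2024)
        n_genes, n_trios = 18_272, 2_489
        mu_ptv = 10 ** rng.normal(-6, 0.5, size=n_genes)
        mu_mis = 3 * mu_ptv
        rates = {
            f"g{i}": {"PTV": mu_ptv[i], "missense": mu_mis[i]} for i in range(n_genes)
        }
        obs = {
            f"g{i}": {
                "PTV": int(rng.poisson(2 * n_trios * mu_ptv[i])),
                "missense": int(rng.poisson(2 * n_trios * mu_mis[i])),
            }
            for i in range(n_genes)
        }
        p = np.array(list(poisson_recurrence_test(obs, rates, n_trios).values()))
        for alpha in (0.05, 0.01):
            se = math.sqrt(alpha * (1 - alpha) / n_genes)
            assert (p < alpha).mean() <= alpha + 3 * se

    def test_power_twenty_fold_ptv(self):
        # 20-fold PTV enrichment in 10 of many genes; mu chosen so the
        # expected enriched count clears the Bonferroni detection floor
        rng = np.random.default_rng(99)
        n_trios, n_genes, mu = 2_500, 18_272, 2e-4
        rates = {f"g{i}": {"PTV": mu, "missense": 3 * mu} for i in range(20)}
        enriched = [f"g{i}" for i in range(10)]
        obs = {}
        for g, r in rates.items():
            mult = 20.0 if g in enriched else 1.0
            obs[g] = {
                "PTV": int(rng.poisson(2 * n_trios * r["PTV"] * mult)),
                "missense": int(rng.poisson(2 * n_trios * r["missense"])),
            }
        p = poisson_recurrence_test(obs, rates, n_trios)
        recovered = sum(p[g] * n_genes < 0.05 for g in enriched)
        assert recovered >= 8


class TestSeverityTest:
    RATES = {"PTV": 5e-5, "missense": 1.5e-4}

    def test_no_variants_p1(self):
        assert severity_weighted_test([], self.RATES, 2_500, n_sim=200, seed=0) == 1.0

    def test_equal_weights_matches_count_tail(self):
        records = [rec("G", "stop_gained"), rec("G", "missense"), rec("G", "missense")]
        weights = {"PTV": 1.0, "missense": 1.0}
        n_sim = 20_000
        p_sev = severity_weighted_test(
            records, self.RATES, 2_500, severity_weights=weights, n_sim=n_sim, seed=4
        )
        lam = 2 * 2_500 * (5e-5 + 1.5e-4)
        p_count = poisson_class_tail(3, lam)
        sd = math.sqrt(p_count * (1 - p_count) / n_sim)
        assert abs(p_sev - p_count) < 3 * sd + 2 / n_sim

    def test_weight_monotonicity(self):
        records = [rec("G", "stop_gained")] * 3
        ps = []
        for w_ptv in (0.5, 1.0, 2.0):
            ps.append(
                severity_weighted_test(
                    records,
                    self.RATES,
                    2_500,
                    severity_weights={"PTV": w_ptv, "missense": 1.0},
                    n_sim=5_000,
                    seed=8,
                )
            )
        assert ps[0] >= ps[1] >= ps[2]

    def test_min_sim_error(self):
        with pytest.raises(ValueError):
            severity_weighted_test([], self.RATES, 100, n_sim=10)


class TestFinalize:
    def test_minimum(self):
        p, _ = finalize_dnv_p(1e-3, 2.84e-26)
        assert p == 2.84e-26

    def test_single_component(self):
        p, bonf = finalize_dnv_p(0.2)
        assert p == 0.2 and bonf == 1.0

    def test_bonferroni_cap(self):
        p, bonf = finalize_dnv_p(1e-3, n_genes=18_272)
        assert p == 1e-3 and bonf == 1.0

    def test_bonferroni_scaling(self):
        _, bonf = finalize_dnv_p(1e-9, n_genes=18_272)
        assert bonf == pytest.approx(18_272e-9)

    def test_no_components(self):
        p, bonf = finalize_dnv_p(None)
        assert p == 1.0 and bonf == 1.0

    def test_never_exceeds_components(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            parts = [float(x) for x in rng.uniform(1e-6, 1, size=3)]
            p, _ = finalize_dnv_p(*parts)
            assert all(p <= q for q in parts)


class TestGeneTests:
    def test_pipeline_counts_and_min(self):
        rates = {"G": {"PTV": 1e-5, "missense": 3e-5}}
        records = [
            rec("G", "stop_gained"),
            rec("G", "missense"),
            rec("G", "synonymous"),
        ]
        results = dnv_gene_tests(records, rates, n_trios=2_500, n_genes=100)
        res = results["G"]
        assert res.n_ptv == 1 and res.n_missense == 1 and res.n_silent == 1
        assert res.n_nsdnv == 2
        assert res.p_dnv == res.p_poisson
        assert res.p_bonferroni == pytest.approx(min(1.0, 100 * res.p_dnv))

    def test_external_p_used_in_min(self):
        rates = {"G": {"PTV": 1e-5, "missense": 3e-5}}
        records = [rec("G", "stop_gained")]
        results = dnv_gene_tests(
            records, rates, n_trios=2_500, external_p={"G": 1e-12}, n_genes=100
        )
        assert results["G"].p_dnv == 1e-12

    def test_count_by_gene_class(self):
        records = classify_records(
            [rec("A", "stop_gained"), rec("A", "stop_gained"), rec("B", "synonymous")]
        )
        counts = count_by_gene_class(records)
        assert counts["A"] == {"PTV": 2}
        assert counts["B"] == {"silent": 1}
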