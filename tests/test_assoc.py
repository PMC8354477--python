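import itertools

import numpy as np
import pandas as pd
import pytest

from varburden.assoc import (
    build_burden_table,
    exact_gene_test,
    gene_overlap_counts,
    geneset_burden_logistic,
    merge_significant_loci,
    permutation_gene_test,
    syndrome_region_test,
)
from varburden.core import CNVCall, GeneModel, GenomicInterval


def make_del(chrom, start, end, sample, phenotype):
    return CNVCall(
        interval=GenomicInterval(chrom, start, end),
        cnv_type="DEL",
        sample_id=sample,
        phenotype=phenotype,
    )


def gene(gid, chrom, start, end):
    return gid, GenomicInterval(chrom, start, end)


class TestOverlapCounts:
    def test_case_and_control_carriers(self):
        targets = [gene("G", "1", 1000, 2000)]
        cnvs = [
            make_del("1", 900, 1100, "c1", "case"),
            make_del("1", 1500, 2500, "c2", "case"),
            make_del("1", 0, 5000, "k1", "control"),
        ]
        counts = gene_overlap_counts(cnvs, targets)
        assert counts.counts("G") == (2, 1)

    def test_cnv_spanning_multiple_genes(self):
        targets = [
            gene("A", "1", 0, 100),
            gene("B", "1", 200, 300),
            gene("C", "1", 400, 500),
        ]
        cnvs = [make_del("1", 50, 450, "s1", "case")]
        counts = gene_overlap_counts(cnvs, targets)
        assert all(counts.counts(g) == (1, 0) for g in ("A", "B", "C"))

    def test_individual_counted_once_per_gene(self):
        targets = [gene("G", "1", 0, 1000)]
        cnvs = [
            make_del("1", 0, 100, "s1", "case"),
            make_del("1", 500, 900, "s1", "case"),
        ]
        assert gene_overlap_counts(cnvs, targets).counts("G") == (1, 0)

    def test_single_shared_base_counts(self):
        targets = [gene("G", "1", 100, 200)]
        cnvs = [make_del("1", 199, 300, "s1", "case")]
        assert gene_overlap_counts(cnvs, targets).counts("G") == (1, 0)

    def test_empty_targets_error(self):
        with pytest.raises(ValueError):
            gene_overlap_counts([], [])


def toy_counts():
    """2 cases carrying a deletion over G, 2 controls without."""
    targets = [gene("G", "1", 0, 1000)]
    cnvs = [
        make_del("1", 0, 500, "case1", "case"),
        make_del("1", 100, 600, "case2", "case"),
    ]
    phen = {"case1": "case", "case2": "case", "ctrl1": "control", "ctrl2": "control"}
    return gene_overlap_counts(cnvs, targets), phen


class TestPermutationTest:
    def test_toy_exact_sixth(self):
        counts, phen = toy_counts()
        exact = exact_gene_test(counts, phen)
        assert exact[0] == pytest.approx(1 / 6)
        res = permutation_gene_test(counts, phen, n_perm=10_000, seed=5)
        sd = np.sqrt((1 / 6) * (5 / 6) / 10_000)
        assert abs(res.emp1[0] - 1 / 6) < 3 * sd

    def test_oracle_equivalence_random_cohorts(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = int(rng.integers(4, 9))
            n_case = int(rng.integers(1, n))
            samples = [f"s{i}" for i in range(n)]
            phen = {
                s: ("case" if i < n_case else "control") for i, s in enumerate(samples)
            }
            targets = [gene(f"G{j}", "1", j * 1000, j * 1000 + 500) for j in range(3)]
            cnvs = []
            for s in samples:
                for j in range(3):
                    if rng.random() < 0.4:
                        cnvs.append(
                            make_del("1", j * 1000, j * 1000 + 400, s, phen[s])
                        )
            counts = gene_overlap_counts(cnvs, targets)
            exact = exact_gene_test(counts, phen)
            res = permutation_gene_test(counts, phen, n_perm=10_000, seed=trial)
            for g in range(3):
                sd = max(np.sqrt(exact[g] * (1 - exact[g]) / 10_000), 1e-4)
                assert abs(res.emp1[g] - exact[g]) < 3 * sd + 2e-4

    def test_floor_when_observed_exceeds_all(self):
        # 10 case carriers, 40 non-carrier controls: observed stat is
        # essentially never matched by permutation
        targets = [gene("G", "1", 0, 1000)]
        cnvs = [make_del("1", 0, 900, f"case{i}", "case") for i in range(10)]
        phen = {f"case{i}": "case" for i in range(10)}
        phen.update({f"ctrl{i}": "control" for i in range(40)})
        counts = gene_overlap_counts(cnvs, targets)
        res = permutation_gene_test(counts, phen, n_perm=10_000, seed=1)
        assert res.emp1[0] == pytest.approx(1 / 10_001)

    def test_balanced_null_gene_large_p(self):
        targets = [gene("G", "1", 0, 1000)]
        cnvs = [make_del("1", 0, 900, f"case{i}", "case") for i in range(3)] + [
            make_del("1", 0, 900, f"ctrl{i}", "control") for i in range(3)
        ]
        phen = {f"case{i}": "case" for i in range(50)}
        phen.update({f"ctrl{i}": "control" for i in range(50)})
        counts = gene_overlap_counts(cnvs, targets)
        res = permutation_gene_test(counts, phen, n_perm=5_000, seed=3)
        assert res.emp1[0] >= 0.4

    def test_emp2_at_least_emp1(self, cohort, annotation, sim_config):
        genes, masks = annotation
        targets = [(g.gene_id, g.interval) for g in genes[:50]]
        counts = gene_overlap_counts(cohort.calls, targets)
        res = permutation_gene_test(counts, cohort.phenotypes, n_perm=500, seed=9)
        assert (res.emp2 >= res.emp1 - 1e-12).all()
        assert ((res.emp1 >= 1 / 501) & (res.emp1 <= 1.0)).all()

    def test_emp1_monotone_in_case_count(self):
        # same carrier margin (6), increasing case share
        phen = {f"case{i}": "case" for i in range(30)}
        phen.update({f"ctrl{i}": "control" for i in range(30)})
        emp1 = []
        for n_case_carriers in (2, 4, 6):
            targets = [gene("G", "1", 0, 1000)]
            cnvs = [
                make_del("1", 0, 900, f"case{i}", "case")
                for i in range(n_case_carriers)
            ] + [
                make_del("1", 0, 900, f"ctrl{i}", "control")
                for i in range(6 - n_case_carriers)
            ]
            counts = gene_overlap_counts(cnvs, targets)
            res = permutation_gene_test(counts, phen, n_perm=4_000, seed=11)
            emp1.append(res.emp1[0])
        assert emp1[0] > emp1[1] > emp1[2]

    def test_global_null_fwer_control(self):
        rng = np.random.default_rng(0)
        n, n_genes = 60, 40
        phen = {f"s{i}": ("case" if i < 30 else "control") for i in range(n)}
        targets = [gene(f"G{j}", "1", j * 1000, j * 1000 + 500) for j in range(n_genes)]
        hits = 0
        reps = 20
        for rep in range(reps):
            cnvs = []
            for i in range(n):
                for j in range(n_genes):
                    if rng.random() < 0.1:
                        cnvs.append(
                            make_del("1", j * 1000, j * 1000 + 400, f"s{i}", phen[f"s{i}"])
                        )
            counts = gene_overlap_counts(cnvs, targets)
            res = permutation_gene_test(counts, phen, n_perm=400, seed=rep)
            if (res.emp2 < 0.05).any():
                hits += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 3 * se

    def test_determinism(self):
        counts, phen = toy_counts()
        a = permutation_gene_test(counts, phen, n_perm=500, seed=7)
        b = permutation_gene_test(counts, phen, n_perm=500, seed=7)
        assert np.array_equal(a.emp1, b.emp1) and np.array_equal(a.emp2, b.emp2)

    def test_errors(self):
        counts, phen = toy_counts()
        with pytest.raises(ValueError):
            permutation_gene_test(counts, phen, n_perm=0)
        with pytest.raises(ValueError):
            permutation_gene_test(counts, {"a": "case", "b": "case"}, n_perm=10)


class TestSyndromeRegions:
    def test_planted_region_floor_and_empty_region(self):
        regions = [
            ("hit", GenomicInterval("1", 0, 10_000)),
            ("empty", GenomicInterval("2", 0, 10_000)),
        ]
        cnvs = [make_del("1", 100, 5_000, f"case{i}", "case") for i in range(8)]
        phen = {f"case{i}": "case" for i in range(20)}
        phen.update({f"ctrl{i}": "control" for i in range(40)})
        res = syndrome_region_test(cnvs, regions, phen, n_perm=2_000, seed=2)
        by_region = dict(zip(res.targets, res.emp1))
        assert by_region["hit"] < 0.01
        assert by_region["empty"] == 1.0
        counts = dict(zip(res.targets, res.case_counts))
        assert counts["hit"] == 8


class TestLocusMerging:
    def setup_method(self):
        self.genes = {
            "A": GeneModel("A", GenomicInterval("1", 0, 100)),
            "B": GeneModel("B", GenomicInterval("1", 200, 300)),
            "C": GeneModel("C", GenomicInterval("1", 400, 500)),
            "D": GeneModel("D", GenomicInterval("2", 0, 100)),
        }

    def test_shared_deletion_merges(self):
        cnvs = [make_del("1", 50, 250, "s1", "case")]
        loci = merge_significant_loci(["A", "B"], self.genes, cnvs)
        assert len(loci) == 1
        assert loci[0].member_genes == ["A", "B"]
        assert loci[0].interval == GenomicInterval("1", 0, 300)

    def test_isolated_gene_singleton(self):
        loci = merge_significant_loci(["A", "D"], self.genes, [])
        assert len(loci) == 2
        assert all(len(l.member_genes) == 1 for l in loci)

    def test_transitive_closure(self):
        cnvs = [
            make_del("1", 50, 250, "s1", "case"),
            make_del("1", 250, 450, "s2", "case"),
        ]
        loci = merge_significant_loci(["A", "B", "C"], self.genes, cnvs)
        assert len(loci) == 1 and loci[0].member_genes == ["A", "B", "C"]

    def test_control_deletions_do_not_link(self):
        cnvs = [make_del("1", 50, 250, "s1", "control")]
        loci = merge_significant_loci(["A", "B"], self.genes, cnvs)
        assert len(loci) == 2


def _burden_frame(rng, n, effect=1.0, n_set_genes=5):
    """Synthetic per-individual table; ``effect`` multiplies the case rate
    of set-gene disruption."""
    rows = []
    set_genes = [f"S{i}" for i in range(n_set_genes)]
    for i in range(n):
        case = i < n // 2
        lam = 0.3 * (effect if case else 1.0)
        k = rng.poisson(lam)
        disrupted = set(rng.choice(set_genes, size=min(k, n_set_genes), replace=False))
        n_seg = rng.poisson(2) + (len(disrupted) > 0)
        rows.append(
            {
                "sample": f"s{i}",
                "phenotype": "case" if case else "control",
                "study": f"st{i % 3}",
                "n_segments": n_seg,
                "mean_size": float(rng.uniform(1e4, 1e5)) if n_seg else 0.0,
                "disrupted": disrupted,
            }
        )
    return pd.DataFrame(rows), set(set_genes)


class TestBurdenLogistic:
    def test_null_calibration(self):
        rng = np.random.default_rng(123)
        ok = 0
        reps = 20
        for _ in range(reps):
            table, genes = _burden_frame(rng, 2_000, effect=1.0)
            res = geneset_burden_logistic(table, genes)
            if res.error is None and 0.8 <= res.odds_ratio <= 1.25 and res.p_value > 0.05:
                ok += 1
        assert ok >= 0.9 * reps - 2  # >= 90% with 3SE-ish slack

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        table, genes = _burden_frame(rng, 2_000, effect=3.0)
        res = geneset_burden_logistic(table, genes)
        assert res.error is None
        assert res.odds_ratio > 1.0
        assert res.p_value < 0.05
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_separation_flagged(self):
        rows = []
        for i in range(30):
            case = i < 15
            rows.append(
                {
                    "sample": f"s{i}",
                    "phenotype": "case" if case else "control",
                    "study": "st0",
                    "n_segments": 1,
                    "mean_size": 5e4,
                    "disrupted": {"S0"} if case else set(),
                }
            )
        res = geneset_burden_logistic(pd.DataFrame(rows), {"S0"})
        assert res.error is not None

    def test_empty_set_error(self):
        rng = np.random.default_rng(1)
        table, _ = _burden_frame(rng, 50)
        with pytest.raises(ValueError):
            geneset_burden_logistic(table, set())

    def test_oelof_stratified_ordering(self):
        # effect planted only in the "low" bin gives monotone OR decrease
        rng = np.random.default_rng(77)
        rows = []
        bins = {"low": [f"L{i}" for i in range(5)],
                "mid": [f"M{i}" for i in range(5)],
                "high": [f"H{i}" for i in range(5)]}
        for i in range(3_000):
            case = i < 1_500
            disrupted = set()
            for name, members in bins.items():
                lam = 0.3 * (3.0 if (case and name == "low") else 1.0)
                k = min(rng.poisson(lam), 5)
                disrupted |= set(rng.choice(members, size=k, replace=False))
            rows.append(
                {
                    "sample": f"s{i}",
                    "phenotype": "case" if case else "control",
                    "study": f"st{i % 2}",
                    "n_segments": len(disrupted),
                    "mean_size": 5e4 if disrupted else 0.0,
                    "disrupted": disrupted,
                }
            )
        table = pd.DataFrame(rows)
        ors = [
            geneset_burden_logistic(table, set(bins[name])).odds_ratio
            for name in ("low", "mid", "high")
        ]
        assert ors[0] > ors[1] and ors[0] > ors[2]
        assert ors[0] > 1.5


def test_build_burden_table(cohort, annotation):
    genes, _ = annotation
    gene_map = {g.gene_id: g for g in genes}
    table = build_burden_table(
        cohort.calls, gene_map, cohort.phenotypes, cohort.study_of
    )
    assert len(table) == len(cohort.phenotypes)
    no_cnv = table[table["n_segments"] == 0]
    assert (no_cnv["mean_size"] == 0).all()
    assert (no_cnv["disrupted"].map(len) == 0).all()
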