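"""Gene-wise and region-wise CNV association testing.

The statistic per target (gene or region) is the number of *case* carriers
— distinct case individuals with at least one QC-passed deletion sharing
>= 1 base with the target — so the test is one-sided for case excess.
Pointwise empirical p-values (emp1) come from label permutation at fixed
carrier profiles; the family-wise value (emp2) is a min-p step: for each
permutation the smallest pointwise p across all targets is recorded, and
emp2 for a target is the fraction of permutations whose minimum is at
least as extreme as the target's own pointwise p.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CNVCall, GeneModel, GenomicInterval, Locus


@dataclass
class OverlapCounts:
    """Per-target carrier bookkeeping."""

    targets: list[str]
    case_carriers: dict[str, set[str]]
    control_carriers: dict[str, set[str]]

    def counts(self, target: str) -> tuple[int, int]:
        return len(self.case_carriers[target]), len(self.control_carriers[target])


@dataclass
class PermutationResult:
    """Observed statistics and empirical p-values per target."""

    targets: list[str]
    observed: np.ndarray
    emp1: np.ndarray
    emp2: np.ndarray
    n_permutations: int
    case_counts: np.ndarray = None
    control_counts: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.targets,
                "case": self.case_counts,
                "control": self.control_counts,
                "emp1": self.emp1,
                "emp2": self.emp2,
            }
        )


def _target_index(
    targets: Sequence[tuple[str, GenomicInterval]],
) -> dict[str, list[tuple[int, int, str]]]:
    """chrom -> sorted (start, end, target_id)."""
    idx: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for tid, iv in targets:
        idx[iv.chrom].append((iv.start, iv.end, tid))
    for chrom in idx:
        idx[chrom].sort()
    return idx


def gene_overlap_counts(
    cnvs: Iterable[CNVCall],
    targets: Sequence[tuple[str, GenomicInterval]],
) -> OverlapCounts:
    """Count distinct case/control carriers per target (>=1 shared base).

    A CNV spanning several targets contributes a carrier to each; an
    individual with several CNVs over one target is counted once.
    """
    if not targets:
        raise ValueError("empty target list")
    idx = _target_index(targets)
    starts = {chrom: [t[0] for t in lst] for chrom, lst in idx.items()}
    case_carriers: dict[str, set[str]] = {tid: set() for tid, _ in targets}
    control_carriers: dict[str, set[str]] = {tid: set() for tid, _ in targets}
    for c in cnvs:
        lst = idx.get(c.interval.chrom)
        if not lst:
            continue
        hi = bisect.bisect_left(starts[c.interval.chrom], c.interval.end)
        for start, end, tid in lst[:hi]:
            if end > c.interval.start:
                bucket = case_carriers if c.phenotype == "case" else control_carriers
                bucket[tid].add(c.sample_id)
    return OverlapCounts(
        targets=[tid for tid, _ in targets],
        case_carriers=case_carriers,
        control_carriers=control_carriers,
    )


def permutation_gene_test(
    counts: OverlapCounts,
    phenotypes: Mapping[str, str],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    study_of: Optional[Mapping[str, str]] = None,
) -> PermutationResult:
    """Label-permutation test of case-carrier excess per target.

    ``phenotypes`` maps every individual in the cohort (carriers and
    non-carriers alike) to "case"/"control"; carrier profiles travel with
    individuals under permutation.  With ``study_of`` set, labels are
    shuffled within study strata.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples = sorted(phenotypes)
    labels = np.array([phenotypes[s] == "case" for s in samples])
    n_case = int(labels.sum())
    if n_case == 0 or n_case == len(samples):
        raise ValueError("cohort must contain both cases and controls")
    sample_idx = {s: i for i, s in enumerate(samples)}

    # CSR-style carrier incidence: all carrier indices concatenated per target
    targets = counts.targets
    carrier_cat: list[int] = []
    indptr = [0]
    for tid in targets:
        members = counts.case_carriers[tid] | counts.control_carriers[tid]
        carrier_cat.extend(sample_idx[s] for s in members if s in sample_idx)
        indptr.append(len(carrier_cat))
    cat = np.array(carrier_cat, dtype=np.int64)
    indptr_arr = np.array(indptr, dtype=np.int64)
    n_targets = len(targets)

    def stats_for(is_case: np.ndarray) -> np.ndarray:
        if len(cat) == 0:
            return np.zeros(n_targets, dtype=np.int32)
        vals = is_case[cat].astype(np.int32)
        # reduceat cannot take start == len(vals); clip and zero empties after
        starts_clipped = np.minimum(indptr_arr[:-1], len(vals) - 1)
        out = np.add.reduceat(vals, starts_clipped)
        out[indptr_arr[:-1] == indptr_arr[1:]] = 0
        return out

    observed = stats_for(labels)

    rng = np.random.default_rng(seed)
    strata: list[np.ndarray]
    if study_of is not None:
        groups: dict[str, list[int]] = defaultdict(list)
        for s in samples:
            groups[study_of.get(s, "")].append(sample_idx[s])
        strata = [np.array(v) for v in groups.values()]
    else:
        strata = [np.arange(len(samples))]

    null = np.empty((n_perm, n_targets), dtype=np.int32)
    perm_labels = labels.copy()
    for r in range(n_perm):
        for stratum in strata:
            perm_labels[stratum] = perm_labels[rng.permutation(stratum)]
        null[r] = stats_for(perm_labels)

    ge_counts = (null >= observed[None, :]).sum(axis=0)
    emp1 = (1.0 + ge_counts) / (1.0 + n_perm)

    # pointwise p of each permuted statistic within its own null column,
    # then the per-permutation minimum across targets (min-p adjustment)
    null_sorted = np.sort(null, axis=0)
    perm_p = np.empty_like(null, dtype=np.float64)
    for g in range(n_targets):
        pos = np.searchsorted(null_sorted[:, g], null[:, g], side="left")
        perm_p[:, g] = (1.0 + (n_perm - pos)) / (1.0 + n_perm)
    min_p = perm_p.min(axis=1)
    emp2 = np.array(
        [(1.0 + (min_p <= emp1[g]).sum()) / (1.0 + n_perm) for g in range(n_targets)]
    )
    emp2 = np.maximum(emp2, emp1)

    case_counts = np.array([len(counts.case_carriers[t]) for t in targets])
    control_counts = np.array([len(counts.control_carriers[t]) for t in targets])
    return PermutationResult(
        targets=list(targets),
        observed=observed,
        emp1=emp1,
        emp2=emp2,
        n_permutations=n_perm,
        case_counts=case_counts,
        control_counts=control_counts,
    )


def exact_gene_test(
    counts: OverlapCounts, phenotypes: Mapping[str, str]
) -> np.ndarray:
    """Exact one-sided pointwise p by full enumeration of label assignments.

    Only feasible for small cohorts; used as the oracle for the
    permutation machinery.
    """
    from itertools import combinations

    samples = sorted(phenotypes)
    n_case = sum(phenotypes[s] == "case" for s in samples)
    carrier_sets = [
        {s for s in (counts.case_carriers[t] | counts.control_carriers[t]) if s in phenotypes}
        for t in counts.targets
    ]
    observed = [
        len(counts.case_carriers[t] & set(samples)) for t in counts.targets
    ]
    totals = np.zeros(len(counts.targets))
    n_assign = 0
    for case_set in combinations(samples, n_case):
        cs = set(case_set)
        n_assign += 1
        for g, members in enumerate(carrier_sets):
            if len(members & cs) >= observed[g]:
                totals[g] += 1
    return totals / n_assign


def syndrome_region_test(
    cnvs: Iterable[CNVCall],
    regions: Sequence[tuple[str, GenomicInterval]],
    phenotypes: Mapping[str, str],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Region-wise permutation test (same machinery as the gene test)."""
    counts = gene_overlap_counts(cnvs, regions)
    return permutation_gene_test(counts, phenotypes, n_perm=n_perm, seed=seed)


def merge_significant_loci(
    significant_genes: Sequence[str],
    genes: Mapping[str, GeneModel],
    cnvs: Iterable[CNVCall],
) -> list[Locus]:
    """Merge significant genes into loci via shared supporting case deletions.

    Two genes join the same locus when at least one case deletion overlaps
    both; loci are the connected components of that relation, with spans
    covering all member genes, sorted by genomic position.
    """
    sig = [g for g in significant_genes if g in genes]
    parent = {g: g for g in sig}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    targets = [(g, genes[g].interval) for g in sig]
    idx = _target_index(targets)
    starts = {chrom: [t[0] for t in lst] for chrom, lst in idx.items()}
    for c in cnvs:
        if c.phenotype != "case" or c.cnv_type != "DEL":
            continue
        lst = idx.get(c.interval.chrom)
        if not lst:
            continue
        hi = bisect.bisect_left(starts[c.interval.chrom], c.interval.end)
        hit = [tid for start, end, tid in lst[:hi] if end > c.interval.start]
        for other in hit[1:]:
            union(hit[0], other)

    components: dict[str, list[str]] = defaultdict(list)
    for g in sig:
        components[find(g)].append(g)
    loci = []
    for members in components.values():
        ivs = [genes[g].interval for g in members]
        chrom = ivs[0].chrom
        span = GenomicInterval(chrom, min(i.start for i in ivs), max(i.end for i in ivs))
        loci.append((span, sorted(members, key=lambda g: genes[g].interval.start)))
    loci.sort(key=lambda t: (int(t[0].chrom), t[0].start))
    return [
        Locus(locus_id=f"locus_{i + 1}", interval=span, member_genes=members)
        for i, (span, members) in enumerate(loci)
    ]


@dataclass
class BurdenResult:
    """Gene-set logistic burden test result."""

    gene_set: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_case: int
    n_control: int
    error: Optional[str] = None


def build_burden_table(
    cnvs: Iterable[CNVCall],
    genes: Mapping[str, GeneModel],
    phenotypes: Mapping[str, str],
    study_of: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-individual covariate table for the burden test.

    Columns: sample, phenotype, study, n_segments, mean_size, plus the set
    of genes each individual's CNVs disrupt (as a python set column).
    Individuals without CNVs get zero segments and size 0.
    """
    per_sample: dict[str, list[CNVCall]] = defaultdict(list)
    for c in cnvs:
        per_sample[c.sample_id].append(c)
    targets = [(g, gm.interval) for g, gm in genes.items()]
    idx = _target_index(targets)
    starts = {chrom: [t[0] for t in lst] for chrom, lst in idx.items()}

    rows = []
    for s, pheno in phenotypes.items():
        calls = per_sample.get(s, [])
        disrupted: set[str] = set()
        for c in calls:
            lst = idx.get(c.interval.chrom)
            if not lst:
                continue
            hi = bisect.bisect_left(starts[c.interval.chrom], c.interval.end)
            disrupted.update(
                tid for start, end, tid in lst[:hi] if end > c.interval.start
            )
        rows.append(
            {
                "sample": s,
                "phenotype": pheno,
                "study": (study_of or {}).get(
                    s, calls[0].study_id if calls else "study0"
                ),
                "n_segments": len(calls),
                "mean_size": (
                    float(np.mean([c.interval.length for c in calls])) if calls else 0.0
                ),
                "disrupted": disrupted,
            }
        )
    return pd.DataFrame(rows)


def geneset_burden_logistic(
    table: pd.DataFrame,
    gene_set: set[str],
    set_name: str = "set",
) -> BurdenResult:
    """Logistic regression of phenotype on the per-individual count of set
    genes disrupted, adjusting for mean CNV size, segment count and study.

    Complete separation or non-convergence yields a flagged result, not a
    crash.
    """
    import statsmodels.api as sm

    if not gene_set:
        raise ValueError("empty gene set")
    y = (table["phenotype"] == "case").astype(float).to_numpy()
    n_case = int(y.sum())
    n_control = len(y) - n_case
    predictor = table["disrupted"].map(lambda d: len(d & gene_set)).astype(float)
    X = pd.DataFrame(
        {
            "gene_count": predictor,
            "mean_size": table["mean_size"] / 1e6,  # Mb scale for conditioning
            "n_segments": table["n_segments"].astype(float),
        }
    )
    studies = pd.get_dummies(table["study"], prefix="study", drop_first=True, dtype=float)
    X = pd.concat([X, studies], axis=1)
    X = sm.add_constant(X, has_constant="add")

    def flagged(msg: str) -> BurdenResult:
        return BurdenResult(
            gene_set=set_name, odds_ratio=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p_value=float("nan"),
            n_case=n_case, n_control=n_control, error=msg,
        )

    if predictor.sum() == 0:
        return flagged("no individual disrupts the set")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X.to_numpy()).fit(disp=False, maxiter=200)
        coef = fit.params[1]
        se = fit.bse[1]
        if not np.isfinite(coef) or not np.isfinite(se) or se > 50 or abs(coef) > 50:
            return flagged("separation or unstable fit")
        return BurdenResult(
            gene_set=set_name,
            odds_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.959963984540054 * se)),
            ci_high=float(np.exp(coef + 1.959963984540054 * se)),
            p_value=float(fit.pvalues[1]),
            n_case=n_case,
            n_control=n_control,
        )
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        return flagged(f"fit failed: {type(exc).__name__}")
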