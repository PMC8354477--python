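"""De novo variant classification and gene-wise recurrence testing.

Expected counts use the diploid convention ``lambda = 2 * n_trios * rate``.
The recurrence test evaluates two nested classes (PTV alone, and
PTV+missense) and Bonferroni-corrects over the two, mirroring published
enrichment-tool behaviour; a severity-weighted Monte-Carlo surrogate and
externally computed per-gene p-values can contribute, and the reported
per-gene p is the minimum of the available components.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import DNVRecord

PTV = "PTV"
MISSENSE = "missense"
SILENT = "silent"
UNCLASSIFIED = "unclassified"

DEFAULT_N_GENES = 18_272

PTV_TERMS = frozenset(
    {
        "stop_gained",
        "splice_acceptor",
        "splice_donor",
        "frameshift",
        "initiator_codon",
        "start_lost",
        "conserved_exon_terminus",
    }
)
MISSENSE_TERMS = frozenset(
    {
        "stop_lost",
        "missense",
        "inframe_deletion",
        "inframe_insertion",
        "coding_sequence",
        "protein_altering",
    }
)
SILENT_TERMS = frozenset({"synonymous"})

#: Monte-Carlo surrogate severity weights per class (arbitrary defaults,
#: configurable; the reference severity model is not reimplemented here).
DEFAULT_SEVERITY_WEIGHTS = {PTV: 1.0, MISSENSE: 0.5}


def classify_consequence(term: str) -> str:
    """Map a consequence term to PTV / missense / silent / unclassified."""
    if not term:
        raise ValueError("empty consequence term")
    t = term.strip().lower()
    # tolerate common VEP-style suffixes, e.g. "stop_gained_variant"
    t = t.removesuffix("_variant")
    if t in PTV_TERMS:
        return PTV
    if t in MISSENSE_TERMS:
        return MISSENSE
    if t in SILENT_TERMS:
        return SILENT
    return UNCLASSIFIED


def filter_dnvs(
    records: Iterable[DNVRecord], maf_threshold: float = 0.01
) -> list[DNVRecord]:
    """Drop records with population MAF strictly above the threshold."""
    return [r for r in records if r.population_maf <= maf_threshold]


def classify_records(records: Iterable[DNVRecord]) -> list[DNVRecord]:
    """Fill ``variant_class`` from the consequence term (returns new list)."""
    out = []
    for r in records:
        cls = classify_consequence(r.consequence_term)
        out.append(
            DNVRecord(
                sample_id=r.sample_id,
                gene_id=r.gene_id,
                consequence_term=r.consequence_term,
                variant_class=cls,
                severity=r.severity,
                population_maf=r.population_maf,
                cohort_id=r.cohort_id,
            )
        )
    return out


def cohort_rate_comparison(
    counts: Mapping[str, Mapping[str, int]],
    n_probands: Mapping[str, int],
) -> dict[str, float]:
    """Exact two-rate Poisson comparison between two cohorts, per class.

    ``counts`` maps cohort id -> {class: count}; exposure is the proband
    count.  Conditional on the total, the first cohort's count is
    binomial, giving an exact two-sided p per class.
    """
    cohorts = sorted(n_probands)
    if len(cohorts) != 2:
        raise ValueError("exactly two cohorts required")
    if any(n_probands[c] <= 0 for c in cohorts):
        raise ValueError("zero probands in a cohort")
    a, b = cohorts
    frac = n_probands[a] / (n_probands[a] + n_probands[b])
    classes = sorted(set(counts.get(a, {})) | set(counts.get(b, {})))
    out = {}
    for cls in classes:
        xa = counts.get(a, {}).get(cls, 0)
        xb = counts.get(b, {}).get(cls, 0)
        total = xa + xb
        if total == 0:
            out[cls] = 1.0
            continue
        out[cls] = float(stats.binomtest(xa, total, frac, alternative="two-sided").pvalue)
    return out


def poisson_class_tail(observed: int, lam: float) -> float:
    """Upper tail P(Poisson(lam) >= observed)."""
    if observed <= 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


@dataclass
class DNVTestResult:
    gene_id: str
    n_ptv: int = 0
    n_missense: int = 0
    n_silent: int = 0
    p_poisson: float = 1.0
    p_severity: Optional[float] = None
    p_external: Optional[float] = None
    p_dnv: float = 1.0
    p_bonferroni: float = 1.0
    flags: set = field(default_factory=set)

    @property
    def n_nsdnv(self) -> int:
        return self.n_ptv + self.n_missense


def count_by_gene_class(records: Iterable[DNVRecord]) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in records:
        cls = r.variant_class or classify_consequence(r.consequence_term)
        counts[r.gene_id][cls] += 1
    return {g: dict(v) for g, v in counts.items()}


def poisson_recurrence_test(
    observed: Mapping[str, Mapping[str, int]],
    rates: Mapping[str, Mapping[str, float]],
    n_trios: int,
) -> dict[str, float]:
    """Per-gene recurrence p over the PTV and PTV+missense classes.

    lambda per class is ``2 * n_trios * rate``; the reported p is the
    smaller of the two class tails, doubled (Bonferroni over two tests)
    and capped at 1.  Genes with observations but no rate get p = 1.
    """
    if n_trios <= 0:
        raise ValueError("n_trios must be > 0")
    out: dict[str, float] = {}
    for gene, cls_counts in observed.items():
        gene_rates = rates.get(gene)
        n_ptv = cls_counts.get(PTV, 0)
        n_mis = cls_counts.get(MISSENSE, 0)
        if gene_rates is None:
            out[gene] = 1.0
            continue
        mu_ptv = gene_rates.get(PTV, 0.0)
        mu_mis = gene_rates.get(MISSENSE, 0.0)
        p_ptv = poisson_class_tail(n_ptv, 2.0 * n_trios * mu_ptv) if mu_ptv > 0 else 1.0
        p_ns = (
            poisson_class_tail(n_ptv + n_mis, 2.0 * n_trios * (mu_ptv + mu_mis))
            if (mu_ptv + mu_mis) > 0
            else 1.0
        )
        out[gene] = min(1.0, 2.0 * min(p_ptv, p_ns))
    return out


def severity_weighted_test(
    records: Sequence[DNVRecord],
    gene_rates: Mapping[str, float],
    n_trios: int,
    severity_weights: Mapping[str, float] = DEFAULT_SEVERITY_WEIGHTS,
    n_sim: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Monte-Carlo severity-score test for one gene.

    The observed statistic is the summed severity over the gene's
    non-synonymous DNVs (per-variant severity when present, else the
    class weight).  Null draws take a Poisson total at the gene's combined
    non-synonymous rate, split classes by rate share, and score them by
    the class weights.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    classes = [c for c in (PTV, MISSENSE) if gene_rates.get(c, 0.0) > 0]
    lam = 2.0 * n_trios * sum(gene_rates[c] for c in classes)
    obs = 0.0
    n_obs = 0
    for r in records:
        cls = r.variant_class or classify_consequence(r.consequence_term)
        if cls in (PTV, MISSENSE):
            obs += r.severity if r.severity is not None else severity_weights.get(cls, 0.0)
            n_obs += 1
    if n_obs == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    shares = np.array([gene_rates[c] for c in classes], dtype=float)
    shares /= shares.sum()
    weights = np.array([severity_weights.get(c, 0.0) for c in classes])
    totals = rng.poisson(lam, size=n_sim)
    sim_scores = np.array(
        [rng.multinomial(t, shares) @ weights if t > 0 else 0.0 for t in totals]
    )
    return float((1.0 + (sim_scores >= obs - 1e-12).sum()) / (1.0 + n_sim))


def finalize_dnv_p(
    p_poisson: Optional[float],
    p_severity: Optional[float] = None,
    p_external: Optional[float] = None,
    n_genes: int = DEFAULT_N_GENES,
) -> tuple[float, float]:
    """Minimum of available component p-values, plus its Bonferroni value."""
    components = [p for p in (p_poisson, p_severity, p_external) if p is not None]
    if not components:
        return 1.0, 1.0
    p_dnv = min(components)
    return p_dnv, min(1.0, n_genes * p_dnv)


def dnv_gene_tests(
    records: Sequence[DNVRecord],
    rates: Mapping[str, Mapping[str, float]],
    n_trios: int,
    run_severity: bool = False,
    severity_weights: Mapping[str, float] = DEFAULT_SEVERITY_WEIGHTS,
    external_p: Optional[Mapping[str, float]] = None,
    n_genes: int = DEFAULT_N_GENES,
    n_sim: int = 2_000,
    seed: Optional[int] = None,
) -> dict[str, DNVTestResult]:
    """Run the full gene-wise DNV pipeline over classified records."""
    records = classify_records(records)
    counts = count_by_gene_class(records)
    by_gene: dict[str, list[DNVRecord]] = defaultdict(list)
    for r in records:
        by_gene[r.gene_id].append(r)
    p_poisson = poisson_recurrence_test(counts, rates, n_trios)

    results: dict[str, DNVTestResult] = {}
    rng = np.random.default_rng(seed)
    for gene, cls_counts in counts.items():
        res = DNVTestResult(
            gene_id=gene,
            n_ptv=cls_counts.get(PTV, 0),
            n_missense=cls_counts.get(MISSENSE, 0),
            n_silent=cls_counts.get(SILENT, 0),
            p_poisson=p_poisson[gene],
        )
        if gene not in rates:
            res.flags.add("no_rate")
        if run_severity and gene in rates:
            res.p_severity = severity_weighted_test(
                by_gene[gene],
                rates[gene],
                n_trios,
                severity_weights=severity_weights,
                n_sim=n_sim,
                seed=int(rng.integers(2**31)),
            )
        if external_p and gene in external_p:
            res.p_external = float(external_p[gene])
        res.p_dnv, res.p_bonferroni = finalize_dnv_p(
            res.p_poisson, res.p_severity, res.p_external, n_genes=n_genes
        )
        results[gene] = res
    return results
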