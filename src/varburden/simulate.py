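"""Seeded generators for every input the pipeline consumes.

The synthetic genome is miniature (22 autosomes of a few Mb; chromosome 1
is long enough to host oversize-deletion QC violators) so the whole
pipeline runs in minutes.  Planted structure — case-only deletion
enrichment in chosen risk genes, de novo rate multipliers, low-LOEUF bias,
heart-specific expression trajectories, dense PPI modules and explicit QC
violators — gives every downstream stage a parameter-recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CASE, CONTROL, CNVCall, GeneModel, GenomicInterval, MaskSet
from .expression import ExpressionMatrix


@dataclass(frozen=True)
class SimConfig:
    seed: int
    # cohort
    n_cases: int = 300
    n_controls: int = 400
    n_studies: int = 4
    taa_fraction: float = 0.1  # cases labelled with the TAA subphenotype
    # genome / annotation
    n_genes: int = 200
    n_chroms: int = 22
    chrom_length: int = 5_000_000
    long_chrom_length: int = 30_000_000  # chromosome "1"
    gene_length: int = 20_000
    probe_spacing: int = 500
    telomere_size: int = 50_000
    centromere_size: int = 100_000
    segdup_size: int = 50_000
    n_segdups_per_chrom: int = 1
    # CNV cohort
    background_del_rate: float = 1.2
    del_length_min: int = 12_000
    del_length_max: int = 80_000
    base_gene_carrier_p: float = 0.002
    n_cnv_risk: int = 10
    cnv_risk_multiplier: float = 25.0
    n_qc_violators_per_gate: int = 8
    common_cnv_control_carriers: int = 12
    # trios / DNV
    n_trios: int = 2_500
    rate_log10_mean: float = -4.3
    rate_log10_sd: float = 0.05
    missense_rate_factor: float = 3.0
    silent_rate_factor: float = 1.0
    n_dnv_risk: int = 10
    dnv_risk_multiplier: float = 8.0
    n_joint_risk: int = 3
    # LOEUF model
    risk_loeuf_range: tuple = (0.03, 0.30)
    null_loeuf_range: tuple = (0.20, 1.50)
    # expression
    expr_noise_sd: float = 0.3
    expr_base_mean: float = 3.0
    expr_base_sd: float = 1.0
    heart_boost: float = 4.0
    heart_slope: float = 4.0
    n_replicates: int = 2
    # PPI
    ppi_background_nodes: int = 40
    ppi_module_edge_p: float = 0.9
    ppi_background_edge_p: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


# independent deterministic substreams per generator
_STREAMS = {
    "planted": 11,
    "annotation": 23,
    "cnv": 37,
    "dnv": 53,
    "expression": 71,
    "ppi": 89,
}


def _stream_rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def gene_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{str(i + 1).zfill(width)}" for i in range(config.n_genes)]


def planted_genes(config: SimConfig) -> tuple[dict[str, float], dict[str, float]]:
    """Deterministic (cnv_risk, dnv_risk) multiplier maps with the
    configured overlap between the two sets."""
    ids = gene_ids(config)
    rng = _stream_rng(config, "planted")
    n_total = config.n_cnv_risk + config.n_dnv_risk - config.n_joint_risk
    if n_total > len(ids):
        raise ValueError("more risk genes than genes")
    chosen = list(rng.choice(ids, size=n_total, replace=False))
    joint = chosen[: config.n_joint_risk]
    cnv_only = chosen[config.n_joint_risk : config.n_cnv_risk]
    dnv_only = chosen[config.n_cnv_risk :]
    cnv_risk = {g: config.cnv_risk_multiplier for g in joint + cnv_only}
    dnv_risk = {g: config.dnv_risk_multiplier for g in joint + dnv_only}
    return cnv_risk, dnv_risk


def chrom_lengths(config: SimConfig) -> dict[str, int]:
    return {
        str(c): (config.long_chrom_length if c == 1 else config.chrom_length)
        for c in range(1, config.n_chroms + 1)
    }


def simulate_annotation(config: SimConfig) -> tuple[list[GeneModel], MaskSet]:
    """Gene models (with rates and LOEUF) plus masks and a probe grid."""
    rng = _stream_rng(config, "annotation")
    lengths = chrom_lengths(config)
    cnv_risk, dnv_risk = planted_genes(config)
    risk = set(cnv_risk) | set(dnv_risk)
    ids = gene_ids(config)

    # spread genes round-robin over chromosomes, evenly within the usable
    # interior (outside telomeres and the mid-chromosome centromere)
    per_chrom: dict[str, list[str]] = {c: [] for c in lengths}
    chroms = list(lengths)
    for i, gid in enumerate(ids):
        per_chrom[chroms[i % len(chroms)]].append(gid)

    genes: list[GeneModel] = []
    telomeres, centromeres, segdups = [], [], []
    probes: dict[str, np.ndarray] = {}
    for chrom, clen in lengths.items():
        telomeres.append(GenomicInterval(chrom, 0, config.telomere_size))
        telomeres.append(GenomicInterval(chrom, clen - config.telomere_size, clen))
        cen_mid = clen // 2
        centromeres.append(
            GenomicInterval(
                chrom,
                cen_mid - config.centromere_size // 2,
                cen_mid + config.centromere_size // 2,
            )
        )
        probes[chrom] = np.arange(config.telomere_size, clen, config.probe_spacing)

        members = per_chrom[chrom]
        if not members:
            continue
        usable_lo = config.telomere_size + config.segdup_size * 2
        usable_hi = clen - config.telomere_size - config.segdup_size * 2
        slot = (usable_hi - usable_lo) // (len(members) + 1)
        if slot <= config.gene_length * 2:
            raise ValueError("genome too small for n_genes")
        for j, gid in enumerate(members):
            start = usable_lo + (j + 1) * slot
            mid = cen_mid
            if start <= mid <= start + config.gene_length:
                start = mid + config.centromere_size  # dodge the centromere
            iv = GenomicInterval(chrom, start, start + config.gene_length)
            mu_ptv = 10 ** rng.normal(config.rate_log10_mean, config.rate_log10_sd)
            rates = {
                "PTV": mu_ptv,
                "missense": mu_ptv * config.missense_rate_factor,
                "silent": mu_ptv * config.silent_rate_factor,
            }
            lo, hi = (
                config.risk_loeuf_range if gid in risk else config.null_loeuf_range
            )
            genes.append(
                GeneModel(
                    gene_id=gid,
                    interval=iv,
                    loeuf=float(rng.uniform(lo, hi)),
                    oe_lof=float(rng.uniform(lo, hi)),
                    mutation_rates=rates,
                )
            )
        # segdups in the gaps before the first gene
        for s in range(config.n_segdups_per_chrom):
            sd_start = config.telomere_size + s * config.segdup_size * 2 + 1_000
            segdups.append(GenomicInterval(chrom, sd_start, sd_start + config.segdup_size))

    genes.sort(key=lambda g: (int(g.interval.chrom), g.interval.start))
    masks = MaskSet(
        telomeres=telomeres,
        centromeres=centromeres,
        segdups=segdups,
        probes={c: list(map(int, v)) for c, v in probes.items()},
    )
    return genes, masks


@dataclass
class CNVCohort:
    """Simulated cohort: calls, per-sample metadata and planted structure."""

    calls: list
    phenotypes: dict
    study_of: dict
    subphenotype_of: dict
    planted_violators: dict  # gate name -> list of indices into calls
    cnv_risk: dict
    dnv_risk: dict


def simulate_cnv_cohort(
    config: SimConfig,
    genes: Sequence[GeneModel],
    masks: MaskSet,
) -> CNVCohort:
    """CNV calls with planted case enrichment and explicit QC violators.

    Background deletions are crafted to pass every default QC gate so the
    planted violators (undersize, oversize, mask-covered, low-probe,
    common) are exactly what each gate removes.
    """
    rng = _stream_rng(config, "cnv")
    lengths = chrom_lengths(config)
    cnv_risk, dnv_risk = planted_genes(config)
    gene_by_id = {g.gene_id: g for g in genes}

    samples = [f"case_{i:05d}" for i in range(config.n_cases)] + [
        f"ctrl_{i:05d}" for i in range(config.n_controls)
    ]
    phenotypes = {
        s: (CASE if s.startswith("case_") else CONTROL) for s in samples
    }
    study_of = {
        s: f"study_{rng.integers(config.n_studies)}" for s in samples
    }
    subpheno_of = {
        s: ("TAA" if phenotypes[s] == CASE and rng.random() < config.taa_fraction else None)
        for s in samples
    }

    from .core import fraction_covered, merge_intervals

    mask_union = merge_intervals(masks.all_mask_regions())
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in mask_union:
        by_chrom.setdefault(r.chrom, []).append(r)

    min_len = max(config.del_length_min, (10 + 2) * config.probe_spacing)

    # window reserved for the planted common deletion so background calls
    # cannot collide with it and pick up a spurious internal frequency
    last_chrom = str(config.n_chroms)
    reserved = GenomicInterval(
        last_chrom, config.telomere_size + 60_000, config.telomere_size + 260_000
    )
    common_iv = GenomicInterval(
        last_chrom, reserved.start + 40_000, reserved.start + 60_000
    )

    def clean_background_interval() -> GenomicInterval:
        for _ in range(100):
            chrom = str(rng.integers(1, config.n_chroms + 1))
            length = int(rng.integers(min_len, config.del_length_max))
            clen = lengths[chrom]
            start = int(rng.integers(config.telomere_size, clen - config.telomere_size - length))
            iv = GenomicInterval(chrom, start, start + length)
            if iv.overlaps(reserved):
                continue
            if fraction_covered(iv, by_chrom.get(chrom, [])) <= 0.3:
                return iv
        raise RuntimeError("could not place a clean background deletion")

    calls: list[CNVCall] = []

    def add(iv, cnv_type, sample, probe_count=None):
        calls.append(
            CNVCall(
                interval=iv,
                cnv_type=cnv_type,
                sample_id=sample,
                phenotype=phenotypes[sample],
                study_id=study_of[sample],
                subphenotype=subpheno_of[sample],
                probe_count=probe_count,
            )
        )

    # background deletions for everyone
    for s in samples:
        for _ in range(rng.poisson(config.background_del_rate)):
            add(clean_background_interval(), "DEL", s)

    # risk-gene deletions: elevated carrier rate in cases only
    for gid, mult in cnv_risk.items():
        g = gene_by_id[gid]
        pad = 2_000
        iv_proto = (g.interval.chrom, g.interval.start - pad, g.interval.end + pad)
        for s in samples:
            p = config.base_gene_carrier_p * (mult if phenotypes[s] == CASE else 1.0)
            if rng.random() < p:
                jitter = int(rng.integers(0, 1_000))
                add(
                    GenomicInterval(iv_proto[0], iv_proto[1] - jitter, iv_proto[2] + jitter),
                    "DEL",
                    s,
                )

    planted: dict[str, list[int]] = {
        "size_small": [],
        "size_large": [],
        "mask": [],
        "probes": [],
        "maf": [],
    }
    ctrl_samples = [s for s in samples if phenotypes[s] == CONTROL]

    for _ in range(config.n_qc_violators_per_gate):
        s = samples[int(rng.integers(len(samples)))]
        # undersized (< 5 kb)
        iv = clean_background_interval()
        small = GenomicInterval(iv.chrom, iv.start, iv.start + 4_000)
        planted["size_small"].append(len(calls))
        add(small, "DEL", s)
        # oversized (> 20 Mb) on the long chromosome
        planted["size_large"].append(len(calls))
        add(GenomicInterval("1", 100_000, 100_000 + 25_000_000), "DEL", s)
        # mostly inside a segdup (> 50% covered)
        sd = masks.segdups[int(rng.integers(len(masks.segdups)))]
        cov = GenomicInterval(
            sd.chrom, sd.start + 1_000, sd.start + 1_000 + int(config.segdup_size * 1.2)
        )
        planted["mask"].append(len(calls))
        add(cov, "DEL", s)
        # too few probes (explicit low probe_count)
        planted["probes"].append(len(calls))
        add(clean_background_interval(), "DEL", s, probe_count=3)

    # a common deletion: identical interval in > 1% of controls plus one case
    carriers = list(
        rng.choice(ctrl_samples, size=config.common_cnv_control_carriers, replace=False)
    )
    for s in carriers:
        planted["maf"].append(len(calls))
        add(common_iv, "DEL", s)
    case_sample = samples[0]
    planted["maf"].append(len(calls))
    add(common_iv, "DEL", case_sample)

    return CNVCohort(
        calls=calls,
        phenotypes=phenotypes,
        study_of=study_of,
        subphenotype_of=subpheno_of,
        planted_violators=planted,
        cnv_risk=cnv_risk,
        dnv_risk=dnv_risk,
    )


_CLASS_TERMS = {
    "PTV": ("stop_gained", "frameshift", "splice_acceptor", "splice_donor"),
    "missense": ("missense", "inframe_deletion", "inframe_insertion"),
    "silent": ("synonymous",),
}


def simulate_trio_dnvs(config: SimConfig, genes: Sequence[GeneModel]):
    """De novo variant records drawn from the per-gene rate model.

    Per gene and class the count is Poisson(2 * n_trios * mu * multiplier)
    with the multiplier applied to PTV and missense classes of the planted
    DNV risk genes.  Population MAF is 0 for all simulated records.
    """
    from .core import DNVRecord

    rng = _stream_rng(config, "dnv")
    _, dnv_risk = planted_genes(config)
    records: list[DNVRecord] = []
    for g in genes:
        for cls, mu in (g.mutation_rates or {}).items():
            mult = dnv_risk.get(g.gene_id, 1.0) if cls in ("PTV", "missense") else 1.0
            n = rng.poisson(2.0 * config.n_trios * mu * mult)
            for _ in range(n):
                term = _CLASS_TERMS[cls][int(rng.integers(len(_CLASS_TERMS[cls])))]
                records.append(
                    DNVRecord(
                        sample_id=f"trio_{rng.integers(config.n_trios):05d}",
                        gene_id=g.gene_id,
                        consequence_term=term,
                        severity=float(rng.uniform(10, 40)),
                        population_maf=0.0,
                        cohort_id=f"cohort{rng.integers(2)}",
                    )
                )
    return records


#: time points (days post-conception): 4-20 wpc plus infant/adult
EXPR_TIMEPOINTS = [28, 35, 42, 49, 56, 63, 77, 91, 112, 140, 280, 1000, 7300]


def simulate_expression(config: SimConfig, genes: Sequence[GeneModel]) -> ExpressionMatrix:
    """Three-organ expression time course with planted heart-specific genes.

    Planted genes (the CNV/DNV risk genes) are boosted in the heart and
    rise with developmental time; all other genes share flat organ-blind
    baselines.  Values are log-normal noise around the templates, with
    ``n_replicates`` replicates per organ/time point.
    """
    rng = _stream_rng(config, "expression")
    cnv_risk, dnv_risk = planted_genes(config)
    planted = set(cnv_risk) | set(dnv_risk)
    ids = [g.gene_id for g in genes]
    base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=len(ids))

    organs = ("heart", "kidney", "liver")
    cols, meta_rows = [], []
    data = np.zeros((len(ids), len(organs) * len(EXPR_TIMEPOINTS) * config.n_replicates))
    t_arr = np.array(EXPR_TIMEPOINTS, dtype=float)
    t_norm = (t_arr - t_arr.min()) / (t_arr.max() - t_arr.min())

    j = 0
    for organ in organs:
        for ti, t in enumerate(EXPR_TIMEPOINTS):
            for rep in range(config.n_replicates):
                log_expr = base.copy()
                if organ == "heart":
                    boost = np.array(
                        [
                            config.heart_boost + config.heart_slope * t_norm[ti]
                            if gid in planted
                            else 0.0
                            for gid in ids
                        ]
                    )
                    log_expr = log_expr + boost
                noise = rng.normal(0.0, config.expr_noise_sd, size=len(ids))
                data[:, j] = np.exp2(log_expr + noise)
                sid = f"{organ}_t{t}_r{rep}"
                cols.append(sid)
                meta_rows.append(
                    {"sample": sid, "organ": organ, "time_days": float(t), "replicate": rep}
                )
                j += 1

    values = pd.DataFrame(data, index=ids, columns=cols)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(values=values, samples=samples)


def simulate_ppi(config: SimConfig, genes: Sequence[GeneModel]) -> list[tuple[str, str]]:
    """Edge list with dense planted modules over the risk genes.

    The CNV-risk and DNV-risk gene sets each form a module with high
    within-module edge probability; background nodes (the first
    ``ppi_background_nodes`` non-risk genes) connect sparsely.
    """
    rng = _stream_rng(config, "ppi")
    cnv_risk, dnv_risk = planted_genes(config)
    modules = [sorted(cnv_risk), sorted(set(dnv_risk) - set(cnv_risk))]
    risk = set(cnv_risk) | set(dnv_risk)
    background = [g.gene_id for g in genes if g.gene_id not in risk][
        : config.ppi_background_nodes
    ]
    nodes = sorted(set().union(*[set(m) for m in modules], background))

    edges: set[tuple[str, str]] = set()
    for module in modules:
        for i, a in enumerate(module):
            for b in module[i + 1 :]:
                if rng.random() < config.ppi_module_edge_p:
                    edges.add((min(a, b), max(a, b)))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if rng.random() < config.ppi_background_edge_p:
                edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def write_fixture(config: SimConfig, out_dir) -> dict:
    """Generate every pipeline input and write it under ``out_dir``.

    Returns a mapping of logical input name to file path, suitable for
    building a :class:`varburden.pipeline.PipelineConfig`.
    """
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, masks = simulate_annotation(config)
    cohort = simulate_cnv_cohort(config, genes, masks)
    dnvs = simulate_trio_dnvs(config, genes)
    expr = simulate_expression(config, genes)
    edges = simulate_ppi(config, genes)

    paths = {
        "cnv_path": out / "cnv.tsv",
        "samples_path": out / "samples.tsv",
        "gene_models_path": out / "genes.tsv",
        "probe_path": out / "probes.tsv",
        "telomere_bed": out / "telomeres.bed",
        "centromere_bed": out / "centromeres.bed",
        "segdup_bed": out / "segdups.bed",
        "dnv_path": out / "dnv.tsv",
        "rates_path": out / "rates.tsv",
        "expression_path": out / "expression.tsv",
        "expression_samples_path": out / "expression_samples.tsv",
        "ppi_path": out / "ppi.tsv",
        "gene_sets_path": out / "gene_sets.gmt",
    }
    io.write_cnv_table(cohort.calls, paths["cnv_path"])
    pd.DataFrame(
        [
            {
                "sample": s,
                "phenotype": p,
                "study": cohort.study_of[s],
                "subphenotype": cohort.subphenotype_of.get(s) or "",
            }
            for s, p in cohort.phenotypes.items()
        ]
    ).to_csv(paths["samples_path"], sep="\t", index=False)
    io.write_gene_models(genes, paths["gene_models_path"])
    pd.DataFrame(
        [
            {"chrom": chrom, "pos": pos}
            for chrom, positions in (masks.probes or {}).items()
            for pos in positions
        ]
    ).to_csv(paths["probe_path"], sep="\t", index=False)
    io.write_bed(masks.telomeres, paths["telomere_bed"])
    io.write_bed(masks.centromeres, paths["centromere_bed"])
    io.write_bed(masks.segdups, paths["segdup_bed"])
    io.write_dnv_table(dnvs, paths["dnv_path"])
    io.write_rate_table(
        {g.gene_id: dict(g.mutation_rates or {}) for g in genes}, paths["rates_path"]
    )
    expr.values.to_csv(paths["expression_path"], sep="\t")
    expr.samples.to_csv(paths["expression_samples_path"], sep="\t")
    io.write_edge_list(edges, paths["ppi_path"])
    rng = _stream_rng(config, "ppi")
    random_set = sorted(rng.choice(gene_ids(config), size=15, replace=False))
    io.write_gene_sets(
        {
            "planted_cnv_risk": sorted(cohort.cnv_risk),
            "planted_dnv_risk": sorted(cohort.dnv_risk),
            "random_set": random_set,
        },
        paths["gene_sets_path"],
    )
    return {k: str(v) for k, v in paths.items()}
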