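"""End-to-end orchestration: QC -> CNV tests -> DNV tests -> integration
-> expression -> network, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, assoc, dnv, expression, integrate, io, network, qc
from .core import MaskSet

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """File paths and knobs for a full run.  ``seed`` is mandatory."""

    seed: int
    out_dir: str
    # inputs
    cnv_path: str
    gene_models_path: str
    samples_path: Optional[str] = None  # TSV: sample, phenotype, study
    probe_path: Optional[str] = None
    telomere_bed: Optional[str] = None
    centromere_bed: Optional[str] = None
    segdup_bed: Optional[str] = None
    dnv_path: Optional[str] = None
    rates_path: Optional[str] = None
    expression_path: Optional[str] = None  # TSV genes x samples
    expression_samples_path: Optional[str] = None
    ppi_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    regions_bed: Optional[str] = None
    # dialects
    cnv_dialect: str = "one-based-inclusive"
    # QC
    min_size: int = 5_000
    max_size: int = 20_000_000
    min_probes: int = 10
    mask_fraction: float = 0.5
    maf_threshold: float = 0.01
    reciprocal_threshold: float = 0.5
    deletions_only: bool = True
    # association
    n_perm: int = 5_000
    cnv_sig_threshold: float = 0.05
    study_stratified: bool = False
    # DNV
    n_trios: int = 2_500
    dnv_n_genes: Optional[int] = None  # default: size of tested gene universe
    run_severity: bool = False
    external_dnv_p_path: Optional[str] = None
    # integration
    ihw_bins: int = 5
    ihw_folds: int = 5
    alpha: float = 0.05
    # network
    network_n_perm: int = 200
    clique_k: int = 3
    # subgroup filters (apply to cases only)
    exclude_subphenotypes: tuple = ()
    include_subphenotypes: tuple = ()

    def qc_params(self) -> qc.QCParams:
        return qc.QCParams(
            min_size=self.min_size,
            max_size=self.max_size,
            min_probes=self.min_probes,
            mask_fraction=self.mask_fraction,
            maf_threshold=self.maf_threshold,
            reciprocal_threshold=self.reciprocal_threshold,
            deletions_only=self.deletions_only,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from JSON or YAML."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    for key in ("exclude_subphenotypes", "include_subphenotypes"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def _load_samples(config: PipelineConfig, calls) -> tuple[dict, dict, dict]:
    """(phenotypes, study_of, subphenotype_of) for the cohort; from the
    sample table when given, else derived from the CNV calls."""
    if config.samples_path:
        df = pd.read_csv(config.samples_path, sep="\t", dtype=str)
        phen = dict(zip(df["sample"], df["phenotype"].str.lower()))
        study = dict(zip(df["sample"], df.get("study", pd.Series(dtype=str)).fillna("study0")))
        sub = {}
        if "subphenotype" in df.columns:
            sub = {
                s: v
                for s, v in zip(df["sample"], df["subphenotype"])
                if isinstance(v, str) and v
            }
        return phen, study, sub
    phen, study, sub = {}, {}, {}
    for c in calls:
        phen[c.sample_id] = c.phenotype
        study[c.sample_id] = c.study_id
        if c.subphenotype:
            sub[c.sample_id] = c.subphenotype
    return phen, study, sub


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns {stage: output path or frame}.

    Any stage failure aborts with :class:`StageError`; partial outputs
    already flushed are kept and a ``FAILED`` marker file names the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        # ---------------- load & subset ----------------
        stage = "load"
        t0 = time.time()
        calls, rejections = io.load_cnv_table(config.cnv_path, dialect=config.cnv_dialect)
        phenotypes, study_of, subpheno_of = _load_samples(config, calls)
        if config.include_subphenotypes or config.exclude_subphenotypes:
            include = set(config.include_subphenotypes)
            exclude = set(config.exclude_subphenotypes)

            def keep_sample(s: str) -> bool:
                if phenotypes.get(s) != "case":
                    return True
                sub = subpheno_of.get(s)
                if exclude and sub in exclude:
                    return False
                if include and sub not in include:
                    return False
                return True

            kept = {s for s in phenotypes if keep_sample(s)}
            calls = [c for c in calls if c.sample_id in kept]
            phenotypes = {s: p for s, p in phenotypes.items() if s in kept}
        genes = io.load_gene_models(config.gene_models_path)
        gene_map = {g.gene_id: g for g in genes}
        masks = MaskSet(
            telomeres=io.load_bed(config.telomere_bed) if config.telomere_bed else (),
            centromeres=io.load_bed(config.centromere_bed) if config.centromere_bed else (),
            segdups=io.load_bed(config.segdup_bed) if config.segdup_bed else (),
            probes=io.load_probe_table(config.probe_path) if config.probe_path else None,
        )
        timings[stage] = time.time() - t0

        # ---------------- QC ----------------
        stage = "qc"
        t0 = time.time()
        n_controls = sum(1 for p in phenotypes.values() if p == "control")
        calls = qc.compute_internal_maf(
            calls, n_controls=n_controls, reciprocal_threshold=config.reciprocal_threshold
        )
        passed, report = qc.apply_qc(calls, masks, config.qc_params())
        pd.DataFrame(report.to_rows()).to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
        results["qc_report"] = report
        timings[stage] = time.time() - t0

        # ---------------- CNV association ----------------
        stage = "cnv_test"
        t0 = time.time()
        targets = [(g.gene_id, g.interval) for g in genes]
        counts = assoc.gene_overlap_counts(passed, targets)
        perm = assoc.permutation_gene_test(
            counts,
            phenotypes,
            n_perm=config.n_perm,
            seed=config.seed,
            study_of=study_of if config.study_stratified else None,
        )
        cnv_frame = perm.to_frame().rename(columns={"target": "gene"})
        cnv_frame.to_csv(out_dir / "cnv_gene_tests.tsv", sep="\t", index=False)
        results["cnv_tests"] = cnv_frame

        sig_genes = cnv_frame.loc[cnv_frame["emp2"] < config.cnv_sig_threshold, "gene"]
        loci = assoc.merge_significant_loci(list(sig_genes), gene_map, passed)
        pd.DataFrame(
            [
                {
                    "locus": l.locus_id,
                    "chrom": l.interval.chrom,
                    "start": l.interval.start,
                    "end": l.interval.end,
                    "n_genes": len(l.member_genes),
                    "genes": ",".join(l.member_genes),
                }
                for l in loci
            ]
        ).to_csv(out_dir / "loci.tsv", sep="\t", index=False)
        results["loci"] = loci

        if config.regions_bed:
            regions, labels = io.load_bed(config.regions_bed, names=True)
            region_perm = assoc.syndrome_region_test(
                passed,
                list(zip(labels, regions)),
                phenotypes,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            region_perm.to_frame().rename(columns={"target": "region"}).to_csv(
                out_dir / "region_tests.tsv", sep="\t", index=False
            )
            results["region_tests"] = region_perm
        timings[stage] = time.time() - t0

        # ---------------- gene-set burden ----------------
        if config.gene_sets_path:
            stage = "cnv_burden"
            t0 = time.time()
            gene_sets = io.load_gene_sets(config.gene_sets_path)
            table = assoc.build_burden_table(passed, gene_map, phenotypes, study_of)
            burden_rows = []
            for name, members in gene_sets.items():
                if not members:
                    continue
                r = assoc.geneset_burden_logistic(table, members, set_name=name)
                burden_rows.append(
                    {
                        "gene_set": r.gene_set,
                        "odds_ratio": r.odds_ratio,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "p_value": r.p_value,
                        "n_case": r.n_case,
                        "n_control": r.n_control,
                        "error": r.error or "",
                    }
                )
            pd.DataFrame(burden_rows).to_csv(out_dir / "burden.tsv", sep="\t", index=False)
            results["burden"] = burden_rows
            timings[stage] = time.time() - t0

        # ---------------- DNV ----------------
        dnv_frame = None
        if config.dnv_path and config.rates_path:
            stage = "dnv_test"
            t0 = time.time()
            records = io.load_dnv_table(config.dnv_path)
            records = dnv.filter_dnvs(records)
            rates = io.load_rate_table(config.rates_path)
            external = None
            if config.external_dnv_p_path:
                ext = pd.read_csv(config.external_dnv_p_path, sep="\t")
                external = dict(zip(ext["gene"], ext["p"]))
            n_genes_corr = config.dnv_n_genes or len(gene_map)
            dnv_results = dnv.dnv_gene_tests(
                records,
                rates,
                n_trios=config.n_trios,
                run_severity=config.run_severity,
                external_p=external,
                n_genes=n_genes_corr,
                seed=config.seed,
            )
            dnv_frame = pd.DataFrame(
                [
                    {
                        "gene": r.gene_id,
                        "n_ptv": r.n_ptv,
                        "n_missense": r.n_missense,
                        "n_nsdnv": r.n_nsdnv,
                        "p_poisson": r.p_poisson,
                        "p_dnv": r.p_dnv,
                        "p_bonferroni": r.p_bonferroni,
                    }
                    for r in dnv_results.values()
                ]
            )
            dnv_frame.to_csv(out_dir / "dnv_gene_tests.tsv", sep="\t", index=False)
            results["dnv_tests"] = dnv_frame
            timings[stage] = time.time() - t0

        # ---------------- integration ----------------
        stage = "integrate"
        t0 = time.time()
        loeuf = {g.gene_id: g.loeuf for g in genes if g.loeuf is not None}
        final = integrate.assemble_results(
            cnv_frame,
            dnv_frame,
            loeuf=loeuf,
            universe=[g.gene_id for g in genes],
            alpha=config.alpha,
            cnv_sig_threshold=config.cnv_sig_threshold,
            dnv_n_genes=config.dnv_n_genes or len(gene_map),
            ihw_config=integrate.IHWConfig(
                n_bins=config.ihw_bins,
                n_folds=config.ihw_folds,
                alpha=config.alpha,
                seed=config.seed,
            ),
        )
        final.to_csv(out_dir / "gene_results.tsv", sep="\t", index=False)
        results["gene_results"] = final
        timings[stage] = time.time() - t0

        # ---------------- expression ----------------
        if config.expression_path and config.expression_samples_path:
            stage = "expression"
            t0 = time.time()
            values = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            meta = pd.read_csv(config.expression_samples_path, sep="\t", index_col=0)
            expr = expression.ExpressionMatrix(values=values, samples=meta)
            stage_summary = expression.stage_means_and_ranks(expr)
            stage_summary.to_csv(out_dir / "expression_stages.tsv", sep="\t")
            results["expression_stages"] = stage_summary
            de_frames = []
            for organ_b in ("kidney", "liver"):
                if (meta["organ"] == organ_b).any():
                    de = expression.timecourse_de(expr, organ_a="heart", organ_b=organ_b)
                    de = de.rename(columns={c: f"{c}_{organ_b}" for c in de.columns})
                    de_frames.append(de)
            if de_frames:
                de_all = pd.concat(de_frames, axis=1)
                deg_cols = [c for c in de_all.columns if c.startswith("deg_")]
                de_all["deg"] = de_all[deg_cols].fillna(False).any(axis=1)
                de_all.to_csv(out_dir / "expression_de.tsv", sep="\t")
                results["expression_de"] = de_all
            timings[stage] = time.time() - t0

        # ---------------- network ----------------
        if config.ppi_path:
            stage = "network"
            t0 = time.time()
            edges = io.load_edge_list(config.ppi_path)
            seeds = final.loc[final["q_bh"] < config.alpha, "gene"].tolist()
            clusters = []
            if seeds:
                g = network.build_seed_network(seeds, edges)
                clusters = network.cluster_network(
                    g,
                    n_perm=config.network_n_perm,
                    seed=config.seed,
                    k=config.clique_k,
                )
            case_counts = dict(zip(final["gene"], final["case"]))
            control_counts = dict(zip(final["gene"], final["control"]))
            cluster_rows = []
            enrich_frames = []
            gene_sets = (
                io.load_gene_sets(config.gene_sets_path) if config.gene_sets_path else {}
            )
            for cl in clusters:
                contrast_p = network.cluster_cnv_contrast(cl, case_counts, control_counts)
                cluster_rows.append(
                    {
                        "cluster": cl.cluster_id,
                        "n_members": len(cl.members),
                        "members": ",".join(cl.members),
                        "internal_edges": cl.internal_edges,
                        "perm_p": cl.perm_p,
                        "cnv_contrast_p": contrast_p,
                    }
                )
                if gene_sets and seeds:
                    enr = network.overrepresentation(cl.members, gene_sets, seeds)
                    enr.insert(0, "cluster", cl.cluster_id)
                    enrich_frames.append(enr)
            pd.DataFrame(cluster_rows).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
            results["clusters"] = clusters
            if enrich_frames:
                pd.concat(enrich_frames).to_csv(
                    out_dir / "cluster_enrichment.tsv", sep="\t", index=False
                )
            timings[stage] = time.time() - t0

        # ---------------- manifest ----------------
        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "n_samples": len(phenotypes),
            "n_cases": sum(1 for p in phenotypes.values() if p == "case"),
            "n_controls": n_controls,
            "n_rejected_rows": len(rejections),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
        return results
    except StageError:
        raise
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc
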