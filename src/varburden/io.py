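"""Readers and writers for the tabular formats the pipeline consumes.

Supported dialects for interval tables:

* ``"one-based-inclusive"`` (default) — typical CNV-call exports; a row
  ``start=101, end=200`` becomes internal ``[100, 200)``.
* ``"zero-based-half-open"`` — BED-style; stored as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    AUTOSOMES,
    CNVCall,
    DNVRecord,
    GeneModel,
    GenomicInterval,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

DIALECTS = ("one-based-inclusive", "zero-based-half-open")


@dataclass
class Rejection:
    """A rejected input row with its zero-based row index and a reason."""

    row: int
    reason: str


def _to_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "one-based-inclusive":
        return start - 1, end
    if dialect == "zero-based-half-open":
        return start, end
    raise ValueError(f"unknown coordinate dialect: {dialect!r}")


def _from_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "one-based-inclusive":
        return start + 1, end
    if dialect == "zero-based-half-open":
        return start, end
    raise ValueError(f"unknown coordinate dialect: {dialect!r}")


def load_cnv_table(
    path: str | Path,
    dialect: str = "one-based-inclusive",
    autosome_only: bool = True,
) -> tuple[list[CNVCall], list[Rejection]]:
    """Load a CNV call TSV into :class:`CNVCall` objects.

    Required columns: chrom, start, end, type, sample, phenotype, study.
    Optional: subphenotype, probe_count, internal_maf.  Row order is
    preserved; malformed rows are returned as :class:`Rejection` entries
    rather than raising.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "start", "end", "type", "sample", "phenotype", "study"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CNV table missing columns: {sorted(missing)}")

    calls: list[CNVCall] = []
    rejections: list[Rejection] = []
    for i, row in enumerate(df.itertuples(index=False)):
        chrom = normalize_chrom(row.chrom)
        if autosome_only and chrom not in AUTOSOMES:
            rejections.append(Rejection(i, "non-autosomal"))
            continue
        try:
            start, end = _to_internal(int(row.start), int(row.end), dialect)
            interval = GenomicInterval(chrom, start, end)
        except (ValueError, TypeError):
            rejections.append(Rejection(i, "invalid interval"))
            continue
        cnv_type = str(row.type).strip().upper()
        if cnv_type not in ("DEL", "DUP"):
            rejections.append(Rejection(i, f"unknown type {row.type!r}"))
            continue
        phenotype = str(row.phenotype).strip().lower()
        if phenotype not in ("case", "control"):
            rejections.append(Rejection(i, f"unknown phenotype {row.phenotype!r}"))
            continue
        sub = getattr(row, "subphenotype", None)
        if sub is not None and (pd.isna(sub) or sub == ""):
            sub = None
        probe_count = getattr(row, "probe_count", None)
        probe_count = (
            int(probe_count) if probe_count is not None and not pd.isna(probe_count)
            else None
        )
        maf = getattr(row, "internal_maf", None)
        maf = float(maf) if maf is not None and not pd.isna(maf) else None
        calls.append(
            CNVCall(
                interval=interval,
                cnv_type=cnv_type,
                sample_id=str(row.sample),
                phenotype=phenotype,
                study_id=str(row.study),
                subphenotype=sub,
                probe_count=probe_count,
                internal_maf=maf,
            )
        )
    for rej in rejections:
        logger.info("rejected CNV row %d: %s", rej.row, rej.reason)
    return calls, rejections


def write_cnv_table(
    calls: Iterable[CNVCall],
    path: str | Path,
    dialect: str = "one-based-inclusive",
) -> None:
    rows = []
    for c in calls:
        start, end = _from_internal(c.interval.start, c.interval.end, dialect)
        rows.append(
            {
                "chrom": c.interval.chrom,
                "start": start,
                "end": end,
                "type": c.cnv_type,
                "sample": c.sample_id,
                "phenotype": c.phenotype,
                "study": c.study_id,
                "subphenotype": c.subphenotype if c.subphenotype else "",
                "probe_count": "" if c.probe_count is None else c.probe_count,
                "internal_maf": "" if c.internal_maf is None else c.internal_maf,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "type", "sample", "phenotype",
            "study", "subphenotype", "probe_count", "internal_maf",
        ],
    ).to_csv(path, sep="\t", index=False)


def load_bed(path: str | Path, names: bool = False):
    """Load a BED(3/4) file into intervals (optionally with a name column)."""
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            intervals.append(iv)
            labels.append(parts[3] if len(parts) > 3 else f"region_{lineno}")
    if names:
        return intervals, labels
    return intervals


def write_bed(
    regions: Iterable[GenomicInterval],
    path: str | Path,
    names: Optional[Sequence[str]] = None,
) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = f"\t{names[i]}" if names is not None else ""
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}{name}\n")


def load_probe_table(path: str | Path) -> dict[str, list[int]]:
    """Probe positions per chromosome from a TSV with columns chrom, pos."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"}.issubset(df.columns):
        raise ValueError("probe table must have columns 'chrom' and 'pos'")
    probes: dict[str, list[int]] = {}
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for chrom, sub in df.groupby("chrom"):
        probes[str(chrom)] = sorted(int(p) for p in set(sub["pos"]))
    return probes


def load_gene_models(path: str | Path, dialect: str = "zero-based-half-open") -> list[GeneModel]:
    """Gene models from a TSV with columns gene, chrom, start, end [, loeuf, oe_lof]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene model table missing columns: {sorted(required - set(df.columns))}")
    genes = []
    for row in df.itertuples(index=False):
        start, end = _to_internal(int(row.start), int(row.end), dialect)
        loeuf = getattr(row, "loeuf", None)
        loeuf = float(loeuf) if loeuf is not None and not pd.isna(loeuf) else None
        oe = getattr(row, "oe_lof", None)
        oe = float(oe) if oe is not None and not pd.isna(oe) else None
        genes.append(
            GeneModel(
                gene_id=str(row.gene),
                interval=GenomicInterval(str(row.chrom), start, end),
                loeuf=loeuf,
                oe_lof=oe,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "loeuf": "" if g.loeuf is None else g.loeuf,
            "oe_lof": "" if g.oe_lof is None else g.oe_lof,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "loeuf", "oe_lof"]).to_csv(
        path, sep="\t", index=False
    )


def load_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Load gene sets from a GMT file (name, description, members per line).

    Duplicate set names raise; duplicate members within a line are
    deduplicated; empty sets are kept with a warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            members = {g for g in parts[2:] if g}
            if not members:
                warnings.warn(f"gene set {name!r} is empty", stacklevel=2)
            sets[name] = members
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + sorted(set(members))) + "\n")


def load_dnv_table(path: str | Path) -> list[DNVRecord]:
    """DNV records from a TSV with columns sample, gene, consequence
    [, severity, maf, cohort]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "gene", "consequence"}
    if not required.issubset(df.columns):
        raise ValueError(f"DNV table missing columns: {sorted(required - set(df.columns))}")
    records = []
    for row in df.itertuples(index=False):
        severity = getattr(row, "severity", None)
        severity = float(severity) if severity is not None and not pd.isna(severity) else None
        maf = getattr(row, "maf", None)
        maf = float(maf) if maf is not None and not pd.isna(maf) else 0.0
        cohort = getattr(row, "cohort", None)
        cohort = str(cohort) if cohort is not None and not pd.isna(cohort) else "cohort0"
        records.append(
            DNVRecord(
                sample_id=str(row.sample),
                gene_id=str(row.gene),
                consequence_term=str(row.consequence).strip().lower(),
                severity=severity,
                population_maf=maf,
                cohort_id=cohort,
            )
        )
    return records


def write_dnv_table(records: Iterable[DNVRecord], path: str | Path) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "gene": r.gene_id,
            "consequence": r.consequence_term,
            "severity": "" if r.severity is None else r.severity,
            "maf": r.population_maf,
            "cohort": r.cohort_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample", "gene", "consequence", "severity", "maf", "cohort"]).to_csv(
        path, sep="\t", index=False
    )


def load_rate_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Per-gene per-class mutation rates from a TSV: gene, class, rate."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "class", "rate"}.issubset(df.columns):
        raise ValueError("rate table must have columns gene, class, rate")
    rates: dict[str, dict[str, float]] = {}
    for gene, cls, rate in zip(df["gene"], df["class"], df["rate"]):
        rates.setdefault(str(gene), {})[str(cls)] = float(rate)
    return rates


def write_rate_table(rates: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    rows = [
        {"gene": g, "class": cls, "rate": rate}
        for g, by_class in rates.items()
        for cls, rate in by_class.items()
    ]
    pd.DataFrame(rows, columns=["gene", "class", "rate"]).to_csv(path, sep="\t", index=False)


def load_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """PPI edges from a 2-column TSV (header optional, detected by content)."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed edge line {lineno}")
            if lineno == 1 and parts[0].lower() in ("gene_a", "source", "node1", "protein_a"):
                continue
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
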