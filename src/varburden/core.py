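"""Core domain types and interval arithmetic.

All genomic coordinates are held internally as 0-based half-open
``[start, end)`` intervals on autosomes labelled ``"1"`` .. ``"22"``
(any ``"chr"`` prefix is stripped on construction).  Input tables may use a
different convention; conversion happens in :mod:`varburden.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

AUTOSOMES = tuple(str(c) for c in range(1, 23))

CASE = "case"
CONTROL = "control"

DEL = "DEL"
DUP = "DUP"


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr``/``Chr`` prefix and surrounding whitespace."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: ``min(ov/len(a), ov/len(b))``.

    Symmetric; 0.0 for different chromosomes or half-open adjacency.
    """
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_intervals(regions: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list (adjacent merged)."""
    by_pos = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[GenomicInterval] = []
    for r in by_pos:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, r.end)
        else:
            merged.append(r)
    return merged


def fraction_covered(
    target: GenomicInterval, regions: Iterable[GenomicInterval]
) -> float:
    """Fraction of ``target`` covered by the union of ``regions``."""
    covered = 0
    for r in merge_intervals(regions):
        covered += target.overlap_length(r)
    return covered / target.length


@dataclass
class CNVCall:
    """One deletion/duplication call with provenance and QC state."""

    interval: GenomicInterval
    cnv_type: str
    sample_id: str
    phenotype: str
    study_id: str = "study0"
    subphenotype: Optional[str] = None
    probe_count: Optional[int] = None
    internal_maf: Optional[float] = None
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.cnv_type not in (DEL, DUP):
            raise ValueError(f"unknown CNV type: {self.cnv_type!r}")
        if self.phenotype not in (CASE, CONTROL):
            raise ValueError(f"unknown phenotype: {self.phenotype!r}")
        if self.probe_count is not None and self.probe_count < 0:
            raise ValueError("probe_count must be >= 0")
        if self.internal_maf is not None and not (0.0 <= self.internal_maf <= 1.0):
            raise ValueError("internal_maf must be in [0, 1]")

    @property
    def passed_qc(self) -> bool:
        return not self.qc_flags


@dataclass
class GeneModel:
    """A gene with optional constraint, mutation-rate and expression annotations."""

    gene_id: str
    interval: GenomicInterval
    loeuf: Optional[float] = None
    oe_lof: Optional[float] = None
    mutation_rates: Optional[Mapping[str, float]] = None
    mean_expression: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.loeuf is not None and self.loeuf <= 0:
            raise ValueError("loeuf must be > 0")
        if self.mutation_rates is not None:
            for cls, rate in self.mutation_rates.items():
                if not (0.0 < rate < 1.0):
                    raise ValueError(
                        f"mutation rate for {cls!r} must be in (0, 1): {rate}"
                    )


@dataclass
class MaskSet:
    """Genome masks (telomeres, centromeres, segmental duplications) and probes.

    ``probes`` maps chromosome label to a sorted array/list of probe positions.
    """

    telomeres: Sequence[GenomicInterval] = ()
    centromeres: Sequence[GenomicInterval] = ()
    segdups: Sequence[GenomicInterval] = ()
    probes: Optional[Mapping[str, Sequence[int]]] = None

    def __post_init__(self) -> None:
        if self.probes is not None:
            for chrom, pos in self.probes.items():
                pos = list(pos)
                if any(b <= a for a, b in zip(pos, pos[1:])):
                    raise ValueError(
                        f"probe positions on chromosome {chrom} must be "
                        "strictly increasing"
                    )

    def all_mask_regions(self) -> list[GenomicInterval]:
        return list(self.telomeres) + list(self.centromeres) + list(self.segdups)


@dataclass
class DNVRecord:
    """One de novo variant call in a proband."""

    sample_id: str
    gene_id: str
    consequence_term: str
    variant_class: Optional[str] = None
    severity: Optional[float] = None
    population_maf: float = 0.0
    cohort_id: str = "cohort0"

    def __post_init__(self) -> None:
        if not (0.0 <= self.population_maf <= 1.0):
            raise ValueError("population_maf must be in [0, 1]")
        if self.severity is not None and self.severity < 0:
            raise ValueError("severity must be >= 0")


@dataclass
class GeneResult:
    """Per-gene evidence ledger across the CNV and DNV analyses."""

    gene_id: str
    n_case_cnv: int = 0
    n_control_cnv: int = 0
    p_cnv_emp1: float = 1.0
    p_cnv_emp2: float = 1.0
    n_nsdnv: int = 0
    p_dnv: float = 1.0
    meta_p: float = 1.0
    q_bh: float = 1.0
    p_ihw: float = 1.0
    significant_in: str = "none"

    def __post_init__(self) -> None:
        for name in ("p_cnv_emp1", "p_cnv_emp2", "p_dnv", "meta_p", "q_bh", "p_ihw"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]: {v}")
        if self.p_cnv_emp2 < self.p_cnv_emp1:
            raise ValueError("p_cnv_emp2 must be >= p_cnv_emp1")


@dataclass
class Locus:
    """A merged locus spanning one or more member genes."""

    locus_id: str
    interval: GenomicInterval
    member_genes: Sequence[str]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError("locus must contain at least one gene")
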