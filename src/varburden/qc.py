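"""CNV quality control and internal-frequency filtering.

Produces the analysis-ready rare deletion set.  Filters are applied in a
fixed order (type -> size -> autosome -> mask -> probes -> MAF) so that
first-failure attribution in the report is deterministic; membership of the
passed set does not depend on the order.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import CNVCall, GenomicInterval, MaskSet, fraction_covered, merge_intervals

FILTER_NON_DELETION = "non_deletion"
FILTER_SIZE = "size"
FILTER_NON_AUTOSOME = "non_autosome"
FILTER_MASK = "mask"
FILTER_PROBES = "probes"
FILTER_MAF = "maf"

FILTER_ORDER = (
    FILTER_NON_DELETION,
    FILTER_SIZE,
    FILTER_NON_AUTOSOME,
    FILTER_MASK,
    FILTER_PROBES,
    FILTER_MAF,
)


@dataclass(frozen=True)
class QCParams:
    """Thresholds for the CNV QC gates.

    Size bounds are inclusive; the mask gate removes calls with strictly
    more than ``mask_fraction`` of their length covered by mask regions;
    the MAF gate keeps calls with internal frequency strictly below
    ``maf_threshold``.
    """

    min_size: int = 5_000
    max_size: int = 20_000_000
    min_probes: int = 10
    mask_fraction: float = 0.5
    maf_threshold: float = 0.01
    reciprocal_threshold: float = 0.5
    deletions_only: bool = True

    def __post_init__(self) -> None:
        if self.min_size >= self.max_size:
            raise ValueError("min_size must be < max_size")
        for name in ("mask_fraction", "maf_threshold", "reciprocal_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1): {v}")


@dataclass
class QCReport:
    """Per-filter removal counts, split by phenotype."""

    input: dict = field(default_factory=lambda: {"case": 0, "control": 0})
    removed: dict = field(default_factory=dict)  # filter -> {case: n, control: n}
    passed: dict = field(default_factory=lambda: {"case": 0, "control": 0})

    def total_input(self) -> int:
        return sum(self.input.values())

    def total_passed(self) -> int:
        return sum(self.passed.values())

    def total_removed(self) -> int:
        return sum(sum(v.values()) for v in self.removed.values())

    def reconciles(self) -> bool:
        return self.total_input() == self.total_passed() + self.total_removed()

    def to_rows(self) -> list[dict]:
        rows = [{"stage": "input", **self.input}]
        for name in FILTER_ORDER:
            if name in self.removed:
                rows.append({"stage": f"removed_{name}", **self.removed[name]})
        rows.append({"stage": "passed", **self.passed})
        return rows


def compute_internal_maf(
    cnvs: Sequence[CNVCall],
    n_controls: int,
    reciprocal_threshold: float = 0.5,
) -> list[CNVCall]:
    """Set ``internal_maf`` on every call from control carrier frequencies.

    For each CNV, the frequency is the number of *distinct control
    individuals* carrying a same-type CNV with reciprocal overlap strictly
    above the threshold, divided by ``n_controls``.  Deletions and
    duplications are matched separately.  A control call matches itself, so
    a singleton control CNV gets frequency ``1 / n_controls``.
    """
    if n_controls <= 0:
        raise ValueError("n_controls must be > 0")

    # index control calls by (type, chrom), sorted by start, for a sweep
    index: dict[tuple[str, str], list[CNVCall]] = defaultdict(list)
    for c in cnvs:
        if c.phenotype == "control":
            index[(c.cnv_type, c.interval.chrom)].append(c)
    starts: dict[tuple[str, str], list[int]] = {}
    for key, lst in index.items():
        lst.sort(key=lambda c: c.interval.start)
        starts[key] = [c.interval.start for c in lst]

    out = []
    for c in cnvs:
        key = (c.cnv_type, c.interval.chrom)
        carriers: set[str] = set()
        pool = index.get(key, [])
        if pool:
            # overlap requires start < c.end; min reciprocal overlap bounds
            # how far left a matching control can start, but a simple scan
            # over start < c.end with an end check is fast enough here
            hi = bisect.bisect_left(starts[key], c.interval.end)
            for other in pool[:hi]:
                if other.interval.end <= c.interval.start:
                    continue
                ov = c.interval.overlap_length(other.interval)
                rec = min(ov / c.interval.length, ov / other.interval.length)
                if rec > reciprocal_threshold:
                    carriers.add(other.sample_id)
        out.append(replace(c, internal_maf=len(carriers) / n_controls))
    return out


def _probe_count(call: CNVCall, masks: MaskSet) -> Optional[int]:
    if call.probe_count is not None:
        return call.probe_count
    if masks.probes is None:
        return None
    positions = masks.probes.get(call.interval.chrom)
    if positions is None:
        return 0
    lo = bisect.bisect_left(positions, call.interval.start)
    hi = bisect.bisect_left(positions, call.interval.end)
    return hi - lo


def apply_qc(
    cnvs: Sequence[CNVCall],
    masks: MaskSet,
    params: QCParams = QCParams(),
) -> tuple[list[CNVCall], QCReport]:
    """Apply the QC gates, returning passed calls and a reconciling report.

    Removed calls are returned nowhere; each input call's ``qc_flags`` is
    updated in the returned copies (passed calls have empty flags).  The
    MAF gate requires ``internal_maf`` to be populated (see
    :func:`compute_internal_maf`).
    """
    mask_union = merge_intervals(masks.all_mask_regions())
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for r in mask_union:
        by_chrom[r.chrom].append(r)

    report = QCReport()
    passed: list[CNVCall] = []
    for c in cnvs:
        report.input[c.phenotype] += 1
        reason = None
        if params.deletions_only and c.cnv_type != "DEL":
            reason = FILTER_NON_DELETION
        elif not (params.min_size <= c.interval.length <= params.max_size):
            reason = FILTER_SIZE
        elif not c.interval.is_autosomal():
            reason = FILTER_NON_AUTOSOME
        elif fraction_covered(c.interval, by_chrom.get(c.interval.chrom, [])) > params.mask_fraction:
            reason = FILTER_MASK
        else:
            n_probes = _probe_count(c, masks)
            if n_probes is None:
                raise ValueError(
                    "probe filter enabled but no probe_count on call and no "
                    "probe table in MaskSet"
                )
            if n_probes < params.min_probes:
                reason = FILTER_PROBES
            else:
                if c.internal_maf is None:
                    raise ValueError(
                        "internal_maf not computed; run compute_internal_maf first"
                    )
                if not (c.internal_maf < params.maf_threshold):
                    reason = FILTER_MAF
        if reason is None:
            passed.append(replace(c, qc_flags=set()))
            report.passed[c.phenotype] += 1
        else:
            report.removed.setdefault(reason, {"case": 0, "control": 0})
            report.removed[reason][c.phenotype] += 1
    return passed, report


def deletion_rate_contrast(cnvs: Iterable[CNVCall], samples: dict[str, str]):
    """Two-sided rank-sum comparison of per-individual deletion counts
    (cases vs controls); returns (case counts, control counts, p)."""
    from scipy.stats import mannwhitneyu

    counts: dict[str, int] = {s: 0 for s in samples}
    for c in cnvs:
        if c.cnv_type == "DEL" and c.sample_id in counts:
            counts[c.sample_id] += 1
    case = np.array([n for s, n in counts.items() if samples[s] == "case"])
    ctrl = np.array([n for s, n in counts.items() if samples[s] == "control"])
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both phenotypes required")
    if np.ptp(case) == 0 and np.ptp(ctrl) == 0 and set(case) == set(ctrl):
        return case, ctrl, 1.0  # degenerate all-tied comparison
    _, p = mannwhitneyu(case, ctrl, alternative="two-sided")
    return case, ctrl, float(p)
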