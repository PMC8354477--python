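"""Organ time-course expression: stage summaries and differential testing.

Developmental stages are derived from sample time in days post-conception:
early development spans 4-8 weeks, maturation 9-20 weeks, and infant/adult
from birth onward.  Level analysis uses raw expression means per stage;
differential testing fits log2(CPM + 1) on a polynomial of time with organ
main/interaction terms and F-tests the organ-dependent terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EARLY = "early_development"
MATURATION = "maturation"
INFANT_ADULT = "infant_adult"
STAGES = (EARLY, MATURATION, INFANT_ADULT)

DAYS_PER_WEEK = 7
#: stage boundaries in days post-conception (inclusive), birth at ~38 wpc
STAGE_BOUNDS = {
    EARLY: (4 * DAYS_PER_WEEK, 8 * DAYS_PER_WEEK),
    MATURATION: (9 * DAYS_PER_WEEK, 20 * DAYS_PER_WEEK),
    INFANT_ADULT: (38 * DAYS_PER_WEEK, None),
}


def stage_of(time_days: float) -> Optional[str]:
    """Developmental stage for a time point, or None if between stages."""
    for stage, (lo, hi) in STAGE_BOUNDS.items():
        if time_days >= lo and (hi is None or time_days <= hi):
            return stage
    return None


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample organ/time metadata.

    ``values``: DataFrame indexed by gene, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``organ`` and
    ``time_days`` (and optionally ``replicate``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        if not {"organ", "time_days"}.issubset(self.samples.columns):
            raise ValueError("sample metadata needs 'organ' and 'time_days'")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0")

    def subset_organ(self, organ: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["organ"] == organ]
        keep = [s for s in self.values.columns if s in set(keep)]
        return ExpressionMatrix(self.values[keep], self.samples.loc[keep])


def stage_means_and_ranks(expr: ExpressionMatrix, organ: str = "heart") -> pd.DataFrame:
    """Mean expression and within-stage percentile rank per gene per stage.

    Returns a DataFrame indexed by gene with ``mean_<stage>``,
    ``rank_<stage>`` (average-rank percentile in (0, 1]) and
    ``top_quartile_<stage>`` (rank >= 0.75) columns.
    """
    sub = expr.subset_organ(organ)
    out = pd.DataFrame(index=sub.values.index)
    stages = sub.samples["time_days"].map(stage_of)
    for stage in STAGES:
        cols = [s for s in sub.values.columns if stages[s] == stage]
        if not cols:
            raise ValueError(f"no samples in stage {stage!r}")
        means = sub.values[cols].mean(axis=1)
        ranks = stats.rankdata(means.to_numpy(), method="average") / len(means)
        out[f"mean_{stage}"] = means
        out[f"rank_{stage}"] = ranks
        out[f"top_quartile_{stage}"] = ranks >= 0.75
    return out


def _design(time: np.ndarray, organ_b: np.ndarray, degree: int) -> tuple[np.ndarray, int]:
    """Full design matrix and the number of organ-dependent columns."""
    t = (time - time.mean()) / max(time.std(), 1e-12)
    cols = [np.ones_like(t)]
    for d in range(1, degree + 1):
        cols.append(t**d)
    organ_cols = [organ_b.astype(float)]
    for d in range(1, degree + 1):
        organ_cols.append(organ_b * t**d)
    X = np.column_stack(cols + organ_cols)
    return X, len(organ_cols)


def timecourse_de(
    expr: ExpressionMatrix,
    organ_a: str = "heart",
    organ_b: str = "liver",
    degree: int = 2,
    r2_threshold: float = 0.50,
    alpha: float = 0.01,
    min_cpm: float = 0.5,
    min_samples: int = 5,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Organ-contrast time-course differential expression.

    Genes failing the abundance gate (CPM > ``min_cpm`` in at least
    ``min_samples`` samples) are excluded; organ/time points with fewer
    than ``min_replicates`` replicates are dropped.  Per gene, an OLS fit
    of log2(CPM+1) on a degree-``degree`` time polynomial with organ and
    organ-by-time terms yields the model R^2 and an F-test p for the
    organ-dependent terms; p is Bonferroni-corrected over tested genes and
    a gene is flagged DEG when R^2 > ``r2_threshold`` and corrected
    p < ``alpha``.
    """
    meta = expr.samples
    keep = meta.index[meta["organ"].isin([organ_a, organ_b])]
    keep = [s for s in expr.values.columns if s in set(keep)]
    meta = meta.loc[keep]
    # drop organ/time combinations with too few replicates
    grp = meta.groupby(["organ", "time_days"]).size()
    ok = {k for k, n in grp.items() if n >= min_replicates}
    keep = [s for s in keep if (meta.loc[s, "organ"], meta.loc[s, "time_days"]) in ok]
    meta = meta.loc[keep]
    if meta["time_days"].nunique() < 2:
        raise ValueError("fewer than 2 usable time points")

    values = expr.values[keep]
    gate = (values > min_cpm).sum(axis=1) >= min_samples
    tested = values.loc[gate]

    time = meta["time_days"].to_numpy(dtype=float)
    organ_ind = (meta["organ"] == organ_a).to_numpy()
    X, q = _design(time, organ_ind, degree)
    X_red = X[:, : X.shape[1] - q]
    n, k = X.shape

    Y = np.log2(tested.to_numpy(dtype=float) + 1.0).T  # samples x genes
    beta_full, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid_full = Y - X @ beta_full
    rss_full = (resid_full**2).sum(axis=0)
    beta_red, _, _, _ = np.linalg.lstsq(X_red, Y, rcond=None)
    rss_red = ((Y - X_red @ beta_red) ** 2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss_full / tss, 0.0)
        f = ((rss_red - rss_full) / q) / (rss_full / (n - k))
    f = np.where(np.isfinite(f), f, 0.0)
    p = stats.f.sf(np.maximum(f, 0.0), q, n - k)
    p_bonf = np.minimum(1.0, p * len(tested))

    out = pd.DataFrame(
        {
            "r2": np.clip(r2, 0.0, 1.0),
            "p": p,
            "p_bonferroni": p_bonf,
            "deg": (r2 > r2_threshold) & (p_bonf < alpha),
        },
        index=tested.index,
    )
    out.index.name = "gene"
    return out


STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_code(p: Optional[float]) -> str:
    if p is None or not np.isfinite(p):
        return "ns"
    for cutoff, stars in STAR_LEVELS:
        if p < cutoff:
            return stars
    return "ns"


def binned_distribution_contrast(
    values: Mapping[str, float],
    bin_of: Mapping[str, str],
    reference: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Two-sided rank-sum test of each bin's values against the reference
    (default: all genes).  Bins with < 2 members get ``p = NaN``/"ns"."""
    vals = pd.Series(values, dtype=float)
    ref = np.asarray(reference, dtype=float) if reference is not None else vals.to_numpy()
    rows = []
    for b in sorted(set(bin_of.values())):
        members = vals[[g for g, bb in bin_of.items() if bb == b and g in vals.index]]
        if len(members) < 2:
            warnings.warn(f"bin {b!r} has fewer than 2 members", stacklevel=2)
            rows.append({"bin": b, "n": len(members), "p": np.nan, "stars": "ns"})
            continue
        _, p = stats.mannwhitneyu(members.to_numpy(), ref, alternative="two-sided")
        rows.append({"bin": b, "n": len(members), "p": float(p), "stars": star_code(p)})
    return pd.DataFrame(rows)
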