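"""Combine CNV and DNV evidence per gene and correct for multiple testing.

Fisher's method with two components (chi-square, 4 df) merges the two
evidence streams; Benjamini-Hochberg q-values select network seeds; and a
covariate-weighted Bonferroni correction learns per-bin weights from a
constraint covariate (LOEUF) by cross-validated grid search over the
weight simplex, subject to the exact budget ``sum_b m_b * w_b = m`` so the
family-wise error rate stays controlled.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_TINY = np.finfo(float).tiny


def fisher_combine(p_cnv: float, p_dnv: float) -> float:
    """Fisher combination of two p-values (chi-square upper tail, 4 df)."""
    ps = []
    for p in (p_cnv, p_dnv):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {p}")
        if p == 0.0:
            warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
            p = _TINY
        ps.append(p)
    x = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(x, df=4))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


@dataclass(frozen=True)
class IHWConfig:
    """Settings for the covariate-weighted Bonferroni correction."""

    n_bins: int = 5
    n_folds: int = 5
    alpha: float = 0.05
    covariate: str = "loeuf"
    seed: Optional[int] = None
    grid_total: int = 8  # integer grid resolution over the weight simplex

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def _weight_candidates(n_bins: int, total: int) -> np.ndarray:
    """All integer compositions of ``total`` over ``n_bins`` parts, the
    uniform candidate first."""
    comps = [
        c
        for c in itertools.product(range(total + 1), repeat=n_bins)
        if sum(c) == total
    ]
    arr = np.array(comps, dtype=float)
    uniform = np.full(n_bins, total / n_bins)
    order = np.argsort(np.abs(arr - uniform).sum(axis=1), kind="mergesort")
    return arr[order]


def ihw_bonferroni(
    p: Sequence[float],
    covariate: Sequence[float],
    config: IHWConfig = IHWConfig(),
    full_output: bool = False,
):
    """Covariate-weighted Bonferroni correction.

    Genes are binned by covariate quantiles; per cross-validation fold,
    bin weights are chosen on the complement to maximize rejections at
    ``alpha`` under the budget ``sum_b m_b * w_b = m``, and applied to the
    held-out genes as ``p_ihw = min(1, m * p / w)``.  A constant covariate
    degrades to plain Bonferroni with a warning.

    Returns ``(weights_per_gene, p_ihw)``; with ``full_output`` also the
    per-fold weight vectors and the bin assignment.
    """
    p = np.asarray(p, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if p.shape != cov.shape:
        raise ValueError("p and covariate must have equal length")
    m = p.size
    if m == 0:
        raise ValueError("empty input")
    if np.all(cov == cov[0]):
        warnings.warn("constant covariate; falling back to plain Bonferroni", stacklevel=2)
        w = np.ones(m)
        out = (w, np.minimum(1.0, m * p))
        return out + (None, None) if full_output else out

    n_bins = min(config.n_bins, len(np.unique(cov)))
    # quantile bins on the covariate (ties collapse edges)
    edges = np.unique(np.quantile(cov, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, cov, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    if n_bins < 2:
        warnings.warn("covariate binning degenerate; plain Bonferroni", stacklevel=2)
        w = np.ones(m)
        out = (w, np.minimum(1.0, m * p))
        return out + (None, None) if full_output else out

    rng = np.random.default_rng(config.seed)
    folds = rng.integers(0, config.n_folds, size=m)
    candidates = _weight_candidates(n_bins, config.grid_total)

    weights = np.ones(m)
    fold_weights = []
    for f in range(config.n_folds):
        train = folds != f
        m_b = np.array([(bins == b).sum() for b in range(n_bins)], dtype=float)
        # scale each candidate so the full-universe budget holds exactly
        denom = candidates @ m_b
        valid = denom > 0
        cand = candidates[valid] * (m / denom[valid])[:, None]
        # rejections on training data: count p <= alpha * w_b / m per bin
        sorted_train = [np.sort(p[train & (bins == b)]) for b in range(n_bins)]
        thresholds = config.alpha * cand / m  # (n_cand, n_bins)
        rejections = np.zeros(cand.shape[0], dtype=int)
        for b in range(n_bins):
            rejections += np.searchsorted(sorted_train[b], thresholds[:, b], side="right")
        best = cand[int(np.argmax(rejections))]
        fold_weights.append(best)
        test = ~train
        weights[test] = best[bins[test]]

    with np.errstate(divide="ignore"):
        p_ihw = np.where(weights > 0, np.minimum(1.0, m * p / weights), 1.0)
    if full_output:
        return weights, p_ihw, fold_weights, bins
    return weights, p_ihw


def assemble_results(
    cnv_results: Optional[pd.DataFrame],
    dnv_results: Optional[pd.DataFrame],
    loeuf: Optional[Mapping[str, float]] = None,
    universe: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    cnv_sig_threshold: float = 0.05,
    dnv_n_genes: int = 18_272,
    ihw_config: IHWConfig = IHWConfig(),
) -> pd.DataFrame:
    """Join per-gene CNV and DNV evidence into the final result table.

    ``cnv_results`` columns: gene, case, control, emp1, emp2.
    ``dnv_results`` columns: gene, n_nsdnv, p_dnv.
    Genes missing from one side carry p = 1 there.  The significance
    label records which per-test thresholds the gene met (emp2 <
    ``cnv_sig_threshold`` for CNV; Bonferroni-corrected p_dnv < alpha for
    DNV), independent of the combined call.
    """
    cnv = (
        cnv_results.set_index("gene")
        if cnv_results is not None and len(cnv_results)
        else pd.DataFrame(columns=["case", "control", "emp1", "emp2"])
    )
    dnv = (
        dnv_results.set_index("gene")
        if dnv_results is not None and len(dnv_results)
        else pd.DataFrame(columns=["n_nsdnv", "p_dnv"])
    )
    if cnv.index.has_duplicates or dnv.index.has_duplicates:
        raise ValueError("duplicate gene ids in results")

    if universe is None:
        genes = sorted(set(cnv.index) | set(dnv.index))
    else:
        genes = list(universe)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene ids in universe")

    rows = []
    for g in genes:
        in_cnv = g in cnv.index
        in_dnv = g in dnv.index
        p_cnv = float(cnv.loc[g, "emp1"]) if in_cnv else 1.0
        emp2 = float(cnv.loc[g, "emp2"]) if in_cnv else 1.0
        p_dnv = float(dnv.loc[g, "p_dnv"]) if in_dnv else 1.0
        cnv_sig = emp2 < cnv_sig_threshold
        dnv_sig = min(1.0, dnv_n_genes * p_dnv) < alpha
        label = {
            (True, True): "both",
            (True, False): "cnv",
            (False, True): "dnv",
            (False, False): "none",
        }[(cnv_sig, dnv_sig)]
        rows.append(
            {
                "gene": g,
                "case": int(cnv.loc[g, "case"]) if in_cnv else 0,
                "control": int(cnv.loc[g, "control"]) if in_cnv else 0,
                "p_cnv": p_cnv,
                "p_cnv_emp2": emp2,
                "n_nsdnv": int(dnv.loc[g, "n_nsdnv"]) if in_dnv else 0,
                "p_dnv": p_dnv,
                "significant": label,
                "meta_p": fisher_combine(p_cnv, p_dnv),
                "loeuf": (loeuf or {}).get(g, np.nan),
            }
        )
    df = pd.DataFrame(rows)
    df["q_bh"] = bh_adjust(df["meta_p"].to_numpy())
    cov = df["loeuf"].to_numpy(dtype=float)
    if np.isnan(cov).all():
        df["ihw_weight"] = 1.0
        df["p_ihw"] = np.minimum(1.0, len(df) * df["meta_p"])
    else:
        filled = np.where(np.isnan(cov), np.nanmedian(cov), cov)
        w, p_ihw = ihw_bonferroni(df["meta_p"].to_numpy(), filled, ihw_config)
        df["ihw_weight"] = w
        df["p_ihw"] = p_ihw
    return df.sort_values("meta_p", kind="mergesort").reset_index(drop=True)
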