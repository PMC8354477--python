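"""Seed-restricted PPI network, overlapping sub-clusters and enrichment.

Sub-clusters come from k-clique percolation (overlapping, deterministic);
their significance is assessed against degree-preserving edge rewiring:
for each rewired graph the densest same-or-larger community's internal
edge count is the null value.  Over-representation of gene sets within a
cluster uses the hypergeometric tail with a standardized z and the product
combined score |ln p| * z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SubCluster:
    cluster_id: str
    members: tuple
    internal_edges: int
    perm_p: float

    def __post_init__(self) -> None:
        if len(self.members) < 5:
            raise ValueError("sub-cluster must have >= 5 members")


def build_seed_network(
    seeds: Iterable[str], edges: Iterable[tuple[str, str]]
) -> nx.Graph:
    """Induced graph on the seed genes only (strictly seeded).

    Duplicate and reversed edges are merged; self-loops are dropped;
    isolated seeds remain as nodes.
    """
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("empty seed list")
    g = nx.Graph()
    g.add_nodes_from(sorted(seed_set))
    for a, b in edges:
        if a == b:
            continue
        if a in seed_set and b in seed_set:
            g.add_edge(a, b)
    return g


def _communities(g: nx.Graph, k: int) -> list[frozenset]:
    comms = [frozenset(c) for c in nx.community.k_clique_communities(g, k)]
    return sorted(comms, key=lambda c: (-len(c), sorted(c)))


def _internal_edges(g: nx.Graph, nodes: frozenset) -> int:
    return g.subgraph(nodes).number_of_edges()


def _best_subgraph_edges(g: nx.Graph, nodes, s: int) -> int:
    """Internal edge count of a dense s-node subset of ``nodes`` (the s
    highest-degree members; deterministic tie-break by label)."""
    sub = g.subgraph(nodes)
    if len(nodes) <= s:
        return sub.number_of_edges()
    chosen = [n for n, _ in sorted(sub.degree, key=lambda kv: (-kv[1], str(kv[0])))[:s]]
    return g.subgraph(chosen).number_of_edges()


def cluster_network(
    g: nx.Graph,
    n_perm: int = 1_000,
    seed: Optional[int] = None,
    k: int = 3,
    min_size: int = 5,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> list[SubCluster]:
    """Overlapping sub-clusters with permutation significance.

    Communities are k-clique-percolation components; the null model is
    degree-preserving rewiring.  For each observed cluster of size s, the
    null statistic per rewired graph is the densest s-node edge count
    found among that graph's communities of size >= s (0 if none).
    Clusters below ``min_size`` members or with p >= ``alpha`` are
    dropped unless ``keep_all``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = [c for c in _communities(g, k) if len(c) >= min_size]
    if not observed:
        return []
    obs_edges = [_internal_edges(g, c) for c in observed]
    sizes = [len(c) for c in observed]

    rng = np.random.default_rng(seed)
    n_edges = g.number_of_edges()
    exceed = np.zeros(len(observed), dtype=int)
    for _ in range(n_perm):
        perm = g.copy()
        if n_edges >= 2:
            try:
                nx.double_edge_swap(
                    perm,
                    nswap=2 * n_edges,
                    max_tries=40 * n_edges + 100,
                    seed=int(rng.integers(2**31)),
                )
            except (nx.NetworkXError, nx.NetworkXAlgorithmError):
                pass  # partial rewiring is an acceptable null draw
        perm_comms = _communities(perm, k)
        for i, s in enumerate(sizes):
            null_val = max(
                (_best_subgraph_edges(perm, c, s) for c in perm_comms if len(c) >= s),
                default=0,
            )
            if null_val >= obs_edges[i]:
                exceed[i] += 1
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    clusters = [
        SubCluster(
            cluster_id=f"cluster_{i + 1}",
            members=tuple(sorted(c)),
            internal_edges=e,
            perm_p=float(p),
        )
        for i, (c, e, p) in enumerate(zip(observed, obs_edges, pvals))
    ]
    if keep_all:
        return clusters
    return [c for c in clusters if c.perm_p < alpha]


def cluster_cnv_contrast(
    cluster: SubCluster,
    case_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    min_size: int = 5,
) -> float:
    """Two-sided rank-sum p comparing member genes' case vs control CNV
    counts; all-tied inputs give p = 1 with a warning."""
    if len(cluster.members) < min_size:
        raise ValueError("cluster below size gate")
    case = np.array([case_counts.get(m, 0) for m in cluster.members], dtype=float)
    ctrl = np.array([control_counts.get(m, 0) for m in cluster.members], dtype=float)
    if np.ptp(np.concatenate([case, ctrl])) == 0:
        warnings.warn("all counts tied; p = 1", stacklevel=2)
        return 1.0
    _, p = stats.mannwhitneyu(case, ctrl, alternative="two-sided")
    return float(p)


def overrepresentation(
    cluster_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a cluster.

    Returns per-set p (upper tail), standardized z, combined score
    ``|ln p| * z`` and BH FDR display tiers.  Sets disjoint from the
    universe are skipped with a warning.
    """
    uni = set(universe)
    members = set(cluster_genes) & uni
    M, N = len(uni), len(members)
    rows = []
    for name, genes in gene_sets.items():
        in_uni = set(genes) & uni
        if not in_uni:
            warnings.warn(f"gene set {name!r} disjoint from universe; skipped", stacklevel=2)
            continue
        n = len(in_uni)
        k = len(in_uni & members)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        mean = N * n / M
        var = N * n * (M - n) * (M - N) / (M**2 * (M - 1)) if M > 1 else 0.0
        z = (k - mean) / np.sqrt(var) if var > 0 else 0.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": n,
                "p": p,
                "z": float(z),
                "combined_score": float(abs(np.log(max(p, np.finfo(float).tiny))) * z),
            }
        )
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p", "z", "combined_score"])
    if len(df):
        from .integrate import bh_adjust

        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df["tier"] = pd.cut(
            df["fdr"],
            bins=[0, 0.05, 0.10, 1.0],
            labels=["<5%", "5-10%", ">10%"],
            include_lowest=True,
        )
        df = df.sort_values("combined_score", ascending=False, kind="mergesort").reset_index(drop=True)
    return df
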