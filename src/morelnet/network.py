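"""Signed Spearman co-occurrence networks over genera.

Edges connect genus pairs whose rank correlation is both strong
(|rho| >= 0.6 by default) and significant after Benjamini-Hochberg
adjustment (q < 0.05). The graph is undirected and signed by the
correlation's sign; node degree identifies hubs (degree >= 10 in the
field convention) and greedy modularity maximization extracts modules.

Spearman p-values use the t approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` when n >= 10 samples are available;
for smaller n an exact (all n! orderings when feasible) or seeded
Monte-Carlo permutation null is used instead, since the approximation is
poor there.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_matrix",
    "bh_adjust",
    "build_network",
    "network_metrics",
    "detect_modules",
    "hub_ranking",
    "CorrelationMatrix",
]


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho/p/q among genera, from n_samples columns."""

    genus_ids: list
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_samples: int
    constant_genera: list = field(default_factory=list)

    def pairs(self) -> pd.DataFrame:
        """Long-form table of unique unordered pairs (i < j)."""
        rows = []
        g = self.genus_ids
        for i, j in itertools.combinations(range(len(g)), 2):
            rows.append(
                {
                    "source": g[i],
                    "target": g[j],
                    "rho": self.rho.iat[i, j],
                    "p": self.p.iat[i, j],
                    "q": self.q.iat[i, j],
                }
            )
        return pd.DataFrame(rows)


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} (p_(j) * m / j)`` over the sorted p-values,
    capped at 1 and mapped back to input order. *m* defaults to the
    number of p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    if m is None:
        m = n
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _standardized_midranks(x: np.ndarray) -> np.ndarray:
    """Row-wise mid-ranks, centered and scaled to unit norm (zero rows for constants)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    z = ranks / safe
    z[norms[:, 0] == 0] = 0.0
    return z


def spearman_matrix(abund: pd.DataFrame, p_mode: str = "auto",
                    seed: int | None = None, n_mc: int = 10_000) -> CorrelationMatrix:
    """All pairwise Spearman rank correlations among the table's genera.

    Rho is the Pearson correlation of mid-ranks (average-rank ties).
    ``p_mode`` is ``auto`` (t approximation for n >= 10, permutation
    below), ``t`` or ``permutation``. Constant genera get rho 0 / p 1 and
    are listed in ``constant_genera``. BH-adjusted q-values are computed
    over the C(G, 2) unique pairs.
    """
    genera = [str(g) for g in abund.index]
    x = abund.to_numpy(dtype=float)
    g, n = x.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    z = _standardized_midranks(x)
    rho = z @ z.T
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    constant = [genera[i] for i in range(g) if not z[i].any()]

    if p_mode == "auto":
        p_mode = "t" if n >= 10 else "permutation"
    if p_mode == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isnan(p)] = 0.0  # |rho| == 1 -> t = inf -> p = 0
    elif p_mode == "permutation":
        if math.factorial(n) <= n_mc:
            perms = np.array(list(itertools.permutations(range(n))))
        else:
            rng = np.random.default_rng(seed)
            perms = np.array([rng.permutation(n) for _ in range(n_mc)])
        b = len(perms)
        obs = np.abs(rho)
        exceed = np.zeros((g, g), dtype=np.int64)
        for perm in perms:
            c = z @ z[:, perm].T  # corr(row_i, permuted row_j)
            exceed += np.abs(c) >= obs - 1e-12
        p = (exceed + exceed.T) / 2.0  # symmetrize the asymmetric null draws
        p = (p + 1.0) / (b + 1.0)
        p = np.minimum(p, 1.0)
    else:
        raise ValueError(f"unknown p_mode: {p_mode!r}")

    # constant pairs are untestable
    for i in range(g):
        if not z[i].any():
            rho[i, :] = rho[:, i] = 0.0
            p[i, :] = p[:, i] = 1.0
            rho[i, i] = 1.0
    np.fill_diagonal(p, np.nan)

    iu = np.triu_indices(g, k=1)
    q_flat = bh_adjust(p[iu]) if len(iu[0]) else np.array([])
    q = np.full((g, g), np.nan)
    q[iu] = q_flat
    q = np.where(np.isnan(q), q.T, q)

    idx = pd.Index(genera)
    return CorrelationMatrix(
        genus_ids=genera,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        q=pd.DataFrame(q, index=idx, columns=idx),
        n_samples=n,
        constant_genera=constant,
    )


def build_network(cm: CorrelationMatrix, r_cutoff: float = 0.6, q_cutoff: float = 0.05,
                  keep_isolates: bool = False, abundance_means=None) -> nx.Graph:
    """Threshold a correlation matrix into a signed co-occurrence graph.

    An edge (i, j) is retained iff ``|rho_ij| >= r_cutoff`` (inclusive)
    and ``q_ij < q_cutoff`` (strict). Genera left with no edge are
    dropped unless ``keep_isolates``; an empty network is valid.
    Node attribute ``mean_abundance`` is attached when
    *abundance_means* (mapping genus -> mean relative abundance) is given.
    """
    g = nx.Graph()
    ids = cm.genus_ids
    if keep_isolates:
        g.add_nodes_from(ids)
    for i, j in itertools.combinations(range(len(ids)), 2):
        rho = float(cm.rho.iat[i, j])
        q = float(cm.q.iat[i, j])
        if abs(rho) >= r_cutoff and q < q_cutoff:
            g.add_edge(
                ids[i], ids[j],
                rho=rho, p=float(cm.p.iat[i, j]), q=q,
                sign="positive" if rho >= 0 else "negative",
            )
    if abundance_means is not None:
        for n in g.nodes:
            if n in abundance_means:
                g.nodes[n]["mean_abundance"] = float(abundance_means[n])
    return g


def network_metrics(net: nx.Graph) -> dict:
    """Whole-network summary statistics.

    average_neighbors = 2E/N; average_clustering averages the local
    clustering coefficient (0 for degree < 2 nodes); average_path_length
    averages shortest-path lengths over all connected pairs, i.e.
    per-component means weighted by each component's pair count. All
    metrics are NaN for an empty node set.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return {
            "n_nodes": 0, "n_edges": 0, "average_neighbors": float("nan"),
            "average_clustering": float("nan"), "average_path_length": float("nan"),
            "density": float("nan"),
        }
    avg_neighbors = 2.0 * e / n
    avg_clust = nx.average_clustering(net) if n > 0 else float("nan")
    total_len = 0
    total_pairs = 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        k = len(comp)
        if k < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total_len += sum(lengths.values())
        total_pairs += k * (k - 1)
    apl = total_len / total_pairs if total_pairs else float("nan")
    density = 2.0 * e / (n * (n - 1)) if n > 1 else float("nan")
    return {
        "n_nodes": n, "n_edges": e, "average_neighbors": avg_neighbors,
        "average_clustering": avg_clust, "average_path_length": apl,
        "density": density,
    }


def detect_modules(net: nx.Graph):
    """Partition the network into modules by greedy modularity maximization.

    Deterministic (Clauset-Newman-Moore on a sorted node order). Returns
    ``(assignment, Q, module_table)`` where *assignment* maps node ->
    module id (ids ordered by decreasing module size), Q is the unweighted
    modularity of the partition, and *module_table* reports per-module
    node count, internal edge count, density, and an MCODE-style score =
    density x node count. An edgeless network puts every node in its own
    module with Q = 0.
    """
    nodes = sorted(net.nodes)
    if net.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(nodes)}
        table = pd.DataFrame(
            {"module_id": range(len(nodes)), "n_nodes": 1, "n_edges": 0,
             "density": 0.0, "score": 0.0}
        )
        return assignment, 0.0, table
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in net.edges))
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)))
    q = nx.community.modularity(g, communities)
    assignment = {}
    rows = []
    for mid, comm in enumerate(communities):
        for n in comm:
            assignment[n] = mid
        k = len(comm)
        e_in = g.subgraph(comm).number_of_edges()
        density = 2.0 * e_in / (k * (k - 1)) if k > 1 else 0.0
        rows.append(
            {"module_id": mid, "n_nodes": k, "n_edges": e_in,
             "density": density, "score": density * k}
        )
    return assignment, float(q), pd.DataFrame(rows)


def hub_ranking(net: nx.Graph, degree_threshold: int = 10, top_k: int | None = None) -> pd.DataFrame:
    """Rank nodes by degree and flag hubs.

    Nodes are sorted by degree descending, ties lexicographic; ``is_hub``
    marks degree >= *degree_threshold*. ``result.attrs["hub_summary"]``
    reports the hub count as "h/N".
    """
    rows = sorted(
        ({"genus": n, "degree": int(d)} for n, d in net.degree),
        key=lambda r: (-r["degree"], r["genus"]),
    )
    df = pd.DataFrame(rows, columns=["genus", "degree"])
    df["is_hub"] = df["degree"] >= degree_threshold
    df["rank"] = range(1, len(df) + 1)
    if top_k is not None:
        df = df.head(top_k)
    df.attrs["hub_summary"] = f"{int(df['is_hub'].sum())}/{net.number_of_nodes()}"
    return df
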