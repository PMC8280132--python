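"""Overlapping, coverage-guaranteeing density-based graph clustering.

This is a from-scratch implementation in the DPClus lineage, adapted to
produce overlapping clusters while guaranteeing that every node ends up
in at least one cluster (the DPClusO behaviour):

* the weight of an edge {u, v} is the number of common neighbours of u
  and v; the weight of a node is the sum of its incident edge weights;
* cluster growth starts from a single node and repeatedly scans the
  cluster's neighbourhood in priority order (connections to the cluster
  descending, node weight descending, id ascending), admitting the
  first candidate whose admission keeps the induced density at or above
  ``d_in`` and whose cluster property E_nk / (d_k * |N_k|) is at least
  ``cp_in``;
* the outer loop seeds growth at the uncovered node of maximal weight
  (ties: degree descending, id ascending), grows on the *full* graph -
  which is what lets clusters overlap - and marks the grown cluster's
  nodes covered, so each round covers at least one new node and the
  procedure terminates with full coverage.

Density and cluster-property comparisons are carried out in exact
rational arithmetic (the thresholds are converted to small fractions),
so admission decisions, and therefore the entire clustering, are exact
and independent of floating-point rounding and of edge-file row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

DEFAULT_DENSITIES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ClusterParams:
    d_in: float = 0.5
    cp_in: float = 0.5
    min_report_size: int = 2

    def __post_init__(self):
        if not 0.0 < self.d_in <= 1.0:
            raise ValueError("d_in must lie in (0, 1]")
        if self.cp_in < 0.0:
            raise ValueError("cp_in must be >= 0")
        if self.min_report_size < 1:
            raise ValueError("min_report_size must be >= 1")


@dataclass(frozen=True)
class Cluster:
    id: int
    nodes: frozenset[str]
    density: float
    seed_node: str

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class ClusteringRun:
    params: ClusterParams
    clusters: list[Cluster]
    n_significant: int | None = None

    def summary(self) -> dict[str, float]:
        sizes = [c.size for c in self.clusters]
        multi = [s for s in sizes if s >= max(2, self.params.min_report_size)]
        return {
            "density": self.params.d_in,
            "total_clusters": len(sizes),
            "max_size": max(sizes) if sizes else 0,
            "average_size": sum(sizes) / len(sizes) if sizes else 0.0,
            "total_clusters_min2": len(multi),
            "average_size_min2": sum(multi) / len(multi) if multi else 0.0,
            "n_significant": self.n_significant,
        }

    def membership(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for c in self.clusters:
            for n in c.nodes:
                out.setdefault(n, []).append(c.id)
        return out


def _adjacency(net: nx.Graph) -> dict[str, set[str]]:
    return {n: set(net.neighbors(n)) for n in net.nodes}


def edge_weights(net: nx.Graph) -> dict[tuple[str, str], int]:
    """Common-neighbour count for every edge, keyed by sorted pair."""
    adj = _adjacency(net)
    return {
        (min(u, v), max(u, v)): len(adj[u] & adj[v])
        for u, v in net.edges
    }


def node_weights(net: nx.Graph) -> dict[str, int]:
    ew = edge_weights(net)
    nw = {n: 0 for n in net.nodes}
    for (u, v), w in ew.items():
        nw[u] += w
        nw[v] += w
    return nw


def cluster_property(node: str, cluster_nodes: Iterable[str], net: nx.Graph) -> float:
    """E_nk / (d_k * |N_k|) for an outside node; 0 when the cluster has no edge."""
    members = set(cluster_nodes)
    if node in members:
        raise ValueError(f"node {node!r} is already a member of the cluster")
    if not members:
        raise ValueError("cluster must have at least one member")
    e_nk = sum(1 for m in members if net.has_edge(node, m))
    s = len(members)
    if s == 1:
        return float(e_nk)  # single-node cluster density is taken as 1
    e_k = nx.induced_subgraph(net, members).number_of_edges()
    if e_k == 0:
        return 0.0
    # d_k * |N_k| = 2 e_k / (s - 1); exact form avoids rounding.
    return e_nk * (s - 1) / (2 * e_k)


def _grow(
    seed: str,
    adj: dict[str, set[str]],
    nw: dict[str, int],
    d_in: Fraction,
    cp_in: Fraction,
) -> tuple[set[str], int]:
    """Grow one cluster from ``seed``; returns (nodes, internal edge count)."""
    cluster = {seed}
    e_k = 0
    conn: dict[str, int] = {v: 1 for v in adj[seed]}
    while conn:
        admit = None
        for cand in sorted(conn, key=lambda n: (-conn[n], -nw[n], n)):
            e_nk = conn[cand]
            s = len(cluster)
            # density after admission: 2 (e_k + e_nk) / ((s + 1) s) >= d_in
            if 2 * (e_k + e_nk) * d_in.denominator < d_in.numerator * (s + 1) * s:
                continue
            # cluster property: e_nk (s - 1) / (2 e_k) >= cp_in  (d_1 := 1)
            if s == 1:
                ok = Fraction(e_nk) >= cp_in
            elif e_k == 0:
                ok = cp_in <= 0
            else:
                ok = Fraction(e_nk * (s - 1), 2 * e_k) >= cp_in
            if ok:
                admit = cand
                break
        if admit is None:
            break
        e_k += conn.pop(admit)
        cluster.add(admit)
        for nb in adj[admit]:
            if nb not in cluster:
                conn[nb] = conn.get(nb, 0) + 1
    return cluster, e_k


def _as_fraction(x: float) -> Fraction:
    return Fraction(x).limit_denominator(10**6)


def dpcluso(net: nx.Graph, params: ClusterParams) -> ClusteringRun:
    """Cluster the whole graph; every node lands in at least one cluster.

    Output is deterministic for a given graph: all orderings are total
    (weight, degree, lexicographic id), so the clustering is invariant
    to the order in which edges were loaded.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    adj = _adjacency(net)
    nw = node_weights(net)
    d_in = _as_fraction(params.d_in)
    cp_in = _as_fraction(params.cp_in)
    uncovered = set(adj)
    clusters: list[Cluster] = []
    cid = 0
    while uncovered:
        seed = min(uncovered, key=lambda n: (-nw[n], -len(adj[n]), n))
        nodes, e_k = _grow(seed, adj, nw, d_in, cp_in)
        s = len(nodes)
        density = 1.0 if s == 1 else 2.0 * e_k / (s * (s - 1))
        cid += 1
        clusters.append(Cluster(id=cid, nodes=frozenset(nodes), density=density, seed_node=seed))
        uncovered -= nodes
    return ClusteringRun(params=params, clusters=clusters)


def density_sweep(
    net: nx.Graph,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    cp_in: float = 0.5,
    min_report_size: int = 2,
) -> list[ClusteringRun]:
    """One clustering run per input density."""
    if not densities:
        raise ValueError("densities must be non-empty")
    runs = []
    for d in densities:
        params = ClusterParams(d_in=d, cp_in=cp_in, min_report_size=min_report_size)
        runs.append(dpcluso(net, params))
    return runs


def summary_table(runs: Iterable[ClusteringRun]) -> pd.DataFrame:
    """Sweep summary: one row per density with cluster-count statistics.

    Reports both all-cluster and size->=2 statistics, since coverage
    forces singleton clusters that a complex-level summary may wish to
    ignore.
    """
    rows = [run.summary() for run in runs]
    df = pd.DataFrame(rows)
    return df.rename(
        columns={
            "density": "Density",
            "total_clusters": "Total clusters",
            "max_size": "Max size",
            "average_size": "Average size",
            "total_clusters_min2": "Clusters (size>=2)",
            "average_size_min2": "Average size (size>=2)",
            "n_significant": "Significant clusters",
        }
    )


def clusters_to_frame(run: ClusteringRun) -> pd.DataFrame:
    rows = [
        (c.id, n)
        for c in run.clusters
        for n in sorted(c.nodes)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "node"])
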