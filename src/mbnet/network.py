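"""Disease PPI network construction and global topology statistics.

Edges survive from the scored interactome under two rules: an
interaction between two seed proteins is kept regardless of its score,
and an interaction between a seed protein and a non-seed protein is
kept only when its confidence score strictly exceeds the threshold
(default 0.7). Interactions with both endpoints outside the seed set
are always dropped. Nodes exist only through retained edges, so seed
proteins without any surviving interaction are absent from the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .mapping import SeedSets


@dataclass
class TopologyStats:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    characteristic_path_length: float
    diameter: int
    degree_histogram: dict[int, int]
    powerlaw_slope: float

    def to_json(self, path: Path | str) -> None:
        d = asdict(self)
        d["degree_histogram"] = {str(k): v for k, v in sorted(self.degree_histogram.items())}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def build_network(
    interactions: pd.DataFrame, seeds: SeedSets, threshold: float = 0.7
) -> nx.Graph:
    """Apply the seed-set edge rules to a scored interaction table.

    Returns an undirected simple graph whose edges carry ``score`` and
    whose nodes carry ``in_SCZ``/``in_BD``/``in_seed`` flags. Per-disease
    edge counts are stored in ``graph.graph`` under the reading that an
    edge belongs to a disease when it would survive the same rules
    applied to that disease's seed set alone.
    """
    if not seeds.union:
        raise ValueError("seed set is empty; cannot build a disease network")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    s_all = seeds.union
    net = nx.Graph()
    n_scz = n_bd = 0
    for row in interactions.itertuples(index=False):
        a, b, score = str(row[0]), str(row[1]), float(row[2])
        in_a, in_b = a in s_all, b in s_all
        if not (in_a and in_b) and not ((in_a or in_b) and score > threshold):
            continue
        net.add_edge(a, b, score=score)
        if _edge_in_disease(a, b, score, seeds.scz, threshold):
            n_scz += 1
        if _edge_in_disease(a, b, score, seeds.bd, threshold):
            n_bd += 1
    for n in net.nodes:
        net.nodes[n]["in_SCZ"] = n in seeds.scz
        net.nodes[n]["in_BD"] = n in seeds.bd
        net.nodes[n]["in_seed"] = n in s_all
    net.graph["threshold"] = threshold
    net.graph["n_edges_SCZ"] = n_scz
    net.graph["n_edges_BD"] = n_bd
    net.graph["n_edges_common"] = n_scz + n_bd - net.number_of_edges() if net.number_of_edges() else 0
    return net


def _edge_in_disease(a: str, b: str, score: float, s_d: frozenset[str], t: float) -> bool:
    in_a, in_b = a in s_d, b in s_d
    if in_a and in_b:
        return True
    return (in_a or in_b) and score > t


def topology_stats(net: nx.Graph) -> TopologyStats:
    """Global topology summary of the disease network.

    The mean local clustering counts degree-0/1 nodes as 0; path length
    and diameter are computed on the largest connected component; the
    power-law slope is the least-squares slope of log(count) against
    log(degree) over positive degrees, a descriptive statistic rather
    than a formal fit.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot compute topology of an empty network")
    cc = nx.average_clustering(net, count_zeros=True)
    giant = max(nx.connected_components(net), key=lambda c: (len(c), min(c)))
    sub = net.subgraph(giant)
    if sub.number_of_nodes() > 1:
        cpl = nx.average_shortest_path_length(sub)
        diam = nx.diameter(sub)
    else:
        cpl, diam = 0.0, 0
    degrees = [d for _, d in net.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    pos = sorted((d, c) for d, c in hist.items() if d > 0)
    if len(pos) >= 2:
        x = np.log([d for d, _ in pos])
        y = np.log([c for _, c in pos])
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = float("nan")
    return TopologyStats(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        clustering_coefficient=float(cc),
        characteristic_path_length=float(cpl),
        diameter=int(diam),
        degree_histogram=hist,
        powerlaw_slope=slope,
    )


def network_to_frame(net: nx.Graph) -> pd.DataFrame:
    rows = sorted(
        (min(u, v), max(u, v), d["score"]) for u, v, d in net.edges(data=True)
    )
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


def write_network(net: nx.Graph, path: Path | str) -> None:
    io.write_tsv(path, network_to_frame(net))
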