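"""Bipartite cluster-pathway graph and high-degree pathway selection.

Each statistically significant cluster contributes its top-k enriched
pathways (k = 3 by default); linking clusters to those pathways gives a
bipartite graph in which a pathway's degree counts the distinct
significant clusters that nominated it. Pathways of degree >= 3 are the
final disease-pathway calls, ranked by degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .enrichment import EnrichmentResult


@dataclass
class BipartiteGraph:
    edges: list[tuple[int, str]] = field(default_factory=list)

    @property
    def cluster_ids(self) -> frozenset[int]:
        return frozenset(c for c, _ in self.edges)

    @property
    def pathway_ids(self) -> frozenset[str]:
        return frozenset(p for _, p in self.edges)

    def pathway_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for _, p in self.edges:
            deg[p] = deg.get(p, 0) + 1
        return deg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["cluster_id", "pathway"])


def top_k(enrichments: Sequence[EnrichmentResult], k: int = 3) -> list[EnrichmentResult]:
    """First k results by (EASE p asc, count desc, pathway id asc)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(enrichments, key=lambda r: (r.ease_p, -r.count, r.pathway_id))
    return ranked[:k]


def build_bipartite(per_cluster_topk: Iterable[Sequence[EnrichmentResult]]) -> BipartiteGraph:
    """One edge per (cluster, pathway) membership in a cluster's top-k list."""
    bg = BipartiteGraph()
    seen: set[tuple[int, str]] = set()
    for results in per_cluster_topk:
        for r in results:
            edge = (r.cluster_id, r.pathway_id)
            if edge not in seen:
                seen.add(edge)
                bg.edges.append(edge)
    return bg


def select_pathways(bg: BipartiteGraph, min_degree: int = 3) -> list[tuple[str, int]]:
    """Pathways with degree >= min_degree, by degree desc then id asc."""
    deg = bg.pathway_degree()
    kept = [(p, d) for p, d in deg.items() if d >= min_degree]
    kept.sort(key=lambda t: (-t[1], t[0]))
    return kept


def ranking_frame(bg: BipartiteGraph, min_degree: int = 3) -> pd.DataFrame:
    deg = bg.pathway_degree()
    rows = sorted(deg.items(), key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(
        [(p, d, int(d >= min_degree)) for p, d in rows],
        columns=["pathway", "degree", "selected"],
    )
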