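"""Fisher / EASE enrichment with Bonferroni and Benjamini-Hochberg control.

The one-sided Fisher exact p-value for a 2x2 overlap table is the
hypergeometric upper tail P(X >= k) with population size N, K annotated
successes and a query of size n. The EASE score is the DAVID-style
conservative variant: the same tail after discounting one gene from the
overlap (so single-gene overlaps can never reach significance).
Multiple-testing corrections are applied per family: across one
clustering run's size->=2 clusters for disease enrichment, and across
the pathways tested for one cluster for pathway enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .dpcluso import ClusteringRun


@dataclass(frozen=True)
class ContingencyCounts:
    """Overlap table: k of n query genes fall in a K-of-N annotated set."""

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self):
        if min(self.k, self.K, self.n, self.N) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.K > self.N or self.n > self.N:
            raise ValueError("K and n cannot exceed the background size N")
        if self.k > min(self.K, self.n):
            raise ValueError("overlap k cannot exceed min(K, n)")


@dataclass(frozen=True)
class ClusterSignificance:
    cluster_id: int
    size: int
    k: int
    p: float
    p_bonferroni: float
    fdr: float
    significant: bool


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: int
    pathway_id: str
    count: int
    ease_p: float
    fdr: float


def fisher_greater(c: ContingencyCounts) -> float:
    """Exact one-sided (enrichment) Fisher p-value, P(X >= k)."""
    return float(hypergeom.sf(c.k - 1, c.N, c.K, c.n))


def ease_p(c: ContingencyCounts) -> float:
    """EASE score: the Fisher tail with the overlap discounted by one."""
    return fisher_greater(ContingencyCounts(k=max(c.k - 1, 0), K=c.K, n=c.n, N=c.N))


def _check_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    arr = np.asarray(pvalues, dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    arr = _check_pvalues(pvalues)
    return np.minimum(1.0, arr * arr.size)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = _check_pvalues(pvalues)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def score_clusters(
    run: ClusteringRun,
    disease_set: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
) -> list[ClusterSignificance]:
    """Disease enrichment of every size->=2 cluster of one run.

    The correction family is the run itself: Bonferroni and BH are
    applied across all tested clusters of this density. Selection is by
    BH FDR < ``alpha``.
    """
    bg = frozenset(background)
    disease = frozenset(disease_set)
    if not disease <= bg:
        raise ValueError("disease set must be contained in the background")
    tested = [c for c in run.clusters if c.size >= max(2, run.params.min_report_size)]
    for c in tested:
        if not c.nodes <= bg:
            raise ValueError(f"cluster {c.id} has nodes outside the background")
    pvals = []
    for c in tested:
        counts = ContingencyCounts(
            k=len(c.nodes & disease), K=len(disease), n=c.size, N=len(bg)
        )
        pvals.append(fisher_greater(counts))
    bonf = bonferroni(pvals)
    fdr = bh_fdr(pvals)
    out = []
    for c, p, pb, q in zip(tested, pvals, bonf, fdr):
        out.append(
            ClusterSignificance(
                cluster_id=c.id,
                size=c.size,
                k=len(c.nodes & disease),
                p=float(p),
                p_bonferroni=float(pb),
                fdr=float(q),
                significant=bool(q < alpha),
            )
        )
    return out


def enrich_pathways(
    cluster_id: int,
    cluster_nodes: Iterable[str],
    pathways: Mapping[str, frozenset[str]],
    background: Iterable[str],
    count_min: int = 2,
    ease_max: float = 0.1,
    fdr_max: float = 0.05,
) -> list[EnrichmentResult]:
    """EASE enrichment of one cluster against every pathway gene set.

    All pathways are tested (that is the BH family); results are kept
    when count >= ``count_min``, EASE p <= ``ease_max`` and
    FDR <= ``fdr_max``, sorted by EASE p ascending with count-descending
    then id-ascending tie-breaks. An empty result list is a valid
    outcome; an empty pathway collection is not.
    """
    if not pathways:
        raise ValueError("pathway collection is empty")
    nodes = frozenset(cluster_nodes)
    bg = frozenset(background)
    if not nodes <= bg:
        raise ValueError("cluster nodes must be contained in the background")
    names = sorted(pathways)
    pvals = []
    counts = []
    for name in names:
        genes = frozenset(pathways[name]) & bg
        k = len(nodes & genes)
        counts.append(k)
        pvals.append(
            ease_p(ContingencyCounts(k=k, K=len(genes), n=len(nodes), N=len(bg)))
        )
    fdr = bh_fdr(pvals)
    kept = [
        EnrichmentResult(cluster_id=cluster_id, pathway_id=name, count=k, ease_p=float(p), fdr=float(q))
        for name, k, p, q in zip(names, counts, pvals, fdr)
        if k >= count_min and p <= ease_max and q <= fdr_max
    ]
    kept.sort(key=lambda r: (r.ease_p, -r.count, r.pathway_id))
    return kept
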