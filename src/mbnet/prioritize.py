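"""Protein prioritization: SScores, ROC analysis and density selection.

Each protein inherits a significance score from the clusters that
contain it: SScore = -log10(FDR) of the best (smallest-FDR) size->=2
cluster it belongs to, with FDR floored before the logarithm so that
numerically-zero FDRs stay finite. Proteins covered only by singleton
clusters score 0. Sweeping a threshold over SScores against a truth
labelling (reference disease genes united with the seed proteins)
yields a ROC curve per clustering density; the density with maximal AUC
is retained, ties resolving toward the smaller density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dpcluso import ClusteringRun
from .enrichment import ClusterSignificance
from .errors import MbnetError


@dataclass
class SScoreTable:
    """protein -> SScore with the cluster attaining the maximum."""

    scores: dict[str, float]
    provenance: dict[str, int | None]

    def to_frame(self) -> pd.DataFrame:
        prots = sorted(self.scores)
        return pd.DataFrame(
            {
                "protein": prots,
                "sscore": [self.scores[p] for p in prots],
                "best_cluster": [
                    self.provenance[p] if self.provenance[p] is not None else -1
                    for p in prots
                ],
            }
        )


@dataclass
class RocResult:
    density: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def assign_sscores(
    run: ClusteringRun,
    significance: Sequence[ClusterSignificance],
    fdr_floor: float = 1e-16,
) -> SScoreTable:
    """Max over containing clusters of -log10(FDR); singletons score 0."""
    fdr_by_cluster = {s.cluster_id: s.fdr for s in significance}
    scores: dict[str, float] = {}
    provenance: dict[str, int | None] = {}
    min_size = max(2, run.params.min_report_size)
    for c in run.clusters:
        if c.size >= min_size:
            if c.id not in fdr_by_cluster:
                raise MbnetError(f"no significance record for cluster {c.id}")
            s = -np.log10(max(fdr_by_cluster[c.id], fdr_floor))
            cid: int | None = c.id
        else:
            s, cid = 0.0, None
        for n in c.nodes:
            if n not in scores or s > scores[n]:
                scores[n] = float(s)
                provenance[n] = cid
    return SScoreTable(scores=scores, provenance=provenance)


def truth_labels(
    network_nodes: Sequence[str],
    reference_genes: Sequence[str] | frozenset[str],
    seed_set: Sequence[str] | frozenset[str],
) -> dict[str, int]:
    """Label 1 iff the node is a reference disease gene or a seed protein."""
    truth = frozenset(reference_genes) | frozenset(seed_set)
    return {n: int(n in truth) for n in network_nodes}


def roc_auc(
    scores: SScoreTable | Mapping[str, float],
    labels: Mapping[str, int],
    density: float = float("nan"),
) -> RocResult:
    """ROC curve over SScore thresholds with trapezoidal AUC.

    Ties are grouped (equal scores enter the curve together), so the
    AUC equals the tie-corrected Mann-Whitney statistic. Requires at
    least one positive and one negative label.
    """
    table = scores.scores if isinstance(scores, SScoreTable) else scores
    nodes = sorted(labels)
    if set(table) != set(nodes):
        raise ValueError("scores and labels must cover the same proteins")
    y = np.array([labels[n] for n in nodes], dtype=int)
    s = np.array([table[n] for n in nodes], dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(
        density=density,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def select_density(rocs: Sequence[RocResult]) -> float:
    """Density of maximal AUC; exact ties resolve to the smaller density."""
    if not rocs:
        raise ValueError("no ROC results to select from")
    best = max(rocs, key=lambda r: (r.auc, -r.density))
    return best.density


def roc_to_frame(roc: RocResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
    )
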