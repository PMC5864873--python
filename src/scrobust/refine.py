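"""Consensus-cluster refinement: choose k by maximizing the mean score.

Hierarchical clustering of the noise consensus matrix (distance
1 - association frequency, complete linkage) yields a dendrogram whose
cuts at k = 1..max_k are scored by the unweighted mean cluster score.
The cut with the maximum mean score is the refined "meta-clustering";
ties go to the smallest k. max_k defaults to a tenth of the number of
cells — evaluating every k up to n is expensive and rarely meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .consensus import ClusterLabels, ConsensusMatrix
from .metrics import cluster_promiscuity, cluster_stability

__all__ = ["consensus_tree", "select_k"]


def consensus_tree(cons: ConsensusMatrix) -> np.ndarray:
    """Complete-linkage dendrogram (scipy linkage matrix) on 1 - consensus."""
    if cons.n_cells < 2:
        raise ValueError("need at least 2 cells to build a tree")
    dist = 1.0 - cons.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return linkage(condensed, method="complete")


def _mean_cluster_score(cons: ConsensusMatrix, labels: np.ndarray) -> float:
    scores = []
    for cl in np.unique(labels):
        members = [cons.cell_ids[i] for i in np.flatnonzero(labels == cl)]
        scores.append(
            cluster_stability(cons, members) - cluster_promiscuity(cons, members)
        )
    return float(np.mean(scores))


def select_k(
    cons: ConsensusMatrix, max_k: int | None = None
) -> tuple[int, ClusterLabels, pd.DataFrame]:
    """Cut the consensus dendrogram at each k and keep the best-scoring cut.

    Returns (k, labels, score_curve) where score_curve has one row per
    candidate k with its unweighted mean cluster score. The maximum of the
    curve is attained at the returned k; among ties the smallest k wins.
    """
    n = cons.n_cells
    if max_k is None:
        max_k = max(1, n // 10)
    if not 1 <= max_k <= n:
        raise ValueError(f"max_k must lie in [1, {n}]")
    tree = consensus_tree(cons) if n >= 2 else None
    rows = []
    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(1, max_k + 1):
        if k == 1 or tree is None:
            labels = np.zeros(n, dtype=int)
        else:
            labels = fcluster(tree, t=k, criterion="maxclust")
        score = _mean_cluster_score(cons, labels)
        rows.append((k, score))
        if score > best_score:  # strict: ties keep the smaller k
            best_k, best_score, best_labels = k, score, labels
    curve = pd.DataFrame(rows, columns=["k", "mean_score"])
    labels_out = ClusterLabels(
        cell_ids=list(cons.cell_ids), labels=[int(l) for l in best_labels]
    )
    return int(best_k), labels_out, curve
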