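"""Stability, promiscuity and score from a noise consensus matrix.

Stability of a cluster is the mean association frequency among its members
(upper triangle of the members x members consensus submatrix); values
above 0.5 mean the cells co-cluster more often than chance. Promiscuity
measures how strongly members associate with cells outside the cluster,
using a worst-case subset: when the cluster is smaller than its complement,
only the |cluster| outside cells with the strongest mean association are
counted. Score = stability - promiscuity; positive scores indicate a
grouping that survives technical variance.

The null distribution of all three metrics is estimated by averaging
random association matrices (each unordered cell pair set to 1 with
probability 1/2) into a consensus and scoring an arbitrary reference
cluster, repeated many times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ClusterLabels, ConsensusMatrix

__all__ = [
    "ClusterMetrics",
    "CellMetrics",
    "NullDistribution",
    "cluster_stability",
    "cluster_promiscuity",
    "cluster_score",
    "cell_stability",
    "cell_promiscuity",
    "cell_score",
    "compute_metrics",
    "null_metric_distribution",
]


class MetricsError(ValueError):
    pass


@dataclass
class ClusterMetrics:
    cluster_id: object
    size: int
    stability: float
    promiscuity: float
    score: float


@dataclass
class CellMetrics:
    cell_id: str
    cluster_id: object
    stability: float
    promiscuity: float
    score: float


def _indices(cons: ConsensusMatrix, members) -> np.ndarray:
    pos = {c: i for i, c in enumerate(cons.cell_ids)}
    try:
        return np.array([pos[c] for c in members], dtype=int)
    except KeyError as exc:
        raise MetricsError(f"unknown cell id: {exc.args[0]!r}") from None


def cluster_stability(cons: ConsensusMatrix, members) -> float:
    """Mean upper-triangle association within the cluster; singleton -> 1."""
    idx = _indices(cons, members)
    if idx.size == 0:
        raise MetricsError("empty cluster")
    if idx.size == 1:
        return 1.0
    sub = cons.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def _top_outside(cons: ConsensusMatrix, inside: np.ndarray, n: int) -> np.ndarray:
    """The n outside cells with the strongest mean association with the
    cluster; ties broken by cell order for determinism."""
    outside = np.setdiff1d(np.arange(cons.n_cells), inside, assume_unique=True)
    mean_assoc = cons.values[np.ix_(inside, outside)].mean(axis=0)
    order = np.lexsort((outside, -mean_assoc))  # strongest first, then id order
    return outside[order[:n]]


def cluster_promiscuity(cons: ConsensusMatrix, members) -> float:
    """Mean association between the cluster and its (worst-case) complement.

    Majority clusters (at least as many cells inside as outside) use the
    full inside x outside block; minority clusters use only the |cluster|
    most strongly associated outside cells. An all-cells cluster has
    promiscuity 0 (no complement).
    """
    inside = _indices(cons, members)
    if inside.size == 0:
        raise MetricsError("empty cluster")
    n_out = cons.n_cells - inside.size
    if n_out == 0:
        return 0.0
    if inside.size >= n_out:
        outside = np.setdiff1d(np.arange(cons.n_cells), inside, assume_unique=True)
    else:
        outside = _top_outside(cons, inside, inside.size)
    return float(cons.values[np.ix_(inside, outside)].mean())


def cluster_score(cons: ConsensusMatrix, members) -> float:
    return cluster_stability(cons, members) - cluster_promiscuity(cons, members)


def cell_stability(cons: ConsensusMatrix, cell: str, members) -> float:
    """Mean association of the cell with its cluster-mates; singleton -> 1."""
    idx = _indices(cons, members)
    ci = _indices(cons, [cell])[0]
    if ci not in idx:
        raise MetricsError(f"cell {cell!r} not in the given cluster")
    mates = idx[idx != ci]
    if mates.size == 0:
        return 1.0
    return float(cons.values[ci, mates].mean())


def cell_promiscuity(cons: ConsensusMatrix, cell: str, members) -> float:
    """Mean association of the cell with outside cells (top-n for minority
    clusters, ranked by that cell's own association frequencies)."""
    inside = _indices(cons, members)
    ci = _indices(cons, [cell])[0]
    if ci not in inside:
        raise MetricsError(f"cell {cell!r} not in the given cluster")
    n_out = cons.n_cells - inside.size
    if n_out == 0:
        return 0.0
    outside = np.setdiff1d(np.arange(cons.n_cells), inside, assume_unique=True)
    assoc = cons.values[ci, outside]
    if inside.size < n_out:
        order = np.lexsort((outside, -assoc))
        assoc = assoc[order[: inside.size]]
    return float(assoc.mean())


def cell_score(cons: ConsensusMatrix, cell: str, members) -> float:
    return cell_stability(cons, cell, members) - cell_promiscuity(cons, cell, members)


def compute_metrics(
    cons: ConsensusMatrix, labels: ClusterLabels
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-level and cell-level metric tables for a labelling."""
    if labels.cell_ids != list(cons.cell_ids):
        series = labels.as_series()
        missing = [c for c in cons.cell_ids if c not in series.index]
        if missing:
            raise MetricsError(f"labels missing for cells: {missing}")
        labels = ClusterLabels(
            cell_ids=list(cons.cell_ids),
            labels=[series[c] for c in cons.cell_ids],
        )
    cluster_rows = []
    cell_rows = []
    for cl in labels.clusters:
        members = labels.members(cl)
        stab = cluster_stability(cons, members)
        prom = cluster_promiscuity(cons, members)
        cluster_rows.append(
            ClusterMetrics(cl, len(members), stab, prom, stab - prom)
        )
        for cell in members:
            cs = cell_stability(cons, cell, members)
            cp = cell_promiscuity(cons, cell, members)
            cell_rows.append(CellMetrics(cell, cl, cs, cp, cs - cp))
    cluster_df = pd.DataFrame(
        [(c.cluster_id, c.size, c.stability, c.promiscuity, c.score) for c in cluster_rows],
        columns=["cluster_id", "size", "stability", "promiscuity", "score"],
    )
    cell_df = pd.DataFrame(
        [(c.cell_id, c.cluster_id, c.stability, c.promiscuity, c.score) for c in cell_rows],
        columns=["cell_id", "cluster_id", "stability", "promiscuity", "score"],
    )
    return cluster_df, cell_df


@dataclass
class NullDistribution:
    """Sampled metric values under the random-association null."""

    n_cells: int
    cluster_size: int
    reps: int
    cluster_samples: pd.DataFrame  # columns stability, promiscuity, score
    cell_samples: pd.DataFrame  # one row per reference-cluster cell per rep

    def to_tsv(self, path) -> None:
        cl = self.cluster_samples.assign(level="cluster")
        ce = self.cell_samples.assign(level="cell")
        pd.concat([cl, ce], ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )


def _random_consensus(
    n_cells: int, n_assoc: int, rng: np.random.Generator
) -> ConsensusMatrix:
    """Average of ``n_assoc`` random binary association matrices."""
    iu = np.triu_indices(n_cells, k=1)
    bits = rng.integers(0, 2, size=(n_assoc, iu[0].size))
    upper = bits.mean(axis=0)
    values = np.eye(n_cells)
    values[iu] = upper
    values.T[iu] = upper
    return ConsensusMatrix(
        values=values,
        cell_ids=[f"cell{i}" for i in range(n_cells)],
        n_replicates=n_assoc,
    )


def null_metric_distribution(
    n_cells: int,
    cluster_size: int,
    reps: int = 100,
    n_assoc: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Background distribution of the metrics under random association.

    Each repetition averages ``n_assoc`` random association matrices (every
    unordered cell pair independently 1 with probability 1/2) into a
    consensus, places an arbitrary reference cluster of ``cluster_size``
    cells, and records cluster- and cell-level metrics.
    """
    if not 1 <= cluster_size <= n_cells:
        raise MetricsError("cluster_size must lie in [1, n_cells]")
    if reps < 1:
        raise MetricsError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    members = [f"cell{i}" for i in range(cluster_size)]
    cluster_rows = []
    cell_rows = []
    for rep in range(reps):
        cons = _random_consensus(n_cells, n_assoc, rng)
        stab = cluster_stability(cons, members)
        prom = cluster_promiscuity(cons, members)
        cluster_rows.append((rep, stab, prom, stab - prom))
        for cell in members:
            cs = cell_stability(cons, cell, members)
            cp = cell_promiscuity(cons, cell, members)
            cell_rows.append((rep, cell, cs, cp, cs - cp))
    return NullDistribution(
        n_cells=n_cells,
        cluster_size=cluster_size,
        reps=reps,
        cluster_samples=pd.DataFrame(
            cluster_rows, columns=["rep", "stability", "promiscuity", "score"]
        ),
        cell_samples=pd.DataFrame(
            cell_rows, columns=["rep", "cell_id", "stability", "promiscuity", "score"]
        ),
    )
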