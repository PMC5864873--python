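"""Association matrices and the noise consensus matrix.

Every simulated replicate is clustered with the same algorithm and
parameters as the original experiment (via a pluggable adapter). Each
clustering yields a binary cells x cells association matrix (1 = the two
cells share a cluster); averaging the association matrices over replicates
gives the noise consensus matrix, whose entries are association
frequencies in [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .data_io import CountsMatrix
from .simulate import SimulatedReplicate

__all__ = [
    "ClusterLabels",
    "AssociationMatrix",
    "ConsensusMatrix",
    "build_association_matrix",
    "aggregate_consensus",
    "cluster_replicates",
    "builtin_reference_clusterer",
    "labels_directory_clusterer",
    "gene_sampling_consensus",
    "read_labels",
    "write_labels",
    "plot_consensus",
]

# adapter contract: CountsMatrix -> ClusterLabels, fixed parameters
ClustererAdapter = Callable[[CountsMatrix], "ClusterLabels"]


class ConsensusError(ValueError):
    pass


@dataclass
class ClusterLabels:
    """Cluster assignment for an ordered list of cells."""

    cell_ids: list[str]
    labels: list

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise ConsensusError("one label per cell required")
        if len(self.cell_ids) == 0:
            raise ConsensusError("empty labelling")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids)

    def members(self, cluster) -> list[str]:
        return [c for c, l in zip(self.cell_ids, self.labels) if l == cluster]

    @property
    def clusters(self) -> list:
        seen: dict = {}
        for l in self.labels:
            seen.setdefault(l, None)
        return list(seen)


@dataclass
class AssociationMatrix:
    """Binary co-clustering indicator for one clustering."""

    values: np.ndarray
    cell_ids: list[str]


@dataclass
class ConsensusMatrix:
    """Mean of association matrices: association frequencies in [0, 1]."""

    values: np.ndarray
    cell_ids: list[str]
    n_replicates: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.cell_ids)

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.to_frame()
        df.index.name = f"n_replicates={self.n_replicates}"
        df.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ConsensusMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        n_rep = 1
        if df.index.name and "=" in str(df.index.name):
            n_rep = int(str(df.index.name).split("=", 1)[1])
        return cls(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(c) for c in df.columns],
            n_replicates=n_rep,
        )


def build_association_matrix(labels: ClusterLabels) -> AssociationMatrix:
    """entry(i, j) = 1 iff cells i and j share a cluster label."""
    arr = np.asarray(labels.labels, dtype=object)
    values = (arr[:, None] == arr[None, :]).astype(np.int8)
    return AssociationMatrix(values=values, cell_ids=list(labels.cell_ids))


def aggregate_consensus(mats: Sequence[AssociationMatrix]) -> ConsensusMatrix:
    """Element-wise mean of association matrices with identical cell order."""
    if len(mats) == 0:
        raise ConsensusError("need at least one association matrix")
    cell_ids = mats[0].cell_ids
    for i, mat in enumerate(mats):
        if mat.cell_ids != cell_ids:
            raise ConsensusError(f"association matrix {i} has mismatched cell ids")
    stack = np.stack([m.values.astype(float) for m in mats])
    return ConsensusMatrix(
        values=stack.mean(axis=0), cell_ids=list(cell_ids), n_replicates=len(mats)
    )


def cluster_replicates(
    reps: Sequence[SimulatedReplicate],
    clusterer: ClustererAdapter,
    is_spikein: pd.Series | None = None,
) -> list[ClusterLabels]:
    """Run the adapter on every replicate, preserving cell order."""
    out = []
    for i, rep in enumerate(reps):
        flags = (
            is_spikein
            if is_spikein is not None
            else pd.Series(False, index=rep.values.index)
        )
        try:
            labels = clusterer(rep.as_counts(flags))
        except Exception as exc:
            raise ConsensusError(f"clustering failed on replicate {i}: {exc}") from exc
        if labels.cell_ids != list(rep.values.columns):
            raise ConsensusError(f"replicate {i}: adapter reordered cells")
        out.append(labels)
    return out


def builtin_reference_clusterer(k: int, seed: int | None = None) -> ClustererAdapter:
    """Hierarchical clustering adapter for tests and demos.

    Complete-linkage agglomerative clustering of cells on log2(x+1) counts
    with Euclidean distance, cut at k clusters. Deterministic; ``seed`` is
    accepted for interface uniformity but unused. This is scaffolding for
    exercising the pipeline, not a recommended scRNA-seq clustering method.
    """
    if k < 1:
        raise ConsensusError("k must be >= 1")

    def _cluster(m: CountsMatrix) -> ClusterLabels:
        if k > m.n_cells:
            raise ConsensusError(f"k={k} exceeds number of cells ({m.n_cells})")
        x = np.log2(m.values.to_numpy(dtype=float).T + 1.0)  # cells x genes
        if k == m.n_cells:
            labels = np.arange(m.n_cells)
        else:
            model = AgglomerativeClustering(
                n_clusters=k, metric="euclidean", linkage="complete"
            )
            labels = model.fit_predict(x)
        return ClusterLabels(cell_ids=m.cell_ids, labels=[int(l) for l in labels])

    return _cluster


def labels_directory_clusterer(paths: Sequence[str | os.PathLike]):
    """Adapter factory ingesting pre-computed per-replicate label files.

    Returns one adapter per path; each ignores the counts it is handed and
    reads ``cell_id<TAB>cluster`` from its file. Used to plug in external
    clustering tools that were run out-of-band on the written replicates.
    """
    return [(_make_file_adapter(p)) for p in paths]


def _make_file_adapter(path: str | os.PathLike) -> ClustererAdapter:
    def _adapter(m: CountsMatrix) -> ClusterLabels:
        labels = read_labels(path)
        series = labels.as_series()
        missing = [c for c in m.cell_ids if c not in series.index]
        if missing:
            raise ConsensusError(f"{path}: no label for cells {missing}")
        return ClusterLabels(
            cell_ids=m.cell_ids, labels=[series[c] for c in m.cell_ids]
        )

    return _adapter


def read_labels(path: str | os.PathLike) -> ClusterLabels:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cluster"])
    return ClusterLabels(
        cell_ids=[str(c) for c in df["cell_id"]], labels=list(df["cluster"])
    )


def write_labels(labels: ClusterLabels, path: str | os.PathLike) -> None:
    pd.DataFrame({"cell_id": labels.cell_ids, "cluster": labels.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def gene_sampling_consensus(
    m: CountsMatrix,
    clusterer: ClustererAdapter,
    n_iter: int = 100,
    seed: int = 0,
    min_total_counts: int = 25,
) -> ConsensusMatrix:
    """Baseline consensus from re-clustering random halves of the genes.

    Genes with fewer than ``min_total_counts`` raw counts summed over all
    cells are excluded from the sample space; each iteration samples half
    of the remaining genes without replacement and clusters that submatrix.
    """
    totals = m.values.sum(axis=1)
    eligible = m.values.index[totals >= min_total_counts]
    if len(eligible) < 2:
        raise ConsensusError(
            f"only {len(eligible)} genes with >= {min_total_counts} total counts"
        )
    rng = np.random.default_rng(seed)
    half = len(eligible) // 2
    mats = []
    for _ in range(n_iter):
        chosen = rng.choice(eligible, size=half, replace=False)
        sub = CountsMatrix(
            values=m.values.loc[chosen],
            is_spikein=m.is_spikein.loc[chosen],
            normalized=m.normalized,
        )
        mats.append(build_association_matrix(clusterer(sub)))
    return aggregate_consensus(mats)


def plot_consensus(cons: ConsensusMatrix, path: str | os.PathLike) -> None:
    """Render the consensus matrix as a heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cons.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_title("Noise consensus matrix")
    ax.set_xlabel("cells")
    ax.set_ylabel("cells")
    fig.colorbar(im, ax=ax, label="association frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
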