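"""Synthetic fixtures with known ground truth.

Two generators back the test suite and worked examples:

* spike-in counts drawn from a planted Poisson/NB mixture whose alpha and
  sigma are linear in log2 concentration, with a linear-in-concentration
  drop-out rate — the exact generative family the fitting code assumes,
  so parameter recovery is well-defined;
* cell matrices with planted cluster structure (group-specific fold
  changes on a subset of marker genes, NB-distributed counts), for
  exercising clustering, consensus and refinement end to end.

These emulate the statistical structure the models target, not real
scRNA-seq data: there are no library-size gradients, doublets or batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ClusterLabels
from .data_io import CountsMatrix, SpikeInReference

__all__ = [
    "PlantedModel",
    "generate_spikein_counts",
    "generate_cell_matrix_with_clusters",
    "generate_experiment",
]


@dataclass
class PlantedModel:
    """Ground-truth noise/drop-out model for spike-in simulation.

    alpha(c) = clamp(alpha_line[0] * log2(c) + alpha_line[1], 0, 1)
    sigma(c) = 2 ** (sigma_line[0] * log2(c) + sigma_line[1])
    dropout(y) = clamp(dropout_line[0] * y + dropout_line[1], 0, 1)
    """

    alpha_line: tuple[float, float] = (0.08, 0.1)
    sigma_line: tuple[float, float] = (0.75, 0.25)
    dropout_line: tuple[float, float] = (-0.001, 0.25)
    spikein_concentrations: list[float] = field(
        default_factory=lambda: list(np.exp2(np.linspace(2.0, 7.0, 40)))
    )
    n_cells: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.spikein_concentrations, dtype=float)
        if (conc <= 0).any():
            raise ValueError("spike-in concentrations must be positive")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        alpha = self.alpha(conc)
        sigma = self.sigma(conc)
        bad = (alpha > 0) & (np.square(sigma) <= conc)
        if bad.any():
            raise ValueError(
                "planted model ill-posed: sigma(c)^2 <= c where alpha(c) > 0 "
                f"at concentrations {conc[bad].tolist()}"
            )
        d_raw = self.dropout_line[0] * conc + self.dropout_line[1]
        if (d_raw > 1).any():
            raise ValueError("planted drop-out probability exceeds 1 in range")

    def alpha(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return np.clip(
            self.alpha_line[0] * np.log2(c) + self.alpha_line[1], 0.0, 1.0
        )

    def sigma(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return np.exp2(self.sigma_line[0] * np.log2(c) + self.sigma_line[1])

    def dropout_probability(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.clip(self.dropout_line[0] * y + self.dropout_line[1], 0.0, 1.0)

    def sample_mixture(self, c: float, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from the planted Z(c) (no drop-out)."""
        alpha = float(self.alpha(c))
        sigma = float(self.sigma(c))
        if alpha > 0 and sigma**2 <= c:
            alpha = 0.0
        out = rng.poisson(c, size=size)
        use_nb = rng.random(size) < alpha
        if use_nb.any():
            r = c**2 / (sigma**2 - c)
            p = r / (r + c)
            out[use_nb] = rng.negative_binomial(r, p, size=int(use_nb.sum()))
        return out


def generate_spikein_counts(
    pm: PlantedModel, id_prefix: str = "ERCC-SYN-"
) -> tuple[CountsMatrix, SpikeInReference]:
    """Spike-in counts matrix plus matching reference table.

    Per concentration y and cell: with probability dropout(y) emit 0,
    otherwise a draw from the planted mixture Z(y).
    """
    rng = np.random.default_rng(pm.seed)
    conc = np.asarray(pm.spikein_concentrations, dtype=float)
    ids = [f"{id_prefix}{i:04d}" for i in range(len(conc))]
    rows = []
    for y in conc:
        counts = pm.sample_mixture(float(y), pm.n_cells, rng)
        dropped = rng.random(pm.n_cells) < pm.dropout_probability(y)
        counts = np.where(dropped, 0, counts)
        rows.append(counts)
    values = pd.DataFrame(
        np.asarray(rows),
        index=ids,
        columns=[f"cell{i}" for i in range(pm.n_cells)],
    )
    m = CountsMatrix(values=values, is_spikein=pd.Series(True, index=values.index))
    ref = SpikeInReference(molecules=pd.Series(conc, index=ids))
    return m, ref


def planted_zero_probability(pm: PlantedModel, y: float) -> float:
    """Exact zero probability of one matrix entry at concentration y.

    Combines the planted drop-out rate with the zero mass of the planted
    mixture: d(y) + (1 - d(y)) * Pr(Z(y) = 0).
    """
    from scipy import stats

    d = float(pm.dropout_probability(y))
    alpha = float(pm.alpha(y))
    sigma = float(pm.sigma(y))
    if alpha > 0 and sigma**2 <= y:
        alpha = 0.0
    p0 = (1.0 - alpha) * stats.poisson.pmf(0, y)
    if alpha > 0:
        r = y**2 / (sigma**2 - y)
        p = r / (r + y)
        p0 += alpha * stats.nbinom.pmf(0, r, p)
    return d + (1.0 - d) * float(p0)


def generate_fidelity_dataset(
    pm: PlantedModel,
    n_genes: int = 300,
    gene_log2_range: tuple[float, float] = (3.0, 7.0),
    seed: int | None = None,
) -> tuple[CountsMatrix, SpikeInReference, np.ndarray]:
    """Genes-plus-spike-ins matrix where every row follows the planted law.

    Gene concentrations are log-uniform over ``gene_log2_range`` (base-2
    exponents); each entry is a drop-out/mixture draw exactly like the
    spike-ins, so the planted per-gene zero probability is known in closed
    form. Returns (counts, reference, gene_concentrations).
    """
    seed = pm.seed if seed is None else seed
    spikes, ref = generate_spikein_counts(pm)
    rng = np.random.default_rng(seed + 1)
    conc = np.exp2(rng.uniform(*gene_log2_range, n_genes))
    rows = []
    for y in conc:
        counts = pm.sample_mixture(float(y), pm.n_cells, rng)
        dropped = rng.random(pm.n_cells) < pm.dropout_probability(y)
        rows.append(np.where(dropped, 0, counts))
    genes = pd.DataFrame(
        np.asarray(rows),
        index=[f"gene{i}" for i in range(n_genes)],
        columns=spikes.values.columns,
    )
    values = pd.concat([genes, spikes.values])
    flags = pd.concat(
        [
            pd.Series(False, index=genes.index),
            pd.Series(True, index=spikes.values.index),
        ]
    )
    return CountsMatrix(values=values, is_spikein=flags), ref, conc


def generate_cell_matrix_with_clusters(
    n_cells: int,
    n_genes: int,
    k: int,
    effect: float,
    marker_fraction: float = 0.2,
    base_mean_range: tuple[float, float] = (1.0, 50.0),
    dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[CountsMatrix, ClusterLabels]:
    """NB counts with planted group structure.

    Cells split evenly into k groups. A ``marker_fraction`` of genes are
    markers assigned round-robin to groups; a marker's mean is multiplied
    by ``effect`` in its group. Counts are gamma-Poisson (NB) with
    variance mean + dispersion * mean^2.
    """
    if k > n_cells:
        raise ValueError("k cannot exceed n_cells")
    if effect < 1:
        raise ValueError("effect must be >= 1")
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(k), int(np.ceil(n_cells / k)))[:n_cells]
    lo, hi = np.log(base_mean_range[0]), np.log(base_mean_range[1])
    base = np.exp(rng.uniform(lo, hi, size=n_genes))
    n_markers = int(round(marker_fraction * n_genes))
    marker_group = np.full(n_genes, -1)
    marker_group[:n_markers] = np.arange(n_markers) % k

    means = np.tile(base[:, None], (1, n_cells))
    for g in range(k):
        rows = marker_group == g
        cols = groups == g
        means[np.ix_(rows, cols)] *= effect

    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, means / shape)
    else:
        lam = means
    counts = rng.poisson(lam)
    values = pd.DataFrame(
        counts,
        index=[f"gene{i}" for i in range(n_genes)],
        columns=[f"cell{i}" for i in range(n_cells)],
    )
    m = CountsMatrix(values=values, is_spikein=pd.Series(False, index=values.index))
    labels = ClusterLabels(
        cell_ids=list(values.columns), labels=[int(g) for g in groups]
    )
    return m, labels


def generate_experiment(
    pm: PlantedModel,
    n_genes: int = 400,
    k: int = 3,
    effect: float = 8.0,
    marker_fraction: float = 0.2,
    seed: int | None = None,
) -> tuple[CountsMatrix, SpikeInReference, ClusterLabels]:
    """Full fixture: endogenous genes with planted clusters stacked on top
    of spike-in rows from the planted noise model, plus the reference."""
    seed = pm.seed if seed is None else seed
    cells_m, truth = generate_cell_matrix_with_clusters(
        n_cells=pm.n_cells,
        n_genes=n_genes,
        k=k,
        effect=effect,
        marker_fraction=marker_fraction,
        seed=seed,
    )
    spikes_m, ref = generate_spikein_counts(pm)
    spikes_m.values.columns = cells_m.values.columns  # align cell ids
    values = pd.concat([cells_m.values, spikes_m.values])
    flags = pd.concat(
        [
            pd.Series(False, index=cells_m.values.index),
            pd.Series(True, index=spikes_m.values.index),
        ]
    )
    return CountsMatrix(values=values, is_spikein=flags), ref, truth
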