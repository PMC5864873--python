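"""Counts and spike-in reference I/O, plus adjusted-cpm normalization.

A counts matrix is genes x cells. Spike-in rows (synthetic RNA controls of
known concentration, conventionally named ``ERCC-*``) are flagged so the
noise-fitting stages can separate them from endogenous genes. Normalization
is counts-per-million followed by a per-library detection-rate scaling
factor, which damps batch-dependent differences in library complexity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountsMatrix",
    "SpikeInReference",
    "read_counts",
    "write_counts",
    "read_spikein_reference",
    "compute_detection_rates",
    "normalize_adjusted_cpm",
]

DEFAULT_SPIKE_PREFIX = "ERCC-"


class CountsValidationError(ValueError):
    """Raised when a counts table violates its invariants."""


class CountsParseError(ValueError):
    """Raised when a counts file cannot be parsed."""


@dataclass
class CountsMatrix:
    """Genes x cells count table with spike-in row flags.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are cell ids. Raw counts are
        non-negative integers; normalized counts are non-negative reals.
    is_spikein
        Boolean Series aligned to ``values.index``.
    normalized
        True once adjusted-cpm normalization has been applied.
    """

    values: pd.DataFrame
    is_spikein: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise CountsValidationError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise CountsValidationError(f"duplicate cell ids: {dups}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise CountsValidationError("counts contain missing/non-finite entries")
        if arr.size and (arr < 0).any():
            raise CountsValidationError("counts contain negative entries")
        self.is_spikein = self.is_spikein.reindex(v.index).astype(bool)
        if self.is_spikein.isna().any():
            raise CountsValidationError("is_spikein flag missing for some genes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def spikeins(self) -> pd.DataFrame:
        """Subset of rows that are spike-in controls."""
        return self.values.loc[self.is_spikein.to_numpy()]

    def endogenous(self) -> pd.DataFrame:
        """Subset of rows that are endogenous genes."""
        return self.values.loc[~self.is_spikein.to_numpy()]


@dataclass
class SpikeInReference:
    """Expected spike-in molecule numbers per cell-equivalent sample.

    ``molecules`` is indexed by spike-in id; values are the expected number
    of transcript molecules y_i in each sample after applying the user's
    dilution factor.
    """

    molecules: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if self.molecules.index.duplicated().any():
            raise CountsValidationError("duplicate spike-in ids in reference")
        if (self.molecules <= 0).any():
            bad = self.molecules.index[self.molecules <= 0].tolist()
            raise CountsValidationError(
                f"non-positive expected molecule numbers for: {bad}"
            )

    @property
    def spikein_ids(self) -> list[str]:
        return list(self.molecules.index)


def _flag_spikeins(
    gene_ids: pd.Index,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    spike_ids: list[str] | None = None,
) -> pd.Series:
    if spike_ids is not None:
        flags = gene_ids.isin(set(spike_ids))
    else:
        flags = gene_ids.str.startswith(spike_prefix)
    return pd.Series(np.asarray(flags, dtype=bool), index=gene_ids)


def read_counts(
    path: str | os.PathLike,
    format: str = "tsv",
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    spike_ids: list[str] | None = None,
) -> CountsMatrix:
    """Read a genes x cells counts table.

    ``tsv``: tab-separated, header row of cell ids, first column gene ids.
    ``mtx``: MatrixMarket coordinate file with sidecar ``genes.txt`` /
    ``cells.txt`` (one id per line) next to it.

    Spike-in rows are flagged by id prefix (default ``ERCC-``) or by an
    explicit ``spike_ids`` list, which takes precedence.
    """
    path = os.fspath(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        except pd.errors.EmptyDataError as exc:
            raise CountsParseError(f"{path}: empty counts file") from exc
        except pd.errors.ParserError as exc:
            raise CountsParseError(f"{path}: {exc}") from exc
        if df.shape[1] == 0:
            raise CountsParseError(f"{path}: no cell columns found")
        non_numeric = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ].tolist()
        if non_numeric:
            raise CountsParseError(
                f"{path}: non-numeric entries in columns {non_numeric}"
            )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        base = os.path.dirname(path)
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # mmread raises bare ValueError on bad files
            raise CountsParseError(f"{path}: {exc}") from exc
        genes = _read_id_file(os.path.join(base, "genes.txt"))
        cells = _read_id_file(os.path.join(base, "cells.txt"))
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        if dense.shape != (len(genes), len(cells)):
            raise CountsParseError(
                f"{path}: matrix is {dense.shape} but sidecars name "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        df = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        raise ValueError(f"unknown counts format: {format!r}")
    return CountsMatrix(
        values=df,
        is_spikein=_flag_spikeins(df.index, spike_prefix, spike_ids),
    )


def _read_id_file(path: str) -> list[str]:
    if not os.path.exists(path):
        raise CountsParseError(f"missing sidecar id file: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise CountsParseError(f"{path}: empty id file")
    return ids


def write_counts(m: CountsMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a counts matrix; round-trips through :func:`read_counts`."""
    path = os.fspath(path)
    if format == "tsv":
        out = m.values.copy()
        out.index.name = "gene_id"
        # repr-precision floats so normalized values survive the round trip
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "mtx":
        base = os.path.dirname(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values.to_numpy()))
        with open(os.path.join(base, "genes.txt"), "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(os.path.join(base, "cells.txt"), "w") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format: {format!r}")


def read_spikein_reference(
    path: str | os.PathLike, dilution: float = 1.0
) -> SpikeInReference:
    """Read a spike-in reference TSV (columns ``spikein_id``, ``molecules``).

    ``molecules`` in the file is the stock concentration per sample; the
    returned expected molecule numbers are ``concentration * dilution``.
    """
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"spikein_id", "molecules"}
    if not required.issubset(df.columns):
        raise CountsParseError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    ser = pd.Series(
        df["molecules"].to_numpy(dtype=float) * dilution,
        index=df["spikein_id"].astype(str),
    )
    return SpikeInReference(molecules=ser)


def compute_detection_rates(m: CountsMatrix) -> pd.Series:
    """Per-cell fraction of ever-observed genes detected in that cell.

    A gene counts as observed in a cell when its count is >= 1; the
    denominator is the number of genes observed in at least one cell.
    """
    arr = m.values.to_numpy()
    observed_any = (arr >= 1).any(axis=1)
    n_observed = int(observed_any.sum())
    if n_observed == 0:
        raise CountsValidationError("no gene is observed in any cell")
    detected = (arr[observed_any] >= 1).sum(axis=0)
    return pd.Series(detected / n_observed, index=m.values.columns)


def normalize_adjusted_cpm(m: CountsMatrix) -> CountsMatrix:
    """Normalize raw counts to adjusted counts per million.

    Step 1 scales each cell to one million total counts. Step 2 divides each
    cell by its detection-rate scaling factor (library detection rate over
    the median detection rate), so libraries that detect unusually many
    genes are shrunk toward the cohort median.
    """
    totals = m.values.sum(axis=0)
    zero_cells = totals.index[totals == 0].tolist()
    if zero_cells:
        raise CountsValidationError(f"cells with zero total counts: {zero_cells}")
    cpm = m.values.div(totals, axis=1) * 1e6
    rates = compute_detection_rates(m)
    scaling = rates / rates.median()
    adjusted = cpm.div(scaling, axis=1)
    return CountsMatrix(
        values=adjusted, is_spikein=m.is_spikein.copy(), normalized=True
    )
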