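"""Simulated technical replicates.

Each replicate re-draws every entry of the observed counts matrix through
the fitted noise and drop-out models:

* observed zero  -> sample a true molecule number y from the gene's
  recovery distribution; emit 0 if y = 0, otherwise a draw from Z(y);
* 0 < c <= k     -> inject a drop-out (emit 0) with probability
  Pr(X=0 | Y=c), otherwise draw from Z(c);
* c > k          -> draw from Z(c).

Spike-in rows are transformed like any other gene. Non-integer normalized
counts are used as-is as the Z parameter and compared to k as reals.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CountsMatrix, write_counts
from .dropout_model import DropoutModels
from .noise_model import MixtureNoiseModel, sample_z

__all__ = [
    "SimulatedReplicate",
    "simulate_replicate",
    "simulate_replicates",
    "write_replicates",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulatedReplicate:
    """One simulated technical replicate of a counts matrix."""

    values: pd.DataFrame  # integer counts, same index/columns as the source
    replicate_index: int
    seed: int

    def as_counts(self, is_spikein: pd.Series) -> CountsMatrix:
        return CountsMatrix(values=self.values, is_spikein=is_spikein)


def _replicate_rng(base_seed: int, index: int) -> np.random.Generator:
    # fixed derivation rule so replicates can be produced independently and
    # in parallel yet reassemble deterministically
    return np.random.default_rng([int(base_seed), int(index)])


def simulate_replicate(
    m: CountsMatrix,
    noise: MixtureNoiseModel,
    dropout: DropoutModels,
    rng: np.random.Generator,
    replicate_index: int = 0,
    seed: int = 0,
) -> SimulatedReplicate:
    """Apply the noise and drop-out models once to every matrix entry."""
    vals = m.values.to_numpy(dtype=float)
    k = dropout.injection.k
    # parameter of the Z draw for each entry; NaN means "emit 0, no draw"
    param = np.where(vals > 0, vals, np.nan)

    zero_rows = np.flatnonzero((vals == 0).any(axis=1))
    gene_ids = m.values.index
    for gi in zero_rows:
        gid = str(gene_ids[gi])
        cols = np.flatnonzero(vals[gi] == 0)
        rec = dropout.recovery.get(gid)
        if rec is None:
            if k == 0:
                continue  # no calibrated drop-outs: zeros stay zero
            raise SimulationError(
                f"gene {gid!r} has zeros but no recovery distribution"
            )
        y = rng.choice(rec.recovery.size, size=cols.size, p=rec.recovery)
        param[gi, cols] = np.where(y > 0, y, np.nan)

    if k > 0:
        low = (vals > 0) & (vals <= k)
        if low.any():
            pdrop = np.clip(
                dropout.injection.slope * vals[low] + dropout.injection.intercept,
                0.0,
                1.0,
            )
            dropped = rng.random(pdrop.shape) < pdrop
            lowpar = param[low]
            lowpar[dropped] = np.nan
            param[low] = lowpar

    out = np.zeros_like(vals, dtype=np.int64)
    draw_mask = ~np.isnan(param)
    if draw_mask.any():
        out[draw_mask] = sample_z(noise, param[draw_mask], rng)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return SimulatedReplicate(values=values, replicate_index=replicate_index, seed=seed)


def simulate_replicates(
    m: CountsMatrix,
    noise: MixtureNoiseModel,
    dropout: DropoutModels,
    n_replicates: int = 100,
    base_seed: int = 0,
) -> list[SimulatedReplicate]:
    """Generate a deterministic set of replicates from one master seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reps = []
    for r in range(n_replicates):
        rng = _replicate_rng(base_seed, r)
        reps.append(
            simulate_replicate(
                m, noise, dropout, rng, replicate_index=r, seed=base_seed
            )
        )
    return reps


def _model_hash(*paths_or_objs) -> str:
    h = hashlib.sha256()
    for obj in paths_or_objs:
        h.update(repr(obj).encode())
    return h.hexdigest()[:16]


def write_replicates(
    reps: list[SimulatedReplicate],
    outdir: str | os.PathLike,
    prefix: str = "simulated",
    is_spikein: pd.Series | None = None,
    noise: MixtureNoiseModel | None = None,
    dropout: DropoutModels | None = None,
) -> str:
    """Write replicates as ``<prefix>_rep<NNN>.tsv`` plus a JSON manifest."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    files = []
    for rep in reps:
        name = f"{prefix}_rep{rep.replicate_index:03d}.tsv"
        flags = (
            is_spikein
            if is_spikein is not None
            else pd.Series(False, index=rep.values.index)
        )
        write_counts(rep.as_counts(flags), os.path.join(outdir, name))
        files.append(name)
    manifest = {
        "prefix": prefix,
        "n_replicates": len(reps),
        "seed": reps[0].seed if reps else None,
        "files": files,
        "noise_model_hash": _model_hash(noise) if noise is not None else None,
        "dropout_model_hash": _model_hash(dropout) if dropout is not None else None,
    }
    manifest_path = os.path.join(outdir, f"{prefix}_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
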