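"""Drop-out injection and recovery distributions.

Drop-outs are false-negative zeros: a transcript present in the cell that
was never captured or amplified. Spike-ins give a direct handle on the
phenomenon because their true molecule numbers y are known.

The *injection* distribution Pr(X=0 | Y=y) is a linear fit D = a*y + b of
the per-spike-in zero fraction on expected molecules, clamped to [0,1] and
truncated at k, the largest integer molecule count with positive density.
Every gene shares this injection density.

The *recovery* distribution Pr(Y_j=y | X_j=0) is gene-specific and obtained
by Bayes' theorem with a prior that puts mass prior_zero on y=0 and is
uniform over y = 1..k. prior_zero is determined by forcing the law of total
probability to reproduce the gene's observed zero fraction:

    prior_zero = (Pr(X_j=0) - S) / (1 - S),   S = (1/k) * sum_{y=1..k} Pr(X=0|Y=y)

with Pr(X=0|Y=0) taken as 1 (no molecules, necessarily a zero).
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountsMatrix, SpikeInReference

__all__ = [
    "DropoutInjectionModel",
    "GeneRecoveryDistribution",
    "DropoutModels",
    "fit_dropout_injection",
    "injection_probability",
    "compute_recovery_distribution",
    "fit_dropout_models",
    "sample_recovery",
]


class DropoutModelError(ValueError):
    pass


@dataclass
class DropoutInjectionModel:
    """Linear zero-observation density D(y) = clamp(slope*y + intercept, 0, 1),
    zero beyond the threshold k (no extrapolation past the calibrated range)."""

    slope: float
    intercept: float
    k: int

    def injection_probability(self, y) -> float | np.ndarray:
        return injection_probability(self, y)


def injection_probability(model: DropoutInjectionModel, y) -> float | np.ndarray:
    """Probability of observing zero given y true molecules."""
    yarr = np.asarray(y, dtype=float)
    if (yarr < 0).any():
        raise DropoutModelError("molecule number y must be non-negative")
    d = np.clip(model.slope * yarr + model.intercept, 0.0, 1.0)
    d = np.where(yarr > model.k, 0.0, d)
    return float(d) if np.isscalar(y) else d


def fit_dropout_injection(
    spike_counts: pd.DataFrame, ref: SpikeInReference
) -> DropoutInjectionModel:
    """Regress per-spike-in zero fractions on expected molecule numbers.

    ``spike_counts`` is spike-ins x cells; only spike-ins present in both
    the counts and the reference contribute. k is the largest integer
    y >= 1 with positive clamped density, capped at the largest expected
    molecule number among the spike-ins used (the calibrated range).
    """
    shared = [sid for sid in spike_counts.index if sid in ref.molecules.index]
    if len(shared) < 2:
        raise DropoutModelError(
            f"only {len(shared)} spike-ins shared between counts and "
            "reference (need >= 2)"
        )
    sub = spike_counts.loc[shared]
    d = (sub.to_numpy() == 0).mean(axis=1)
    y = ref.molecules.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DropoutModelError("all spike-ins have identical expected molecules")
    res = stats.linregress(y, d)
    slope, intercept = float(res.slope), float(res.intercept)
    k = _positive_density_threshold(slope, intercept, cap=int(np.floor(y.max())))
    if (d == 0).all():
        warnings.warn(
            "no zeros observed in any spike-in; drop-out injection disabled (k=0)",
            stacklevel=2,
        )
        k = 0
    return DropoutInjectionModel(slope=slope, intercept=intercept, k=k)


def _positive_density_threshold(slope: float, intercept: float, cap: int) -> int:
    """Largest integer y in [1, cap] with slope*y + intercept > 0, else 0."""
    if cap < 1:
        return 0
    if slope < 0:
        # line crosses zero at y0 = -intercept/slope
        y0 = -intercept / slope
        k = int(np.ceil(y0 - 1e-12)) - 1  # largest integer strictly below y0
        return max(0, min(cap, k))
    # flat or rising line: positive at cap iff positive anywhere in [1, cap]
    return cap if slope * cap + intercept > 0 else 0


@dataclass
class GeneRecoveryDistribution:
    """Gene-specific posterior over true molecule numbers given an observed zero."""

    gene_id: str
    zero_fraction: float
    prior_zero: float
    prior_uniform: float
    recovery: np.ndarray  # probabilities over y = 0..k

    def __post_init__(self) -> None:
        self.recovery = np.asarray(self.recovery, dtype=float)
        if not np.isclose(self.recovery.sum(), 1.0, atol=1e-9):
            raise DropoutModelError(
                f"recovery distribution for {self.gene_id} does not sum to 1"
            )

    @property
    def k(self) -> int:
        return self.recovery.size - 1


def compute_recovery_distribution(
    zero_fraction: float,
    model: DropoutInjectionModel,
    gene_id: str = "",
) -> GeneRecoveryDistribution:
    """Bayes-invert the injection density for one gene.

    The prior is prior_zero at y=0 and uniform mass prior_uniform on
    y = 1..k, chosen so the marginal zero probability matches the gene's
    observed zero fraction. When the observed zero fraction is below the
    average injection density S, the exact solution for prior_zero is
    negative; it is clamped to [0,1] and the posterior renormalized.
    """
    if zero_fraction <= 0.0:
        raise DropoutModelError("gene has no zeros; recovery distribution unneeded")
    if zero_fraction > 1.0:
        raise DropoutModelError("zero_fraction must lie in (0, 1]")
    if model.k < 1:
        raise DropoutModelError("recovery requires an injection threshold k >= 1")
    k = model.k
    inj = np.asarray(injection_probability(model, np.arange(1, k + 1)))
    s = float(inj.mean())
    clamped = False
    if s >= 1.0:
        # injection says zeros are certain for all y <= k: the observed zero
        # fraction itself is the only usable mass estimate at y = 0
        prior_zero = zero_fraction
        clamped = True
        warnings.warn(
            f"degenerate injection density (S=1) for gene {gene_id!r}; "
            "prior_zero set to the observed zero fraction",
            stacklevel=2,
        )
    else:
        raw = (zero_fraction - s) / (1.0 - s)
        prior_zero = float(np.clip(raw, 0.0, 1.0))
        clamped = raw != prior_zero
    prior_uniform = (1.0 - prior_zero) / k
    prior = np.concatenate([[prior_zero], np.full(k, prior_uniform)])
    likelihood = np.concatenate([[1.0], inj])  # Pr(X=0|Y=0) assumed 1
    recovery = likelihood * prior / zero_fraction
    if clamped:
        recovery = recovery / recovery.sum()
    return GeneRecoveryDistribution(
        gene_id=gene_id,
        zero_fraction=float(zero_fraction),
        prior_zero=prior_zero,
        prior_uniform=prior_uniform,
        recovery=recovery,
    )


def sample_recovery(
    dist: GeneRecoveryDistribution,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Categorical draw(s) of a true molecule number y in 0..k."""
    draws = rng.choice(dist.recovery.size, size=size, p=dist.recovery)
    return int(draws) if size is None else draws


@dataclass
class DropoutModels:
    """Injection model plus per-gene recovery distributions."""

    injection: DropoutInjectionModel
    recovery: dict[str, GeneRecoveryDistribution] = field(default_factory=dict)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#slope={self.injection.slope!r}\n")
            fh.write(f"#intercept={self.injection.intercept!r}\n")
            fh.write(f"#k={self.injection.k}\n")
            rows = [
                (
                    g.gene_id,
                    g.zero_fraction,
                    g.prior_zero,
                    ",".join(f"{p:.17g}" for p in g.recovery),
                )
                for g in self.recovery.values()
            ]
            pd.DataFrame(
                rows, columns=["gene_id", "zero_fraction", "prior_zero", "recovery"]
            ).to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DropoutModels":
        header: dict[str, str] = {}
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, val = line[1:].strip().split("=", 1)
                    header[key] = val
                else:
                    body.append(line)
        injection = DropoutInjectionModel(
            slope=float(header["slope"]),
            intercept=float(header["intercept"]),
            k=int(header["k"]),
        )
        recovery: dict[str, GeneRecoveryDistribution] = {}
        if body:
            df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
            for r in df.itertuples():
                probs = np.array([float(p) for p in str(r.recovery).split(",")])
                recovery[str(r.gene_id)] = GeneRecoveryDistribution(
                    gene_id=str(r.gene_id),
                    zero_fraction=float(r.zero_fraction),
                    prior_zero=float(r.prior_zero),
                    prior_uniform=(1.0 - float(r.prior_zero)) / max(1, probs.size - 1),
                    recovery=probs,
                )
        return cls(injection=injection, recovery=recovery)


def fit_dropout_models(m: CountsMatrix, ref: SpikeInReference) -> DropoutModels:
    """Fit injection from spike-ins, then recovery for every gene with zeros.

    Spike-in rows get recovery distributions too — the simulator transforms
    them alongside endogenous genes. Genes without zeros need none; with
    k = 0 no drop-outs were calibrated and observed zeros are left alone.
    """
    injection = fit_dropout_injection(m.spikeins(), ref)
    recovery: dict[str, GeneRecoveryDistribution] = {}
    if injection.k >= 1:
        zero_frac = (m.values.to_numpy() == 0).mean(axis=1)
        for gid, zf in zip(m.values.index, zero_frac):
            if zf > 0:
                recovery[str(gid)] = compute_recovery_distribution(
                    zf, injection, gene_id=str(gid)
                )
    return DropoutModels(injection=injection, recovery=recovery)
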