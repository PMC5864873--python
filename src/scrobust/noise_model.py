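"""Spike-in mixture noise model Z(c).

Technical variance of counts is modelled per spike-in as a two-component
mixture of a Poisson and a negative binomial sharing the observed mean:

    Z_i ~ (1 - alpha_i) * Pois(mu_i) + alpha_i * NBin(mu_i, sigma_i)

mu_i and sigma_i are the observed mean and standard deviation of spike-in
i across cells; alpha_i is fitted by grid search minimizing the total
absolute difference between the empirical count frequencies and the mixture
pmf. The per-spike-in parameters are then regressed onto log2 mean
expression, yielding a generalized single-parameter model Z(c) that can be
evaluated at any observed count c during replicate simulation.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountsMatrix

__all__ = [
    "SpikeInFit",
    "MixtureNoiseModel",
    "mixture_pmf",
    "fit_spikein_mixture",
    "fit_noise_model",
    "regress_mixture_parameters",
    "evaluate_alpha",
    "evaluate_sigma",
    "sample_from_mixture",
    "sample_z",
]

ALPHA_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


class NoiseModelError(ValueError):
    """Raised for invalid mixture parameterizations or unusable fits."""


def _nb_size_prob(mu: float | np.ndarray, sigma: float | np.ndarray):
    """(size r, success prob p) of an NB with given mean and SD.

    Requires sigma^2 > mu (overdispersion); r = mu^2/(sigma^2 - mu),
    p = r/(r + mu).
    """
    var = np.square(sigma)
    r = np.square(mu) / (var - mu)
    p = r / (r + mu)
    return r, p


def mixture_pmf(
    x: int | np.ndarray, alpha: float, mu: float, sigma: float
) -> float | np.ndarray:
    """Pmf of the Poisson/NB mixture at integer count(s) x."""
    if mu <= 0:
        raise NoiseModelError("mu must be positive")
    if not 0.0 <= alpha <= 1.0:
        raise NoiseModelError("alpha must lie in [0, 1]")
    pois = stats.poisson.pmf(x, mu)
    if alpha == 0.0:
        return pois
    if sigma**2 <= mu:
        raise NoiseModelError(
            "NB component undefined: sigma^2 <= mu (no overdispersion)"
        )
    r, p = _nb_size_prob(mu, sigma)
    return (1.0 - alpha) * pois + alpha * stats.nbinom.pmf(x, r, p)


@dataclass
class SpikeInFit:
    """Per-spike-in mixture fit; invalid fits are excluded from regression."""

    spikein_id: str
    mu: float
    sigma: float
    alpha: float
    valid: bool


def fit_spikein_mixture(counts, spikein_id: str = "") -> SpikeInFit:
    """Fit the mixture weight alpha for one spike-in's per-cell counts.

    mu and sigma are the sample mean and standard deviation. alpha is the
    grid value in {0, 0.01, ..., 1} minimizing the summed absolute
    difference between empirical count frequencies (counts rounded to the
    nearest integer) and the mixture pmf over x = 0..max observed; ties go
    to the smallest alpha. Degenerate spike-ins (mu = 0, sigma = 0, or
    sigma^2 <= mu, where the NB component is undefined) get alpha = 0 and
    are marked invalid.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise NoiseModelError("need at least 2 observations to fit a spike-in")
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=1))
    if mu == 0.0 or sigma == 0.0 or sigma**2 <= mu:
        return SpikeInFit(spikein_id, mu, sigma, alpha=0.0, valid=False)

    rounded = np.round(counts).astype(np.int64)
    xmax = int(rounded.max())
    xs, freq = np.unique(rounded, return_counts=True)
    emp = freq / rounded.size

    # L1 distance over the full support x = 0..xmax, computed sparsely:
    #   sum_x |emp - mix| = sum_{x observed} (|emp - mix| - mix) + CDF_mix(xmax)
    # since emp(x) = 0 off the observed values and mix(x) >= 0.
    r, p = _nb_size_prob(mu, sigma)
    pois = stats.poisson.pmf(xs, mu)
    nb = stats.nbinom.pmf(xs, r, p)
    cdf_mix = (1.0 - ALPHA_GRID) * stats.poisson.cdf(xmax, mu) + ALPHA_GRID * stats.nbinom.cdf(xmax, r, p)
    mix = (1.0 - ALPHA_GRID[:, None]) * pois[None, :] + ALPHA_GRID[:, None] * nb[None, :]
    objective = (np.abs(emp[None, :] - mix) - mix).sum(axis=1) + cdf_mix
    alpha = float(ALPHA_GRID[int(np.argmin(objective))])  # first min = smallest alpha
    return SpikeInFit(spikein_id, mu, sigma, alpha=alpha, valid=True)


@dataclass
class MixtureNoiseModel:
    """Generalized noise model: alpha and sigma as linear functions of log2 c.

    alpha(c) = clamp(alpha_slope * log2(c) + alpha_intercept, 0, 1)
    sigma(c) = 2 ** (sigma_slope * log2(c) + sigma_intercept)

    Whenever sigma(c)^2 <= c the NB component would be ill-defined, so
    alpha(c) is forced to 0 and Z(c) reduces to Pois(c).
    """

    alpha_slope: float
    alpha_intercept: float
    sigma_slope: float
    sigma_intercept: float
    fits: list[SpikeInFit] = field(default_factory=list)

    # -- persistence ------------------------------------------------------
    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for key in ("alpha_slope", "alpha_intercept", "sigma_slope", "sigma_intercept"):
                fh.write(f"#{key}={getattr(self, key)!r}\n")
            df = pd.DataFrame(
                [
                    (f.spikein_id, f.mu, f.sigma, f.alpha, f.valid)
                    for f in self.fits
                ],
                columns=["spikein_id", "mu", "sigma", "alpha", "valid"],
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "MixtureNoiseModel":
        header: dict[str, float] = {}
        body_lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, val = line[1:].strip().split("=", 1)
                    header[key] = float(val)
                else:
                    body_lines.append(line)
        fits = []
        if body_lines:
            df = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t")
            fits = [
                SpikeInFit(str(r.spikein_id), r.mu, r.sigma, r.alpha, bool(r.valid))
                for r in df.itertuples()
            ]
        return cls(fits=fits, **header)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        raise NoiseModelError(
            "degenerate regression: all spike-in means identical; "
            "provide spike-ins spanning a range of concentrations"
        )
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def regress_mixture_parameters(fits: list[SpikeInFit]) -> MixtureNoiseModel:
    """OLS of alpha_i and log2(sigma_i) on log2(mu_i) over valid fits."""
    valid = [f for f in fits if f.valid]
    if len(valid) < 2:
        raise NoiseModelError(
            f"only {len(valid)} usable spike-in fits (need >= 2); "
            "more spike-ins or deeper coverage required"
        )
    log_mu = np.log2([f.mu for f in valid])
    a_slope, a_int = _ols_line(log_mu, np.array([f.alpha for f in valid]))
    s_slope, s_int = _ols_line(log_mu, np.log2([f.sigma for f in valid]))
    return MixtureNoiseModel(
        alpha_slope=a_slope,
        alpha_intercept=a_int,
        sigma_slope=s_slope,
        sigma_intercept=s_int,
        fits=list(fits),
    )


def fit_noise_model(m: CountsMatrix) -> MixtureNoiseModel:
    """Fit the generalized model from the spike-in rows of a counts matrix."""
    spikes = m.spikeins()
    fits = [
        fit_spikein_mixture(spikes.loc[sid].to_numpy(), spikein_id=str(sid))
        for sid in spikes.index
    ]
    return regress_mixture_parameters(fits)


def _check_positive(c: np.ndarray) -> None:
    if (c <= 0).any():
        raise NoiseModelError("Z(c) is defined for positive c only")


def evaluate_alpha(model: MixtureNoiseModel, c) -> float | np.ndarray:
    """Mixture weight at count level c, clamped to [0,1]; 0 when the NB
    component would be ill-defined (sigma(c)^2 <= c)."""
    carr = np.asarray(c, dtype=float)
    _check_positive(carr)
    alpha = np.clip(
        model.alpha_slope * np.log2(carr) + model.alpha_intercept, 0.0, 1.0
    )
    sigma = evaluate_sigma(model, carr)
    alpha = np.where(np.square(sigma) <= carr, 0.0, alpha)
    return float(alpha) if np.isscalar(c) else alpha


def evaluate_sigma(model: MixtureNoiseModel, c) -> float | np.ndarray:
    """Model SD at count level c (always positive, being a power of 2)."""
    carr = np.asarray(c, dtype=float)
    _check_positive(carr)
    sigma = np.exp2(model.sigma_slope * np.log2(carr) + model.sigma_intercept)
    return float(sigma) if np.isscalar(c) else sigma


def sample_z(
    model: MixtureNoiseModel, c, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw from Z(c) for an array of count levels c."""
    carr = np.atleast_1d(np.asarray(c, dtype=float))
    _check_positive(carr)
    alpha = np.asarray(evaluate_alpha(model, carr))
    out = rng.poisson(carr)
    use_nb = rng.random(carr.shape) < alpha
    if use_nb.any():
        sigma = np.asarray(evaluate_sigma(model, carr))[use_nb]
        r, p = _nb_size_prob(carr[use_nb], sigma)
        out[use_nb] = rng.negative_binomial(r, p)
    return out


def sample_from_mixture(
    model: MixtureNoiseModel, c: float, rng: np.random.Generator
) -> int:
    """Draw a single simulated count from Z(c)."""
    return int(sample_z(model, [c], rng)[0])
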