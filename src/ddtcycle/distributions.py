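"""Closed-form passage-time laws.

A single cell-cycle checkpoint is modeled as a latent variable that starts at
0, drifts upward at rate ``mu`` (1/h) with diffusion intensity ``sigma``
(h^-1/2), and triggers passage on first reaching 1.  The passage time then
follows an inverse Gaussian (Wald) distribution

    f(t; mu, sigma) = 1 / (sigma * sqrt(2 pi t^3))
                      * exp(-(mu t - 1)^2 / (2 sigma^2 t)),   t > 0,

with mean ``1/mu``, variance ``sigma^2 / mu^3`` and coefficient of variation
``sigma / sqrt(mu)``.  The competitor exponentially-modified Gaussian (EMG)
law describes checkpoint passage as a Gaussian "transit" plus an exponential
"dwell"; it lacks the switch-like threshold mechanism but is a standard
empirical model for intermitotic-time data.

All densities are evaluated through their log form and exponentiated, so that
likelihood code can take logs safely; outside the support the densities return
exactly 0 (and the log densities ``-inf``), never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CheckpointParams",
    "DDTModel",
    "EMGModel",
    "wald_pdf",
    "wald_logpdf",
    "wald_moments",
    "shifted_wald_pdf",
    "wald_sample",
    "emg_pdf",
    "emg_logpdf",
]


@dataclass(frozen=True)
class CheckpointParams:
    """Drift/diffusion pair governing one checkpoint's passage-time law.

    Parameters
    ----------
    mu : float
        Drift rate toward the threshold, in 1/hour.  The mean passage time
        is ``1/mu``.
    sigma : float
        Diffusion intensity, in hour^(-1/2).  The passage-time variance is
        ``sigma**2 / mu**3``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be finite and > 0, got {self.mu!r}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma!r}")

    @property
    def mean(self) -> float:
        return 1.0 / self.mu

    @property
    def variance(self) -> float:
        return self.sigma**2 / self.mu**3

    @property
    def std(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def cv(self) -> float:
        return self.sigma / float(np.sqrt(self.mu))


@dataclass(frozen=True)
class DDTModel:
    """An m-checkpoint drift-diffusion+threshold model.

    The intermitotic time is the sum of the ``m`` independent checkpoint
    passage times, so its density is the m-fold convolution of the component
    Wald densities.  Because convolution commutes, the order of the
    checkpoints is not identifiable from IMT data alone.
    """

    checkpoints: tuple[CheckpointParams, ...] = field()

    def __init__(self, checkpoints: Sequence[CheckpointParams]) -> None:
        cps = tuple(checkpoints)
        if len(cps) < 1:
            raise ValueError("a DDT model needs at least one checkpoint")
        for cp in cps:
            if not isinstance(cp, CheckpointParams):
                raise TypeError(f"expected CheckpointParams, got {type(cp)!r}")
        object.__setattr__(self, "checkpoints", cps)

    @property
    def m(self) -> int:
        return len(self.checkpoints)

    @property
    def mean(self) -> float:
        """Mean IMT: sum of the checkpoint means."""
        return sum(cp.mean for cp in self.checkpoints)

    @property
    def variance(self) -> float:
        """IMT variance: sum of the checkpoint variances (independence)."""
        return sum(cp.variance for cp in self.checkpoints)


@dataclass(frozen=True)
class EMGModel:
    """Exponentially-modified Gaussian checkpoint model.

    Passage time = Gaussian transit N(gauss_mean, gauss_sd^2) + exponential
    dwell Exp(rate).  Three parameters; support is the whole real line
    (negligible negative mass when gauss_mean >> gauss_sd).
    """

    rate: float
    gauss_mean: float
    gauss_sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValueError(f"rate must be finite and > 0, got {self.rate!r}")
        if not np.isfinite(self.gauss_mean):
            raise ValueError(f"gauss_mean must be finite, got {self.gauss_mean!r}")
        if not (np.isfinite(self.gauss_sd) and self.gauss_sd > 0):
            raise ValueError(
                f"gauss_sd must be finite and > 0, got {self.gauss_sd!r}"
            )

    @property
    def mean(self) -> float:
        return self.gauss_mean + 1.0 / self.rate

    @property
    def variance(self) -> float:
        return self.gauss_sd**2 + 1.0 / self.rate**2


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    return t


def wald_logpdf(t, params: CheckpointParams):
    """Log of the Wald passage-time density; ``-inf`` for t <= 0."""
    t = _check_times(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.full(t.shape, -np.inf)
    pos = t > 0
    tp = t[pos]
    out[pos] = (
        -np.log(params.sigma)
        - 0.5 * np.log(2.0 * np.pi * tp**3)
        - (params.mu * tp - 1.0) ** 2 / (2.0 * params.sigma**2 * tp)
    )
    return out[0] if scalar else out


def wald_pdf(t, params: CheckpointParams):
    """Wald (inverse Gaussian) passage-time density, in 1/hour.

    Returns exactly 0 for ``t <= 0`` (the passage time is positive).
    """
    logp = wald_logpdf(t, params)
    return np.exp(logp)


def wald_moments(params: CheckpointParams) -> tuple[float, float, float]:
    """(mean, variance, cv) of the Wald law: (1/mu, sigma^2/mu^3, sigma/sqrt(mu))."""
    return params.mean, params.variance, params.cv


def shifted_wald_pdf(t, params: CheckpointParams, tau: float):
    """Wald density translated right by ``tau`` hours: f(t - tau); 0 for t <= tau.

    This is the closed form that a convolution with a point mass at ``tau``
    produces, and the model used to fit a constant offset between a
    checkpoint's passage-time law and phase-resolved duration data.
    """
    if not (np.isfinite(tau) and tau >= 0):
        raise ValueError(f"tau must be finite and >= 0, got {tau!r}")
    return wald_pdf(np.asarray(t, dtype=float) - tau, params)


def _invgauss_frozen(params: CheckpointParams):
    # Wald(mu, sigma) == IG(mean=1/mu, shape lambda=1/sigma^2); scipy's
    # invgauss(mu_s, scale=s) is IG(mean=mu_s*s, lambda=s).
    lam = 1.0 / params.sigma**2
    return stats.invgauss(params.sigma**2 / params.mu, scale=lam)


def wald_sample(
    params: CheckpointParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. passage times, in hours.

    Uses the exact inverse-Gaussian transformation sampler (via the
    mean ``1/mu``, shape ``lambda = 1/sigma**2`` re-parameterization), so
    draws follow the Wald law without any time-stepping error.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _invgauss_frozen(params).rvs(size=n, random_state=rng)


def wald_cdf(t, params: CheckpointParams):
    """Cumulative distribution of the Wald passage-time law; 0 for t <= 0."""
    t = _check_times(t)
    return _invgauss_frozen(params).cdf(t)


def _emg_frozen(model: EMGModel):
    # scipy's exponnorm(K, loc, scale) is N(loc, scale^2) + Exp(rate=1/(K*scale)).
    k = 1.0 / (model.rate * model.gauss_sd)
    return stats.exponnorm(k, loc=model.gauss_mean, scale=model.gauss_sd)


def emg_logpdf(t, model: EMGModel):
    """Log EMG density, defined for all real t."""
    t = _check_times(t)
    return _emg_frozen(model).logpdf(t)


def emg_pdf(t, model: EMGModel):
    """Exponentially-modified Gaussian density (Gaussian transit + exponential dwell)."""
    t = _check_times(t)
    return _emg_frozen(model).pdf(t)
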