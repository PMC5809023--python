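"""Bootstrap uncertainty quantification and two-sample hypothesis tests.

Parameter variability: the IMT vector is resampled with replacement B times
(each resample the size of the original data), the model is refit on each
resample, and percentile intervals are read off the ensemble of fitted
parameter vectors.

Two-sample test: to test whether a model parameter differs between two
conditions, the two IMT vectors are pooled; each of B replicates draws two
with-replacement resamples from the pool (sized like the original samples),
refits both, and records the parameter difference delta'.  The p-value is
the proportion of replicates whose delta' is at least as extreme as the
observed difference delta_hat (one-sided toward the observed sign; ties
count as extreme: the step function is 1 at 0).

Fitted checkpoint blocks are compared in canonical order (descending CV, so
the H phase is always first); replicate fits are warm-started at the
original optimum plus a few fresh method-of-moments starts.  Non-converged
replicates are dropped and counted — p-value denominators use the retained
replicates only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .inference import (
    FitResult,
    GridSettings,
    OptimizerSettings,
    child_seed,
    fit_mle,
)

__all__ = [
    "BootstrapEnsemble",
    "TwoSampleResult",
    "bootstrap_ci",
    "two_sample_test",
    "bootstrap_p_value",
    "param_names",
]

#: replicate fits reuse the original optimum as a warm start plus this many
#: fresh random starts (full multi-start on every replicate would be wasteful)
REPLICATE_EXTRA_STARTS = 5

#: more than this fraction of failed replicate fits voids the ensemble
MAX_FAILURE_FRACTION = 0.2


def param_names(family: str, m: int) -> list[str]:
    """Canonical parameter labels: checkpoint blocks ordered by descending CV."""
    if family == "ddt":
        names = []
        for i in range(m):
            tag = "H" if i == 0 else ("L" if m == 2 else f"L{i}")
            names.extend([f"mu_{tag}", f"sigma_{tag}"])
        return names
    return ["rate", "gauss_mean", "gauss_sd"]


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Fitted parameter vectors across bootstrap replicates (retained rows only)."""

    family: str
    m: int
    B: int
    param_sets: np.ndarray  # (B - n_failed, k)
    n_failed: int
    seed: int

    def __post_init__(self) -> None:
        if self.param_sets.shape[0] != self.B - self.n_failed:
            raise ValueError("ensemble rows must equal B - n_failed")

    @property
    def names(self) -> list[str]:
        return param_names(self.family, self.m)

    def to_frame(self):
        """Ensemble as a pandas DataFrame, one replicate per row (for export)."""
        import pandas as pd

        return pd.DataFrame(self.param_sets, columns=self.names)


@dataclass(frozen=True)
class TwoSampleResult:
    """Per-parameter observed differences and bootstrap p-values.

    ``p_values`` are the one-sided-toward-the-observed-sign proportions the
    resampling scheme defines.  Because the tested tail is chosen by the sign
    of the observed difference, under the null these p-values are uniform on
    (0, 0.5) rather than (0, 1): a decision at level ``alpha`` should use
    :meth:`reject` (equivalently :attr:`p_two_sided`), which accounts for the
    sign selection and is calibrated.
    """

    names: tuple[str, ...]
    delta_hat: np.ndarray
    p_values: np.ndarray
    B: int
    n_failed: int
    degenerate: tuple[bool, ...]  # delta_hat == 0 exactly -> p = 1 by convention

    def __post_init__(self) -> None:
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def p_two_sided(self) -> np.ndarray:
        """Sign-agnostic p-values: double the observed-sign tail (capped at 1)."""
        return np.minimum(1.0, 2.0 * self.p_values)

    def reject(self, alpha: float = 0.05) -> np.ndarray:
        """Calibrated level-``alpha`` decision per parameter."""
        return self.p_two_sided < alpha


def bootstrap_p_value(deltas: np.ndarray, delta_hat: float) -> float:
    """One parameter's two-sample bootstrap p-value.

    For a positive observed difference, the proportion of replicate
    differences with ``delta' - delta_hat >= 0``; for a negative one, the
    proportion with ``delta_hat - delta' >= 0`` (the unit step is 1 at 0, so
    a replicate exactly matching the observed difference counts as extreme).
    An observed difference of exactly 0 falls between the two one-sided
    branches; p = 1 by convention.
    """
    deltas = np.asarray(deltas, dtype=float)
    if delta_hat > 0:
        return float(np.mean(deltas - delta_hat >= 0))
    if delta_hat < 0:
        return float(np.mean(delta_hat - deltas >= 0))
    return 1.0


def _replicate_fit(
    imts: np.ndarray,
    family: str,
    m: int,
    settings: GridSettings,
    seed: int,
    warm_theta: Sequence[float],
    replicate_optimizer: OptimizerSettings,
) -> FitResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return fit_mle(
            imts,
            family=family,
            m=m,
            settings=settings,
            seed=seed,
            optimizer=replicate_optimizer,
            warm_starts=[np.asarray(warm_theta, dtype=float)],
        )


def bootstrap_ci(
    imts,
    family: str = "ddt",
    m: int = 2,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    settings: GridSettings = GridSettings(),
    optimizer: OptimizerSettings = OptimizerSettings(),
    replicate_optimizer: OptimizerSettings = OptimizerSettings(
        n_starts=REPLICATE_EXTRA_STARTS, max_evals=800
    ),
    original_fit: Optional[FitResult] = None,
) -> tuple[BootstrapEnsemble, dict[str, tuple[float, float]]]:
    """Percentile bootstrap intervals for one candidate model's parameters.

    Each of the B replicates resamples the n observations with replacement,
    refits (warm-started at the original optimum), and contributes one
    parameter vector.  Returns the ensemble and ``{name: (lo, hi)}`` at the
    requested level.  Raises when more than 20% of replicate fits fail, or
    when B < 2 (no interval is defined); warns below B = 100.
    """
    imts = np.asarray(imts, dtype=float)
    if B < 2:
        raise ValueError(f"B must be >= 2 to define an interval, got {B}")
    if B < 100:
        warnings.warn(
            f"B={B} is small for percentile intervals; consider B >= 100",
            UserWarning,
            stacklevel=2,
        )
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")

    if original_fit is None:
        original_fit = fit_mle(
            imts, family=family, m=m, settings=settings,
            seed=child_seed(seed, 0), optimizer=optimizer,
        )
    n = imts.size
    rows = []
    n_failed = 0
    for b in range(B):
        rs = np.random.default_rng(child_seed(seed, 2 * b + 1))
        resample = imts[rs.integers(0, n, size=n)]
        fit = _replicate_fit(
            resample, family, m, settings, child_seed(seed, 2 * b + 2),
            original_fit.theta, replicate_optimizer,
        )
        if fit.converged and np.isfinite(fit.loglik):
            rows.append(fit.theta)
        else:
            n_failed += 1
    if n_failed > MAX_FAILURE_FRACTION * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicate fits failed; the ensemble "
            "is untrustworthy"
        )
    ensemble = BootstrapEnsemble(
        family=family, m=m, B=B, param_sets=np.array(rows),
        n_failed=n_failed, seed=seed,
    )
    alpha = 1.0 - level
    lo = np.percentile(ensemble.param_sets, 100 * alpha / 2, axis=0)
    hi = np.percentile(ensemble.param_sets, 100 * (1 - alpha / 2), axis=0)
    intervals = {
        name: (float(l), float(h))
        for name, l, h in zip(ensemble.names, lo, hi)
    }
    point = np.asarray(original_fit.theta)
    outside = [(p < l or p > h) for p, l, h in zip(point, lo, hi)]
    if any(outside):
        bad = [n_ for n_, o in zip(ensemble.names, outside) if o]
        warnings.warn(
            f"point estimate falls outside its percentile interval for "
            f"{bad}; the likelihood surface may be multimodal",
            UserWarning,
            stacklevel=2,
        )
    return ensemble, intervals


def two_sample_test(
    imts_a,
    imts_b,
    family: str = "ddt",
    m: int = 2,
    B: int = 1000,
    seed: int = 0,
    settings: GridSettings = GridSettings(),
    optimizer: OptimizerSettings = OptimizerSettings(),
    replicate_optimizer: OptimizerSettings = OptimizerSettings(
        n_starts=REPLICATE_EXTRA_STARTS, max_evals=800
    ),
) -> TwoSampleResult:
    """Pooled-resampling bootstrap test for parameter differences.

    Null hypothesis: both conditions share the same parameter values.  The
    pooled data is resampled into surrogate A- and B-sized samples B times;
    the p-value for each parameter is the fraction of replicate differences
    at least as extreme as the observed one (toward its sign; a replicate
    exactly equal to the observed difference counts).  An observed difference
    of exactly 0 gets p = 1 by convention and is flagged ``degenerate``.
    """
    a = np.asarray(imts_a, dtype=float)
    b = np.asarray(imts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both IMT vectors must be non-empty")

    fit_a = fit_mle(a, family=family, m=m, settings=settings,
                    seed=child_seed(seed, 0), optimizer=optimizer)
    fit_b = fit_mle(b, family=family, m=m, settings=settings,
                    seed=child_seed(seed, 1), optimizer=optimizer)
    delta_hat = np.asarray(fit_a.theta) - np.asarray(fit_b.theta)

    pool = np.concatenate([a, b])
    deltas = []
    n_failed = 0
    for rep in range(B):
        rs = np.random.default_rng(child_seed(seed, 3 * rep + 2))
        res_a = pool[rs.integers(0, pool.size, size=a.size)]
        res_b = pool[rs.integers(0, pool.size, size=b.size)]
        fa = _replicate_fit(res_a, family, m, settings,
                            child_seed(seed, 3 * rep + 3),
                            fit_a.theta, replicate_optimizer)
        fb = _replicate_fit(res_b, family, m, settings,
                            child_seed(seed, 3 * rep + 4),
                            fit_b.theta, replicate_optimizer)
        if (fa.converged and fb.converged
                and np.isfinite(fa.loglik) and np.isfinite(fb.loglik)):
            deltas.append(np.asarray(fa.theta) - np.asarray(fb.theta))
        else:
            n_failed += 1
    if not deltas:
        raise RuntimeError("every bootstrap replicate fit failed")
    deltas = np.array(deltas)
    retained = deltas.shape[0]

    k = delta_hat.size
    p = np.empty(k)
    degenerate = []
    for j in range(k):
        p[j] = bootstrap_p_value(deltas[:, j], float(delta_hat[j]))
        degenerate.append(delta_hat[j] == 0.0)
    if any(degenerate):
        warnings.warn(
            "observed parameter difference exactly 0 for some parameter(s); "
            "p = 1 assigned by convention",
            UserWarning,
            stacklevel=2,
        )
    return TwoSampleResult(
        names=tuple(param_names(family, m)),
        delta_hat=delta_hat,
        p_values=p,
        B=retained,
        n_failed=n_failed,
        degenerate=tuple(degenerate),
    )
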