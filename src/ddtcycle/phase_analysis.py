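"""Biological interpretation of fitted checkpoint models.

A fitted multi-checkpoint model is labeled by variability: the checkpoint
with the largest coefficient of variation (CV = sigma/sqrt(mu)) is the "H"
(highly variable) phase, the rest "L" (low variability; L1, L2, ... in
descending CV for three or more checkpoints).  Because convolution commutes,
this labeling — not the fit — is what orders the checkpoints.

To place the H phase within the cell cycle, its passage-time density is
compared with phase-resolved duration data (G1 vs combined S-G2-M, from a
Fucci-type reporter).  G1 durations are typically described best by the H
density translated right by a constant offset tau (a nearly-fixed early
portion of G1), estimated by maximum likelihood over the translation; the L
density translated left by the same tau is then compared to the S-G2-M
durations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .distributions import (
    CheckpointParams,
    DDTModel,
    shifted_wald_pdf,
    wald_cdf,
    wald_logpdf,
)
from .inference import FitResult

__all__ = [
    "PhaseInfo",
    "PhaseLabeling",
    "ShiftFit",
    "PhaseComparison",
    "rank_phases",
    "fit_shift",
    "compare_phases",
]


@dataclass(frozen=True)
class PhaseInfo:
    label: str
    params: CheckpointParams
    mean: float
    sd: float
    cv: float


@dataclass(frozen=True)
class PhaseLabeling:
    """Checkpoints of a fitted DDT model, ordered by descending CV."""

    phases: tuple[PhaseInfo, ...]

    @property
    def h(self) -> PhaseInfo:
        return self.phases[0]

    @property
    def l(self) -> tuple[PhaseInfo, ...]:
        return self.phases[1:]


@dataclass(frozen=True)
class ShiftFit:
    """Maximum-likelihood constant offset between a Wald law and duration data."""

    tau_hat: float
    loglik_at_tau: float
    grid_taus: np.ndarray
    grid_logliks: np.ndarray


@dataclass(frozen=True)
class PhaseComparison:
    """How a DDT2 fit's H/L densities line up with G1 / S-G2-M durations.

    KS statistics are sup-distances between the empirical duration
    distributions and the (optionally tau-translated) model CDFs; smaller is
    closer.  Moment rows give (data mean, model mean, data sd, model sd).
    """

    tau_hat: float
    ks_h_g1: float
    ks_h_g1_shifted: float
    ks_l_sgm: float
    ks_l_sgm_shifted: float
    moments: dict[str, tuple[float, float, float, float]]


def rank_phases(fit: FitResult) -> PhaseLabeling:
    """Label a DDT fit's checkpoints by variability (H = largest CV).

    Exact CV ties order by the larger mean first.  Uses moments only, so the
    labeling is invariant to how the fitted blocks were stored.
    """
    if fit.family != "ddt":
        raise ValueError(
            "phase ranking needs per-checkpoint structure; the EMG model "
            "has none"
        )
    model = fit.params
    assert isinstance(model, DDTModel)
    order = sorted(
        range(model.m),
        key=lambda i: (-model.checkpoints[i].cv, -model.checkpoints[i].mean),
    )
    m = model.m
    labels = ["H"] + (["L"] if m == 2 else [f"L{i}" for i in range(1, m)])
    phases = tuple(
        PhaseInfo(
            label=labels[rank],
            params=model.checkpoints[i],
            mean=model.checkpoints[i].mean,
            sd=model.checkpoints[i].std,
            cv=model.checkpoints[i].cv,
        )
        for rank, i in enumerate(order)
    )
    return PhaseLabeling(phases=phases)


def fit_shift(
    h_params: CheckpointParams,
    g1_durations: Sequence[float],
    grid_step: float = 0.05,
) -> ShiftFit:
    """Maximum-likelihood translation of a Wald law onto duration data.

    Maximizes ``sum log f(t_i - tau; mu, sigma)`` over
    ``tau in [0, min(durations))`` by a coarse grid scan followed by bounded
    golden-section refinement around the best grid point.  The boundary
    ``tau = min(durations)`` is excluded (the smallest datum would have zero
    density there).
    """
    t = np.asarray(g1_durations, dtype=float)
    if t.size == 0:
        raise ValueError("empty duration vector")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("durations must be finite and strictly positive")
    upper = float(t.min())

    def negll(tau: float) -> float:
        ll = np.sum(wald_logpdf(t - tau, h_params))
        return -ll if np.isfinite(ll) else np.inf

    taus = np.arange(0.0, upper, grid_step)
    if taus.size == 0:
        taus = np.array([0.0])
    lls = np.array([-negll(tau) for tau in taus])
    best = int(np.argmax(lls))
    lo = max(0.0, taus[best] - grid_step)
    hi = min(upper - 1e-9, taus[best] + grid_step)
    res = optimize.minimize_scalar(
        negll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    tau_hat = float(res.x)
    ll_hat = -float(res.fun)
    if lls[best] > ll_hat:  # refinement should never lose to the scan
        tau_hat, ll_hat = float(taus[best]), float(lls[best])
    return ShiftFit(
        tau_hat=tau_hat,
        loglik_at_tau=ll_hat,
        grid_taus=taus,
        grid_logliks=lls,
    )


def _ks_stat(sample: np.ndarray, cdf) -> float:
    return float(stats.ks_1samp(sample, cdf).statistic)


def compare_phases(
    fit: FitResult,
    g1_durations: Sequence[float],
    sgm_durations: Sequence[float],
) -> PhaseComparison:
    """Pair a DDT2 fit's phases with phase-resolved duration data.

    The H density is compared to G1 durations before and after translating
    it right by the fitted offset tau; the L density is compared to S-G2-M
    durations before and after translating it *left* by the same tau (the
    constant early-G1 portion belongs to the L checkpoint process, so
    removing it should align L with S-G2-M).  The two duration vectors need
    not be paired or equal-length.
    """
    if fit.family != "ddt" or fit.m != 2:
        raise ValueError("phase comparison is defined for two-checkpoint fits")
    g1 = np.asarray(g1_durations, dtype=float)
    sgm = np.asarray(sgm_durations, dtype=float)
    if g1.size == 0 or sgm.size == 0:
        raise ValueError("both duration vectors must be non-empty")

    labeling = rank_phases(fit)
    h, l = labeling.h.params, labeling.l[0].params
    shift = fit_shift(h, g1)
    tau = shift.tau_hat

    ks_h = _ks_stat(g1, lambda x: wald_cdf(x, h))
    ks_h_shift = _ks_stat(g1, lambda x: wald_cdf(np.asarray(x) - tau, h))
    ks_l = _ks_stat(sgm, lambda x: wald_cdf(x, l))
    ks_l_shift = _ks_stat(sgm, lambda x: wald_cdf(np.asarray(x) + tau, l))

    moments = {
        "H_vs_G1": (
            float(g1.mean()), labeling.h.mean + tau,
            float(g1.std(ddof=1)) if g1.size > 1 else 0.0, labeling.h.sd,
        ),
        "L_vs_SGM": (
            float(sgm.mean()), labeling.l[0].mean - tau,
            float(sgm.std(ddof=1)) if sgm.size > 1 else 0.0, labeling.l[0].sd,
        ),
    }
    return PhaseComparison(
        tau_hat=tau,
        ks_h_g1=ks_h,
        ks_h_g1_shifted=ks_h_shift,
        ks_l_sgm=ks_l,
        ks_l_sgm_shifted=ks_l_shift,
        moments=moments,
    )
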