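"""Model comparison by AICc and AICp evidence ratios.

AICc = -2 log L + 2k + 2k(k+1)/(n - k - 1): the usual Akaike criterion plus
a finite-sample correction that vanishes as n grows.  The preferred candidate
minimizes AICc.  The evidence ratio AICp_i = exp((min_j AICc_j - AICc_i)/2)
rescales the criterion so the preferred model scores exactly 1; a pairwise
ratio AICp_i / AICp_j << 1 indicates model j is clearly superior, while a
ratio > 0.1 is conventionally read as "model i cannot be entirely ruled out".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import FitResult

__all__ = ["aicc", "aicp", "select", "SelectionTable", "SelectionRow"]


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with finite-sample correction; requires n > k + 1."""
    if not np.isfinite(loglik):
        raise ValueError(f"loglik must be finite, got {loglik!r}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if n <= k + 1:
        raise ValueError(
            f"need n > k + 1 for the finite-sample correction, got n={n}, k={k}"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicp(aicc_values) -> np.ndarray:
    """Evidence ratios exp((min AICc - AICc_i)/2); the minimum maps to exactly 1."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be finite")
    out = np.exp((a.min() - a) / 2.0)
    out[np.argmin(a)] = 1.0  # exact by definition, immune to round-off
    return out


@dataclass(frozen=True)
class SelectionRow:
    label: str
    family: str
    m: int
    loglik: float
    k: int
    n: int
    aicc: float
    aicp: float


@dataclass(frozen=True)
class SelectionTable:
    """Ranked candidate models; ``preferred`` indexes the minimum-AICc row."""

    rows: tuple[SelectionRow, ...]
    preferred: int

    @property
    def preferred_row(self) -> SelectionRow:
        return self.rows[self.preferred]

    def pairwise_ratio(self, i: int, j: int) -> float:
        """AICp_i / AICp_j — << 1 means model j is clearly superior."""
        return self.rows[i].aicp / self.rows[j].aicp

    def cannot_be_ruled_out(self, i: int, threshold: float = 0.1) -> bool:
        """Reporting convention: evidence ratio vs the preferred model > threshold."""
        return self.pairwise_ratio(i, self.preferred) > threshold


def select(fits: Sequence[FitResult]) -> SelectionTable:
    """Build the AICc/AICp comparison table from converged fits.

    Non-converged fits are excluded with a warning rather than assigned a
    sentinel criterion value.  Exact AICc ties break toward the model with
    fewer parameters, then toward earlier list position.
    """
    fits = list(fits)
    usable = [f for f in fits if f.converged and np.isfinite(f.loglik)]
    dropped = len(fits) - len(usable)
    if dropped:
        warnings.warn(
            f"excluding {dropped} non-converged fit(s) from model selection",
            UserWarning,
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no converged fits to select among")
    if len(usable) == 1:
        warnings.warn(
            "only one converged fit: model comparison is vacuous",
            UserWarning,
            stacklevel=2,
        )
    aicc_vals = np.array([aicc(f.loglik, f.k, f.n) for f in usable])
    aicp_vals = aicp(aicc_vals)
    # argmin with parsimony tie-break: (aicc, k, position)
    order = sorted(
        range(len(usable)), key=lambda i: (aicc_vals[i], usable[i].k, i)
    )
    preferred = order[0]
    aicp_vals = np.exp((aicc_vals[preferred] - aicc_vals) / 2.0)
    aicp_vals[preferred] = 1.0
    rows = tuple(
        SelectionRow(
            label=f.label,
            family=f.family,
            m=f.m,
            loglik=f.loglik,
            k=f.k,
            n=f.n,
            aicc=float(aicc_vals[i]),
            aicp=float(min(aicp_vals[i], 1.0)),
        )
        for i, f in enumerate(usable)
    )
    return SelectionTable(rows=rows, preferred=preferred)
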