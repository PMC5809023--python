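"""Forward simulation of checkpoint passage and synthetic lineage experiments.

Each checkpoint's latent state follows the Ito SDE
``dy = mu dt + sigma dW``, ``y(0) = 0``; passage occurs at the first time
``y >= 1``.  The Euler-Maruyama scheme integrates this directly (useful for
validating the closed-form Wald law); the exact sampler draws passage times
without time-stepping.  :func:`generate_dataset` wraps the sampler in a
synthetic time-lapse experiment: asynchronous births, imaging-frame
quantization, rare death, an end-of-experiment horizon, density-dependent
crowding that lengthens late-born cells' cycles, and an optional Fucci-style
G1 / S-G2-M phase split in which G1 = (constant offset) + (first checkpoint
passage time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distributions import CheckpointParams, DDTModel, wald_sample

__all__ = [
    "SDEPath",
    "SyntheticConfig",
    "simulate_em_passage",
    "simulate_imt",
    "generate_dataset",
]


@dataclass(frozen=True)
class SDEPath:
    """One Euler-Maruyama trajectory, terminated at its first threshold crossing."""

    times: np.ndarray
    y: np.ndarray
    passage_time: float


def simulate_em_passage(
    params: CheckpointParams,
    dt: float,
    seed: int | np.random.Generator,
    max_horizon: Optional[float] = None,
) -> SDEPath:
    """Integrate one checkpoint's SDE to first passage of the threshold 1.

    Fixed-step Euler-Maruyama: ``y_{k+1} = y_k + mu*dt + sigma*sqrt(dt)*Z_k``.
    The crossing is detected at the first grid point with ``y >= 1`` (no
    sub-step interpolation), giving a positive passage-time bias of order dt.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if max_horizon is None:
        max_horizon = 100.0 / params.mu
    max_steps = int(np.ceil(max_horizon / dt))
    sqrt_dt = np.sqrt(dt)

    # grow in blocks so typical paths don't pay for the worst case
    block = max(256, int(4.0 / (params.mu * dt)))
    ys = [0.0]
    y = 0.0
    n = 0
    while n < max_steps:
        k = min(block, max_steps - n)
        z = rng.standard_normal(k)
        incr = params.mu * dt + params.sigma * sqrt_dt * z
        seg = y + np.cumsum(incr)
        hit = np.nonzero(seg >= 1.0)[0]
        if hit.size:
            stop = hit[0] + 1
            ys.extend(seg[:stop].tolist())
            n += stop
            y_arr = np.array(ys)
            t_arr = dt * np.arange(y_arr.size)
            return SDEPath(t_arr, y_arr, float(t_arr[-1]))
        ys.extend(seg.tolist())
        y = seg[-1]
        n += k
    raise RuntimeError(
        f"no threshold crossing within horizon {max_horizon:.3g} h "
        f"(mu={params.mu}, sigma={params.sigma}, dt={dt}); the drift may be "
        "too weak for this horizon"
    )


def _em_passage_times(
    params: CheckpointParams, n: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized EM passage times for n independent paths (no path storage)."""
    sqrt_dt = np.sqrt(dt)
    max_steps = int(np.ceil(100.0 / (params.mu * dt)))
    y = np.zeros(n)
    passage = np.full(n, np.nan)
    active = np.arange(n)
    step_idx = 0
    block = max(64, int(1.0 / (params.mu * dt) / 8))
    while active.size and step_idx < max_steps:
        k = min(block, max_steps - step_idx)
        z = rng.standard_normal((active.size, k))
        seg = y[active, None] + np.cumsum(params.mu * dt + params.sigma * sqrt_dt * z, axis=1)
        crossed = seg >= 1.0
        any_cross = crossed.any(axis=1)
        first = np.argmax(crossed, axis=1)
        done = active[any_cross]
        passage[done] = dt * (step_idx + first[any_cross] + 1)
        y[active] = seg[:, -1]
        active = active[~any_cross]
        step_idx += k
    if active.size:
        raise RuntimeError(
            f"{active.size} of {n} paths failed to cross within the horizon"
        )
    return passage


def simulate_imt(
    model: DDTModel,
    n: int,
    seed: int | np.random.Generator,
    method: str = "exact",
    dt: float = 0.001,
) -> np.ndarray:
    """Draw n intermitotic times: sums of the m independent passage times.

    ``method="exact"`` uses the transformation sampler for each Wald
    component; ``method="em"`` integrates the SDE per checkpoint with step
    ``dt`` (slower, carries the O(dt) crossing bias).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if method == "exact":
        return _passage_matrix(model, n, rng).sum(axis=1)
    if method == "em":
        cols = [_em_passage_times(cp, n, dt, rng) for cp in model.checkpoints]
        return np.sum(cols, axis=0)
    raise ValueError(f"unknown method {method!r}; use 'exact' or 'em'")


def _passage_matrix(model: DDTModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """n x m matrix of exact passage times, column i for checkpoint i."""
    return np.column_stack([wald_sample(cp, n, rng) for cp in model.checkpoints])


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a synthetic asynchronous time-lapse experiment.

    Defaults emulate a typical imaging run: cells born over the first day of
    a ~4-day movie, frames every 6 minutes (0.1 h), rare death, and crowding
    that begins to lengthen cycles for cells born in the second half of the
    birth window.
    """

    model: DDTModel
    n_cells: int = 500
    birth_window: float = 24.0
    frame_interval: Optional[float] = 0.1
    death_rate: float = 0.0
    eoe_time: float = 96.0
    crowding_onset: Optional[float] = None
    crowding_slope: float = 0.0
    g1_offset: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 (or None for continuous time)")
        for name in ("birth_window", "death_rate", "eoe_time", "crowding_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.g1_offset is not None and self.g1_offset < 0:
            raise ValueError("g1_offset must be >= 0")
        if self.eoe_time < self.birth_window:
            warnings.warn(
                "eoe_time precedes the end of the birth window; many cells "
                "will be born after the observation horizon",
                UserWarning,
                stacklevel=2,
            )


def _quantize_up(t: np.ndarray, frame: Optional[float]) -> np.ndarray:
    """Detection happens at the first frame after the event (round up)."""
    if frame is None:
        return t
    return np.ceil(np.round(t / frame, 9)) * frame


def generate_dataset(config: SyntheticConfig) -> "IMTDataset":
    """Simulate a lineage dataset of per-cell birth/division/death records.

    Birth times are uniform on [0, birth_window].  Each cell's true IMT is the
    sum of its checkpoint passage times, inflated by
    ``crowding_slope * max(0, birth - crowding_onset)`` when crowding is
    configured.  An independent exponential death clock (rate ``death_rate``)
    may preempt division; division (or death) is recorded only if it occurs
    before ``eoe_time``; recorded times land on the imaging-frame grid
    (detection at the first frame after the event).  With ``g1_offset`` set,
    each cell carries a Fucci-onset time
    ``birth + g1_offset + first-checkpoint passage``, so G1 is a constant
    offset plus the first checkpoint and S-G2-M is the rest of the cycle.

    The IMT draw consumes the random stream exactly as
    ``simulate_imt(model, n_cells, seed)`` does, so an undisturbed
    configuration (no death, no crowding, no quantization, distant horizon)
    reproduces those IMTs bit-for-bit.
    """
    from .censoring import CellRecord, IMTDataset

    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    passages = _passage_matrix(config.model, n, rng)
    imt_true = passages.sum(axis=1)

    births = rng.uniform(0.0, config.birth_window, size=n)
    if config.crowding_onset is not None and config.crowding_slope > 0:
        imt_true = imt_true + config.crowding_slope * np.maximum(
            0.0, births - config.crowding_onset
        )

    division = births + imt_true
    if config.death_rate > 0:
        death = births + rng.exponential(1.0 / config.death_rate, size=n)
    else:
        death = np.full(n, np.inf)

    frame = config.frame_interval
    q_birth = _quantize_up(births, frame)
    q_division = _quantize_up(division, frame)
    q_death = _quantize_up(death, frame) if config.death_rate > 0 else death
    if frame is not None:
        # an event landing in the birth frame is first detectable a frame later
        q_division = np.maximum(q_division, q_birth + frame)
        q_death = np.where(np.isfinite(q_death), np.maximum(q_death, q_birth + frame), q_death)
    if config.g1_offset is not None:
        fucci = births + config.g1_offset + passages[:, 0]
        q_fucci = _quantize_up(fucci, frame)

    records = []
    for i in range(n):
        b = float(q_birth[i])
        died = q_death[i] < q_division[i]
        div_t: Optional[float] = None
        death_t: Optional[float] = None
        if died and q_death[i] <= config.eoe_time:
            death_t = float(q_death[i])
            end = death_t
        elif not died and q_division[i] <= config.eoe_time:
            div_t = float(q_division[i])
            end = div_t
        else:  # still alive and unsplit at the end of the experiment
            end = config.eoe_time
        onset: Optional[float] = None
        if config.g1_offset is not None:
            cand = float(q_fucci[i])
            visible = cand <= config.eoe_time and (death_t is None or cand < death_t)
            # frame quantization can collide the onset with birth or division;
            # such onsets are unresolvable and recorded as absent
            resolvable = cand > b and (div_t is None or cand < div_t)
            if visible and resolvable:
                onset = cand
        records.append(
            CellRecord(
                cell_id=f"cell_{i:05d}",
                birth_time=b,
                division_time=div_t,
                death_time=death_t,
                fucci_onset=onset,
                observed_end=float(end),
            )
        )
    return IMTDataset(records)
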