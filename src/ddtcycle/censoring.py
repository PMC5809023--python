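"""Per-cell lineage records and the four-stage censoring pipeline.

Raw time-lapse tracking yields one record per cell: birth (the mother's
mitosis), division or death if observed, an optional Fucci-onset time marking
the G1 -> S transition, and the end of observation.  Before fitting, IMT data
is censored to remove known biases, in order:

1. death       — cells that died are excluded outright (death is rare);
2. end of experiment (EoE) — only cells born early enough that > 96% of
   cells born by then divided before the horizon are kept, so the retained
   set is an essentially complete sample of dividing cells;
3. crowding    — if birth time and IMT are rank-correlated (Spearman,
   p <= 0.01), late-born cells are dropped back to the latest birth time at
   which the correlation is not significant;
4. drug delay  — optionally, cells born < t_min hours after drug addition
   are excluded (transient growth before the drug effect stabilizes).

Every stage reports its counts and cutoffs so a run is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CellRecord",
    "IMTDataset",
    "CensorConfig",
    "CensorReport",
    "censor_death",
    "censor_eoe",
    "censor_crowding",
    "censor_drug_delay",
    "censor_pipeline",
]


@dataclass(frozen=True)
class CellRecord:
    """One tracked cell; all times in hours from the start of the experiment."""

    cell_id: str
    birth_time: float
    division_time: Optional[float] = None
    death_time: Optional[float] = None
    fucci_onset: Optional[float] = None
    observed_end: float = np.inf

    def __post_init__(self) -> None:
        if not (np.isfinite(self.birth_time) and self.birth_time >= 0):
            raise ValueError(
                f"{self.cell_id}: birth_time must be finite and >= 0, "
                f"got {self.birth_time!r}"
            )
        if self.division_time is not None and self.death_time is not None:
            raise ValueError(
                f"{self.cell_id}: a cell cannot both divide and die"
            )
        if self.division_time is not None and self.division_time <= self.birth_time:
            raise ValueError(
                f"{self.cell_id}: division_time {self.division_time} must "
                f"exceed birth_time {self.birth_time}"
            )
        if self.death_time is not None and self.death_time <= self.birth_time:
            raise ValueError(
                f"{self.cell_id}: death_time {self.death_time} must exceed "
                f"birth_time {self.birth_time}"
            )
        if (
            self.fucci_onset is not None
            and self.division_time is not None
            and not (self.birth_time < self.fucci_onset < self.division_time)
        ):
            raise ValueError(
                f"{self.cell_id}: fucci_onset must lie strictly between "
                "birth and division"
            )

    @property
    def divided(self) -> bool:
        return self.division_time is not None

    @property
    def died(self) -> bool:
        return self.death_time is not None

    @property
    def imt(self) -> Optional[float]:
        """Intermitotic time (hours), when the cell's division was observed."""
        if self.division_time is None:
            return None
        return self.division_time - self.birth_time

    @property
    def g1_duration(self) -> Optional[float]:
        if self.fucci_onset is None:
            return None
        return self.fucci_onset - self.birth_time

    @property
    def sgm_duration(self) -> Optional[float]:
        """Combined S-G2-M duration, when both phase marks exist."""
        if self.fucci_onset is None or self.division_time is None:
            return None
        return self.division_time - self.fucci_onset


@dataclass(frozen=True)
class IMTDataset:
    """An ordered collection of cell records with derived IMT views."""

    records: tuple[CellRecord, ...]

    def __init__(self, records: Sequence[CellRecord]) -> None:
        object.__setattr__(self, "records", tuple(records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def imts(self) -> np.ndarray:
        """IMTs (hours) of the cells whose division was observed."""
        return np.array([r.imt for r in self.records if r.divided])

    @property
    def births(self) -> np.ndarray:
        return np.array([r.birth_time for r in self.records])

    @property
    def g1_durations(self) -> np.ndarray:
        return np.array(
            [r.g1_duration for r in self.records if r.g1_duration is not None]
        )

    @property
    def sgm_durations(self) -> np.ndarray:
        return np.array(
            [r.sgm_duration for r in self.records if r.sgm_duration is not None]
        )

    def dividing(self) -> "IMTDataset":
        return IMTDataset([r for r in self.records if r.divided])


@dataclass(frozen=True)
class CensorConfig:
    """Thresholds of the censoring pipeline."""

    eoe_frac: float = 0.96
    crowding_alpha: float = 0.01
    drug_delay_min: Optional[float] = None
    crowding_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eoe_frac < 1:
            raise ValueError(f"eoe_frac must be in (0, 1), got {self.eoe_frac}")
        if not 0 < self.crowding_alpha < 1:
            raise ValueError(
                f"crowding_alpha must be in (0, 1), got {self.crowding_alpha}"
            )
        if self.drug_delay_min is not None and self.drug_delay_min < 0:
            raise ValueError("drug_delay_min must be >= 0")


@dataclass(frozen=True)
class CensorReport:
    """Counts and cutoffs of every censoring stage; counts must balance."""

    n_input: int
    removed_death: int
    removed_eoe: int
    eoe_birth_cutoff: float
    removed_crowding: int
    crowding_birth_cutoff: Optional[float]
    removed_drug_delay: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.removed_death
            + self.removed_eoe
            + self.removed_crowding
            + self.removed_drug_delay
        )
        if min(
            self.n_input,
            self.removed_death,
            self.removed_eoe,
            self.removed_crowding,
            self.removed_drug_delay,
            self.n_retained,
        ) < 0:
            raise ValueError("censor counts must be non-negative")
        if self.n_input - removed != self.n_retained:
            raise ValueError(
                f"censor counts do not balance: {self.n_input} - {removed} "
                f"!= {self.n_retained}"
            )


def censor_death(dataset: IMTDataset) -> tuple[IMTDataset, int]:
    """Drop cells that died; returns the retained set and the removal count."""
    kept = [r for r in dataset if not r.died]
    return IMTDataset(kept), len(dataset) - len(kept)


def censor_eoe(
    dataset: IMTDataset, frac: float = 0.96
) -> tuple[IMTDataset, float, int]:
    """End-of-experiment censoring.

    Finds the latest birth time B such that, among cells born at or before B,
    the fraction whose division was observed strictly exceeds ``frac``; cells
    born after B are removed, as are any remaining non-dividers, leaving an
    essentially complete sample of dividing cells.  Raises when no birth time
    qualifies (the experiment is too truncated to de-bias).
    """
    if len(dataset) == 0:
        raise ValueError("cannot EoE-censor an empty dataset")
    recs = sorted(dataset, key=lambda r: r.birth_time)
    births = np.array([r.birth_time for r in recs])
    divided = np.array([r.divided for r in recs], dtype=float)
    frac_by_prefix = np.cumsum(divided) / np.arange(1, len(recs) + 1)
    # a valid cutoff must cover every cell born at that time (ties included)
    is_last_of_birth = np.r_[births[1:] != births[:-1], True]
    ok = (frac_by_prefix > frac) & is_last_of_birth
    if not ok.any():
        raise ValueError(
            f"no birth time has > {frac:.0%} of earlier-born cells dividing "
            "before the end of the experiment; the observation window is too "
            "short for end-of-experiment censoring"
        )
    cutoff_idx = int(np.nonzero(ok)[0][-1])
    cutoff = float(births[cutoff_idx])
    kept = [r for r in recs if r.birth_time <= cutoff and r.divided]
    return IMTDataset(kept), cutoff, len(dataset) - len(kept)


def _spearman_pvalue(
    births: np.ndarray,
    imts: np.ndarray,
    rng: np.random.Generator,
    n_perm: int = 10_000,
) -> float:
    """Two-sided Spearman p: large-sample approximation for n > 30, seeded
    permutation test otherwise (the t-approximation is unreliable at small n)."""
    n = births.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input handled via NaN below
        rho, p_asym = stats.spearmanr(births, imts)
    if np.isnan(rho):
        raise FloatingPointError("Spearman correlation undefined (constant ranks)")
    if n > 30:
        return float(p_asym)
    # Spearman rho is the Pearson correlation of the ranks; permuting one
    # rank vector gives the exact null, vectorized across all permutations.
    rx = stats.rankdata(births)
    ry = stats.rankdata(imts)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perm = np.array([rng.permutation(ry) for _ in range(n_perm)])
    perm_rho = perm @ rx / n
    more_extreme = int(np.sum(np.abs(perm_rho) >= abs(rho) - 1e-12))
    return (1 + more_extreme) / (1 + n_perm)


def censor_crowding(
    dataset: IMTDataset, alpha: float = 0.01, seed: int = 0
) -> tuple[IMTDataset, Optional[float], int]:
    """Crowding (confluence) censoring via birth-time/IMT rank correlation.

    Tests Spearman correlation between birth time and IMT over the dividing
    cells.  If the full set is not significant at ``alpha``, nothing is
    removed.  Otherwise birth-ordered prefixes are scanned from latest to
    earliest; the cutoff is the latest birth time whose prefix is *not*
    significant, and cells born after it are removed.  Fewer than 5 dividing
    cells, or degenerate (constant) IMTs, make the test unstable: the stage
    warns and removes nothing.
    """
    rng = np.random.default_rng(seed)
    recs = sorted(dataset, key=lambda r: r.birth_time)
    div = [r for r in recs if r.divided]
    if len(div) < 5:
        warnings.warn(
            "fewer than 5 dividing cells: crowding correlation is unstable; "
            "skipping this censoring stage",
            UserWarning,
            stacklevel=2,
        )
        return dataset, None, 0
    births = np.array([r.birth_time for r in div])
    imts = np.array([r.imt for r in div])
    try:
        p_full = _spearman_pvalue(births, imts, rng)
    except FloatingPointError:
        warnings.warn(
            "birth/IMT rank correlation undefined (constant values); "
            "skipping crowding censoring",
            UserWarning,
            stacklevel=2,
        )
        return dataset, None, 0
    if p_full > alpha:
        return dataset, None, 0

    cutoff: Optional[float] = None
    for k in range(len(div) - 1, 4, -1):
        if k < len(div) and births[k - 1] == births[k]:
            continue  # a cutoff must separate distinct birth times
        p_k = _spearman_pvalue(births[:k], imts[:k], rng)
        if p_k > alpha:
            cutoff = float(births[k - 1])
            break
    if cutoff is None:
        cutoff = float(births[4])
        warnings.warn(
            "birth/IMT correlation stays significant down to the minimal "
            "prefix; truncating at the 5th-earliest dividing birth",
            UserWarning,
            stacklevel=2,
        )
    kept = [r for r in recs if r.birth_time <= cutoff]
    return IMTDataset(kept), cutoff, len(dataset) - len(kept)


def censor_drug_delay(
    dataset: IMTDataset, t_min: float = 10.0
) -> tuple[IMTDataset, int]:
    """Drop cells born strictly before ``t_min`` hours after drug addition."""
    if t_min < 0:
        raise ValueError(f"t_min must be >= 0, got {t_min}")
    kept = [r for r in dataset if r.birth_time >= t_min]
    if not kept:
        warnings.warn(
            "drug-delay censoring removed every record",
            UserWarning,
            stacklevel=2,
        )
    return IMTDataset(kept), len(dataset) - len(kept)


def censor_pipeline(
    dataset: IMTDataset, config: CensorConfig = CensorConfig()
) -> tuple[np.ndarray, CensorReport]:
    """Run death -> EoE -> crowding -> (optional) drug-delay censoring.

    Returns the analysis-ready IMT vector (division minus birth of every
    retained cell) and the full audit report.  Raises if nothing survives.
    """
    n_input = len(dataset)
    ds, n_death = censor_death(dataset)
    ds, eoe_cutoff, n_eoe = censor_eoe(ds, config.eoe_frac)
    ds, crowd_cutoff, n_crowd = censor_crowding(
        ds, config.crowding_alpha, config.crowding_seed
    )
    if config.drug_delay_min is not None:
        ds, n_drug = censor_drug_delay(ds, config.drug_delay_min)
    else:
        n_drug = 0
    report = CensorReport(
        n_input=n_input,
        removed_death=n_death,
        removed_eoe=n_eoe,
        eoe_birth_cutoff=eoe_cutoff,
        removed_crowding=n_crowd,
        crowding_birth_cutoff=crowd_cutoff,
        removed_drug_delay=n_drug,
        n_retained=len(ds),
    )
    if len(ds) == 0:
        raise ValueError("censoring removed every record; nothing to fit")
    return ds.imts, report
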