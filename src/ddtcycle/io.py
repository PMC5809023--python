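"""Lineage-table and results file formats.

Lineage tables are comma-delimited text with a header row and columns
``cell_id, birth_time_h, division_time_h, death_time_h, observed_end_h`` and
optionally ``fucci_onset_h``; all times are hours with decimal fractions, and
an empty field means "absent" (never a sentinel number).  Results files are
YAML with every number needed to reproduce a run: the master seed, fitted
parameters, log-likelihoods, the AICc/AICp table, and the substitution and
censoring reports.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .censoring import CellRecord, CensorReport, IMTDataset
from .inference import FitResult
from .selection import SelectionTable

__all__ = [
    "IMTDataset",
    "read_lineage",
    "write_lineage",
    "read_imts",
    "write_imts",
    "write_results",
    "read_results",
    "LineageFormatError",
]

REQUIRED_COLUMNS = (
    "cell_id",
    "birth_time_h",
    "division_time_h",
    "death_time_h",
    "observed_end_h",
)
OPTIONAL_COLUMNS = ("fucci_onset_h",)


class LineageFormatError(ValueError):
    """A lineage table violates the format contract."""


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_lineage(path) -> IMTDataset:
    """Parse and validate a lineage table.

    Missing required columns raise immediately; row-level violations (e.g.
    division before birth) are collected and reported together with their
    1-based file line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LineageFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(REQUIRED_COLUMNS)}"
        )
    has_fucci = "fucci_onset_h" in df.columns
    records: list[CellRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            records.append(
                CellRecord(
                    cell_id=str(row["cell_id"]),
                    birth_time=float(row["birth_time_h"]),
                    division_time=_opt(row["division_time_h"]),
                    death_time=_opt(row["death_time_h"]),
                    fucci_onset=_opt(row["fucci_onset_h"]) if has_fucci else None,
                    observed_end=float(row["observed_end_h"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise LineageFormatError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return IMTDataset(records)


def write_lineage(dataset: IMTDataset, path) -> None:
    """Write a lineage table; absent values become empty fields."""
    rows = []
    any_fucci = any(r.fucci_onset is not None for r in dataset)
    for r in dataset:
        row = {
            "cell_id": r.cell_id,
            "birth_time_h": r.birth_time,
            "division_time_h": r.division_time,
            "death_time_h": r.death_time,
            "observed_end_h": r.observed_end,
        }
        if any_fucci:
            row["fucci_onset_h"] = r.fucci_onset
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_imts(path) -> np.ndarray:
    """Read an IMT vector: one decimal value (hours) per line."""
    vals = np.loadtxt(path, ndmin=1)
    return np.asarray(vals, dtype=float)


def write_imts(imts, path) -> None:
    np.savetxt(path, np.asarray(imts, dtype=float), fmt="%.6f")


def _fit_to_dict(fit: FitResult) -> dict:
    d = {
        "label": fit.label,
        "family": fit.family,
        "m": fit.m,
        "theta": [float(v) for v in fit.theta],
        "loglik": float(fit.loglik),
        "n": fit.n,
        "k": fit.k,
        "converged": bool(fit.converged),
        "n_starts": fit.n_starts,
        "seed": fit.seed,
    }
    if fit.grid_drift is not None:
        d["grid_drift_per_datum"] = float(fit.grid_drift)
    if fit.substitutions is not None:
        d["substitutions"] = {
            "substituted": list(fit.substitutions.substituted),
            "delta_locations": [float(v) for v in fit.substitutions.delta_locations],
            "tau_total": float(fit.substitutions.tau_total),
            "error_bound": float(fit.substitutions.error_bound),
            "defect": float(fit.substitutions.defect),
        }
    return d


def write_results(
    fits: Sequence[FitResult],
    selection: Optional[SelectionTable],
    censor_report: Optional[CensorReport],
    path,
    seed: int = 0,
    config: Optional[dict] = None,
) -> None:
    """Serialize a full run: config echo, seed, fits, selection, censoring."""
    doc: dict = {
        "seed": int(seed),
        "fits": [_fit_to_dict(f) for f in fits],
    }
    if config is not None:
        doc["config"] = config
    if selection is not None:
        doc["selection"] = {
            "preferred": selection.preferred,
            "preferred_label": selection.preferred_row.label,
            "rows": [
                {
                    "label": r.label,
                    "loglik": float(r.loglik),
                    "k": r.k,
                    "n": r.n,
                    "aicc": float(r.aicc),
                    "aicp": float(r.aicp),
                }
                for r in selection.rows
            ],
        }
    if censor_report is not None:
        doc["censoring"] = {
            "n_input": censor_report.n_input,
            "removed_death": censor_report.removed_death,
            "removed_eoe": censor_report.removed_eoe,
            "eoe_birth_cutoff": float(censor_report.eoe_birth_cutoff),
            "removed_crowding": censor_report.removed_crowding,
            "crowding_birth_cutoff": (
                None
                if censor_report.crowding_birth_cutoff is None
                else float(censor_report.crowding_birth_cutoff)
            ),
            "removed_drug_delay": censor_report.removed_drug_delay,
            "n_retained": censor_report.n_retained,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


def read_results(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
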