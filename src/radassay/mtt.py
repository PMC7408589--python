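"""MTT viability analysis.

Viability per dose is computed relative to the plate's blank and untreated
strips,

    viability(%) = (OD_treated - OD_blank) / (OD_untreated - OD_blank) * 100,

using the strip means for blank and untreated. Doses whose readout sits at
or below the assay's limit of quantification (default 20%) are flagged, not
truncated: the flag carries a small guard band (default 2 percentage points)
because a readout floored exactly at the LOQ plus blank/untreated strip
noise lands fractionally above the nominal threshold about half the time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError
from .stats import GroupSummary, combine_groups, standard_error

log = logging.getLogger(__name__)

__all__ = ["compute_viability", "dose_response_summary", "DEFAULT_LOQ_PCT", "LOQ_MARGIN_PCT"]

DEFAULT_LOQ_PCT = 20.0
LOQ_MARGIN_PCT = 2.0

OD_COLUMNS = ("well", "condition", "od562")
VIABILITY_COLUMNS = ("dose_gy", "viability_pct", "se_pct", "n_wells", "at_loq")


def _validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = set(OD_COLUMNS) - set(plate.columns)
    if missing:
        raise InputError(f"OD table missing columns: {sorted(missing)}")
    if not np.isfinite(plate["od562"]).all():
        raise InputError("od562 must be finite")
    for needed in ("blank", "untreated"):
        if not (plate["condition"] == needed).any():
            raise InputError(f"OD table needs >= 1 '{needed}' well")
    return plate


def _at_loq(summary: GroupSummary, loq_pct: float, margin_pct: float = LOQ_MARGIN_PCT) -> bool:
    return summary.mean <= loq_pct + margin_pct


def compute_viability(plate: pd.DataFrame, loq_pct: float = DEFAULT_LOQ_PCT) -> pd.DataFrame:
    """Per-dose viability table from one OD plate.

    The SE per dose comes from the spread of per-well viabilities of the
    treated wells (blank/untreated enter through their strip means).
    """
    _validate_plate(plate)
    blank = float(plate.loc[plate["condition"] == "blank", "od562"].mean())
    untreated = float(plate.loc[plate["condition"] == "untreated", "od562"].mean())
    window = untreated - blank
    if window <= 0:
        raise InputError("assay window collapsed: mean untreated OD <= mean blank OD")

    treated = plate[plate["condition"] == "treated"]
    if treated.empty:
        raise InputError("OD table has no treated wells")
    if treated["dose_gy"].isna().any():
        raise InputError("treated wells must carry a dose_gy")

    records = []
    for dose, group in treated.groupby("dose_gy", sort=True):
        v = (group["od562"] - blank) / window * 100.0
        summ = standard_error(v)
        records.append(
            {
                "dose_gy": float(dose),
                "viability_pct": summ.mean,
                "se_pct": summ.se,
                "n_wells": summ.n,
                "at_loq": _at_loq(summ, loq_pct),
            }
        )
    return pd.DataFrame.from_records(records, columns=list(VIABILITY_COLUMNS))


def dose_response_summary(
    tables: list[pd.DataFrame], loq_pct: float = DEFAULT_LOQ_PCT
) -> pd.DataFrame:
    """Pool viability tables from independent experiments, well-weighted.

    Pooling uses the exact grouped sum-of-squares decomposition, so means
    and SEs match what the concatenated per-well viabilities would give.
    Dose grids must agree across experiments.
    """
    if not tables:
        raise InputError("dose_response_summary: no tables to pool")
    grids = [set(t["dose_gy"]) for t in tables]
    for grid in grids[1:]:
        if grid != grids[0]:
            diff = sorted(grid ^ grids[0])
            raise InputError(f"mismatched dose grids; symmetric difference: {diff}")

    records = []
    for dose in sorted(grids[0]):
        groups = []
        for t in tables:
            row = t.loc[t["dose_gy"] == dose].iloc[0]
            groups.append(
                GroupSummary(
                    mean=float(row["viability_pct"]),
                    se=float(row["se_pct"]),
                    n=int(row["n_wells"]),
                )
            )
        pooled = combine_groups(groups)
        records.append(
            {
                "dose_gy": float(dose),
                "viability_pct": pooled.mean,
                "se_pct": pooled.se,
                "n_wells": pooled.n,
                "at_loq": _at_loq(pooled, loq_pct),
            }
        )
    return pd.DataFrame.from_records(records, columns=list(VIABILITY_COLUMNS))
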