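"""Clonogenic survival analysis: plating efficiency, surviving fractions and
the single-hit multi-target fit S(D) = 1 - (1 - e^(-D/D0))^n.

The primary parameter estimates come from the linear stage: least-squares
regression of ln(SF) on dose, with D0 = -1/slope (reciprocal of the slope in
the linear range), n = e^intercept (back-extrapolated intercept) and the
quasi-threshold dose Dq = D0 ln n (where the extrapolated line crosses 100%
survival). An optional nonlinear refinement of S(D) on all points is also
reported. By default the linear range is determined by one iteration of a
shoulder cut (doses >= 2 x the initial Dq estimate); ``all_doses=True``
regresses on every irradiated dose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

from .errors import InputError, NumericalError
from .stats import GroupSummary, standard_error
from .synthetic import multitarget_survival

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalPoint",
    "MultiTargetFit",
    "plating_efficiency",
    "survival_fraction",
    "fit_multitarget",
    "predict_survival",
]

COLONY_COLUMNS = ("dose_gy", "dish_id", "cells_seeded", "colonies")


def _validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(COLONY_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"colony table missing columns: {sorted(missing)}")
    if (table["colonies"] < 0).any():
        raise InputError("colonies must be >= 0")
    if (table["cells_seeded"] <= 0).any():
        raise InputError("cells_seeded must be > 0")
    return table


@dataclass(frozen=True)
class SurvivalPoint:
    """Per-dose surviving fraction after plating-efficiency correction."""

    dose_gy: float
    surviving_fraction: float
    se: float
    n_dishes: int


@dataclass(frozen=True)
class MultiTargetFit:
    """Single-hit multi-target parameters and regression diagnostics."""

    d0: float
    n_extrap: float
    dq: float
    slope_se: float
    r_squared: float
    linear_range_doses: tuple[float, ...]
    refined: Mapping[str, float] | None = None
    primary: str = "linear"
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise NumericalError("fit produced non-positive D0")
        if self.n_extrap < 1:
            raise NumericalError("fit produced extrapolation number < 1")
        if abs(self.dq - self.d0 * math.log(self.n_extrap)) > 1e-9:
            raise NumericalError("Dq must equal D0 * ln(n)")

    def to_dict(self) -> dict:
        return {
            "d0_gy": self.d0,
            "n_extrap": self.n_extrap,
            "dq_gy": self.dq,
            "slope_se": self.slope_se,
            "r_squared": self.r_squared,
            "linear_range_doses": list(self.linear_range_doses),
            "refined": dict(self.refined) if self.refined else None,
            "primary": self.primary,
            "diagnostics": dict(self.diagnostics),
        }


def plating_efficiency(table: pd.DataFrame) -> GroupSummary:
    """Mean colonies/cells_seeded over dose-0 dishes, with SE across dishes."""
    _validate_counts(table)
    zero = table[table["dose_gy"] == 0]
    if zero.empty:
        raise InputError("plating_efficiency: no dose-0 records")
    return standard_error(zero["colonies"] / zero["cells_seeded"])


def survival_fraction(table: pd.DataFrame, pe: float) -> list[SurvivalPoint]:
    """Per-dose mean SF = colonies / (cells_seeded * PE), SE over dishes."""
    _validate_counts(table)
    if not (0.0 < pe <= 1.0):
        raise InputError("plating efficiency must be in (0, 1]")
    points = []
    for dose, group in table.groupby("dose_gy", sort=True):
        sf = group["colonies"] / (group["cells_seeded"] * pe)
        summ = standard_error(sf)
        if summ.mean == 0.0:
            log.warning("survival_fraction: all dishes at %g Gy had zero colonies", dose)
        points.append(
            SurvivalPoint(
                dose_gy=float(dose),
                surviving_fraction=summ.mean,
                se=summ.se if summ.se == summ.se else 0.0,
                n_dishes=summ.n,
            )
        )
    return points


def _linear_stage(
    doses: np.ndarray, log_sf: np.ndarray
) -> tuple[float, float, float, float, float]:
    res = sps.linregress(doses, log_sf)
    if res.slope >= 0:
        raise NumericalError("no killing detected: ln(SF) does not decrease with dose")
    d0 = -1.0 / res.slope
    n_raw = math.exp(res.intercept)
    n = max(1.0, n_raw)
    dq = d0 * math.log(n)
    return d0, n, dq, float(res.stderr), float(res.rvalue**2)


def fit_multitarget(
    points: Sequence[SurvivalPoint],
    all_doses: bool = False,
    refine: bool = True,
) -> MultiTargetFit:
    """Fit the multi-target model to plating-efficiency-corrected SF points.

    Points at dose 0 anchor the nonlinear refinement only; zero-SF points
    cannot enter the ln regression and are dropped from it with a warning.
    """
    irr = [p for p in points if p.dose_gy > 0]
    usable = [p for p in irr if p.surviving_fraction > 0]
    dropped = len(irr) - len(usable)
    if dropped:
        log.warning("fit_multitarget: %d zero-SF dose(s) excluded from ln regression", dropped)
    if len({p.dose_gy for p in usable}) < 3:
        raise InputError("fit_multitarget needs >= 3 distinct irradiated doses")

    usable = sorted(usable, key=lambda p: p.dose_gy)
    doses = np.array([p.dose_gy for p in usable])
    log_sf = np.log([p.surviving_fraction for p in usable])

    d0, n, dq, slope_se, r2 = _linear_stage(doses, log_sf)
    linear_doses = doses
    if not all_doses:
        # one iteration of the shoulder cut: keep doses past ~2x the initial Dq
        sel = doses >= 2.0 * dq
        if sel.sum() < 3:
            raise InputError(
                "fewer than 3 doses in the estimated linear range; "
                "rerun with all_doses=True"
            )
        if sel.sum() < doses.size:
            d0, n, dq, slope_se, r2 = _linear_stage(doses[sel], log_sf[sel])
            linear_doses = doses[sel]

    refined = None
    if refine:
        fit_pts = [p for p in points if p.surviving_fraction > 0]
        x = np.array([p.dose_gy for p in fit_pts])
        y = np.array([p.surviving_fraction for p in fit_pts])
        try:
            popt, _ = curve_fit(
                lambda d, d0_, n_: 1.0 - (1.0 - np.exp(-d / d0_)) ** n_,
                x,
                y,
                p0=(d0, n),
                bounds=((1e-6, 1.0), (np.inf, np.inf)),
                maxfev=2000,
            )
            refined = {
                "d0_gy": float(popt[0]),
                "n_extrap": float(popt[1]),
                "dq_gy": float(popt[0] * math.log(popt[1])),
            }
        except RuntimeError:  # refinement is optional; the linear fit stands
            log.warning("fit_multitarget: nonlinear refinement failed to converge")

    return MultiTargetFit(
        d0=d0,
        n_extrap=n,
        dq=dq,
        slope_se=slope_se,
        r_squared=r2,
        linear_range_doses=tuple(float(d) for d in linear_doses),
        refined=refined,
        diagnostics={"n_points": float(len(usable)), "dropped_zero_sf": float(dropped)},
    )


def predict_survival(fit: MultiTargetFit, dose: float) -> float:
    """Evaluate S(D) = 1 - (1 - e^(-D/D0))^n with n = e^(Dq/D0)."""
    if dose < 0:
        raise InputError("dose must be >= 0")
    n = math.exp(fit.dq / fit.d0)
    return multitarget_survival(dose, fit.d0, n)
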