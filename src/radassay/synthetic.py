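"""Seeded synthetic-data generators for every pipeline stage.

Randomness policy: each public simulator takes one integer ``seed`` and
derives independent child streams from it via ``numpy.random.SeedSequence``
spawning, so adding a draw to one sub-step never perturbs another.
Identical seed + configuration gives byte-identical outputs.

Generated structures:

* flow-cytometry event tables (PI fluorescence area + pulse width) from a
  five-population DNA-content mixture, with optional G1-G1 doublets whose
  area is the sum of two G1 draws and whose pulse width is enlarged;
* colony-count tables, Poisson around ``cells_seeded * PE * S(D)`` with the
  single-hit multi-target survival ``S(D) = 1 - (1 - exp(-D/D0))^n``;
* 96-well MTT OD tables with blank and untreated strips and a configurable
  viability quantification floor;
* G2-arrest kinetics series: one event table per timepoint with the G2
  fraction interpolating baseline -> peak -> baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "PHASES",
    "DEFAULT_RELATIVE_MEANS",
    "CellCycleTruth",
    "SurvivalTruth",
    "ViabilityTruth",
    "TimedEvents",
    "simulate_flow_events",
    "simulate_colony_counts",
    "simulate_mtt_plate",
    "simulate_g2_kinetics",
    "multitarget_survival",
]

#: Canonical population order by DNA content.
PHASES = ("subG1", "G1", "S", "G2", "polyploid")

#: Default fluorescence means as multiples of the G1 mean: sub-G1 debris at
#: half a genome equivalent, S intermediate, G2 at 2x, polyploid at 2x G2.
DEFAULT_RELATIVE_MEANS: Mapping[str, float] = {
    "subG1": 0.5,
    "G1": 1.0,
    "S": 1.5,
    "G2": 2.0,
    "polyploid": 4.0,
}


def _validate_fractions(fractions: Mapping[str, float]) -> dict[str, float]:
    full = {p: float(fractions.get(p, 0.0)) for p in PHASES}
    unknown = set(fractions) - set(PHASES)
    if unknown:
        raise InputError(f"unknown population name(s): {sorted(unknown)}")
    for name, f in full.items():
        if f < 0:
            raise InputError(f"fraction for {name} is negative ({f})")
    total = sum(full.values())
    if abs(total - 1.0) > 1e-9:
        raise InputError(f"fractions must sum to 1 (got {total!r})")
    return full


@dataclass(frozen=True)
class CellCycleTruth:
    """Ground-truth five-population DNA-content mixture.

    ``s_sigma_scale`` broadens the S-phase component relative to G1
    (S content spans G1 -> G2); all other populations get a CV-scaled
    standard deviation ``g1_cv * mean``.
    """

    fractions: Mapping[str, float]
    g1_mean: float = 200.0
    g1_cv: float = 0.04
    relative_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATIVE_MEANS)
    )
    doublet_fraction: float = 0.0
    s_sigma_scale: float = 2.0
    width_mean: float = 100.0
    width_cv: float = 0.05
    doublet_width_factor: float = 1.6

    def validate(self) -> None:
        _validate_fractions(self.fractions)
        if self.g1_mean <= 0:
            raise InputError("g1_mean must be > 0")
        if self.g1_cv <= 0:
            raise InputError("g1_cv must be > 0")
        if not (0.0 <= self.doublet_fraction < 1.0):
            raise InputError("doublet_fraction must be in [0, 1)")
        rel = [self.relative_means.get(p) for p in PHASES]
        if any(r is None for r in rel):
            raise InputError("relative_means must cover all five populations")
        if not all(a < b for a, b in zip(rel, rel[1:])):
            raise InputError(
                "relative_means must be strictly increasing in order "
                "subG1 < G1 < S < G2 < polyploid"
            )
        if self.s_sigma_scale <= 0 or self.width_mean <= 0 or self.width_cv <= 0:
            raise InputError("s_sigma_scale, width_mean and width_cv must be > 0")
        if self.doublet_width_factor <= 1.0:
            raise InputError("doublet_width_factor must exceed singlet width (> 1)")

    def population_mean(self, name: str) -> float:
        return self.relative_means[name] * self.g1_mean

    def population_sigma(self, name: str) -> float:
        if name == "S":
            return self.s_sigma_scale * self.g1_cv * self.g1_mean
        return self.g1_cv * self.population_mean(name)


@dataclass(frozen=True)
class SurvivalTruth:
    """Ground truth for a clonogenic survival experiment.

    ``cells_seeded`` may be a single count per dish or a dose -> count map
    (seeding is scaled up at high dose to keep colonies countable, mimicking
    seeding "adjusted ... to allow growth of about 50 colonies per dish").
    """

    d0: float = 1.45
    n_extrap: float = 1.327
    plating_efficiency: float = 0.64
    cells_seeded: int | Mapping[float, int] = 100
    doses: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    replicates: int = 6

    def validate(self) -> None:
        if self.d0 <= 0:
            raise InputError("d0 must be > 0")
        if self.n_extrap < 1:
            raise InputError("n_extrap must be >= 1")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise InputError("plating_efficiency must be in (0, 1]")
        if any(d < 0 for d in self.doses):
            raise InputError("doses must be >= 0")
        if 0.0 not in [float(d) for d in self.doses]:
            raise InputError("doses must include 0 for plating efficiency")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        for d in self.doses:
            if self.seeded_at(float(d)) <= 0:
                raise InputError("cells_seeded must be > 0 for every dose")

    def seeded_at(self, dose: float) -> int:
        if isinstance(self.cells_seeded, Mapping):
            return int(self.cells_seeded[dose])
        return int(self.cells_seeded)

    def survival(self, dose: float) -> float:
        return multitarget_survival(dose, self.d0, self.n_extrap)

    @classmethod
    def with_target_colonies(
        cls,
        *,
        d0: float = 1.45,
        n_extrap: float = 1.327,
        plating_efficiency: float = 0.64,
        doses: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
        replicates: int = 6,
        target_colonies: float = 50.0,
    ) -> "SurvivalTruth":
        """Seeding adjusted per dose so each dish expects ~``target_colonies``."""
        seeding = {}
        for d in doses:
            s = multitarget_survival(float(d), d0, n_extrap)
            seeding[float(d)] = max(1, round(target_colonies / (plating_efficiency * s)))
        return cls(
            d0=d0,
            n_extrap=n_extrap,
            plating_efficiency=plating_efficiency,
            cells_seeded=seeding,
            doses=tuple(float(d) for d in doses),
            replicates=replicates,
        )


@dataclass(frozen=True)
class ViabilityTruth:
    """Ground truth for an MTT dose-response plate."""

    dose_to_viability: Mapping[float, float]
    od_untreated_mean: float = 0.90
    od_blank_mean: float = 0.08
    noise_sd: float = 0.01
    floor_pct: float = 20.0

    def validate(self) -> None:
        for d, v in self.dose_to_viability.items():
            if not (0.0 <= v <= 100.0):
                raise InputError(f"viability at dose {d} outside [0, 100]: {v}")
        if not self.od_untreated_mean > self.od_blank_mean:
            raise InputError("od_untreated_mean must exceed od_blank_mean")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if not (0.0 <= self.floor_pct <= 100.0):
            raise InputError("floor_pct must be in [0, 100]")


@dataclass(frozen=True)
class TimedEvents:
    """A flow event table acquired at a known time after irradiation."""

    time_h: float
    events: pd.DataFrame


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_flow_events(
    truth: CellCycleTruth, n_events: int, seed: int
) -> pd.DataFrame:
    """Draw a per-event PI area/width table from a population mixture.

    Events are assigned to populations multinomially by the truth fractions;
    a ``doublet_fraction`` share of events are G1-G1 doublets with summed
    area and enlarged pulse width. The returned frame carries the hidden
    truth label in a ``label`` column (dropped when written to CSV).
    """
    truth.validate()
    if n_events <= 0:
        raise InputError("n_events must be > 0")

    rng_split, rng_area, rng_width, rng_perm = _streams(seed, 4)

    n_doublets = int(rng_split.binomial(n_events, truth.doublet_fraction))
    n_singlets = n_events - n_doublets
    fracs = _validate_fractions(truth.fractions)
    counts = rng_split.multinomial(n_singlets, [fracs[p] for p in PHASES])

    areas: list[np.ndarray] = []
    widths: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for name, k in zip(PHASES, counts):
        a = rng_area.normal(truth.population_mean(name), truth.population_sigma(name), k)
        w = rng_width.normal(truth.width_mean, truth.width_cv * truth.width_mean, k)
        areas.append(a)
        widths.append(w)
        labels.append(np.full(k, name, dtype=object))

    if n_doublets:
        g1_mu = truth.population_mean("G1")
        g1_sd = truth.population_sigma("G1")
        a = rng_area.normal(g1_mu, g1_sd, n_doublets) + rng_area.normal(
            g1_mu, g1_sd, n_doublets
        )
        w_mu = truth.doublet_width_factor * truth.width_mean
        w = rng_width.normal(w_mu, truth.width_cv * w_mu, n_doublets)
        areas.append(a)
        widths.append(w)
        labels.append(np.full(n_doublets, "doublet", dtype=object))

    area = np.clip(np.concatenate(areas), 0.0, None)
    width = np.clip(np.concatenate(widths), 0.0, None)
    label = np.concatenate(labels)

    order = rng_perm.permutation(n_events)
    return pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "area": area[order],
            "width": width[order],
            "label": label[order],
        }
    )


def multitarget_survival(dose: float, d0: float, n_extrap: float) -> float:
    """Single-hit multi-target surviving fraction S(D) = 1 - (1 - e^(-D/D0))^n."""
    if dose < 0:
        raise InputError("dose must be >= 0")
    if d0 <= 0:
        raise InputError("d0 must be > 0")
    return float(1.0 - (1.0 - np.exp(-dose / d0)) ** n_extrap)


def simulate_colony_counts(truth: SurvivalTruth, seed: int) -> pd.DataFrame:
    """Poisson colony counts per dish around ``cells_seeded * PE * S(D)``."""
    truth.validate()
    (rng,) = _streams(seed, 1)
    records = []
    for dose in truth.doses:
        dose = float(dose)
        seeded = truth.seeded_at(dose)
        lam = seeded * truth.plating_efficiency * truth.survival(dose)
        for rep in range(truth.replicates):
            records.append(
                {
                    "dose_gy": dose,
                    "dish_id": f"d{dose:g}_r{rep + 1}",
                    "cells_seeded": seeded,
                    "colonies": int(rng.poisson(lam)),
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_mtt_plate(
    truth: ViabilityTruth, wells_per_condition: int, seed: int
) -> pd.DataFrame:
    """Simulate an OD plate with blank/untreated strips and dosed wells.

    OD(D) = blank + window * max(viability(D), floor)/100 + Gaussian noise,
    where window = untreated - blank; blank and untreated wells are drawn
    from the same noise model.
    """
    truth.validate()
    if wells_per_condition < 1:
        raise InputError("wells_per_condition must be >= 1")
    (rng,) = _streams(seed, 1)

    conditions: list[tuple[str, float | None, float]] = [
        ("blank", None, truth.od_blank_mean),
        ("untreated", None, truth.od_untreated_mean),
    ]
    for dose in sorted(truth.dose_to_viability):
        v_eff = max(truth.dose_to_viability[dose], truth.floor_pct)
        # convex combination so v=0/v=100 hit the blank/untreated means exactly
        w = v_eff / 100.0
        od = truth.od_blank_mean * (1.0 - w) + truth.od_untreated_mean * w
        conditions.append(("treated", float(dose), od))

    rows = "ABCDEFGH"
    records = []
    i = 0
    for condition, dose, od_mean in conditions:
        for _ in range(wells_per_condition):
            r, c = divmod(i, 12)
            if r >= len(rows):
                raise InputError("plate layout overflow: more than 96 wells requested")
            od = od_mean + (rng.normal(0.0, truth.noise_sd) if truth.noise_sd else 0.0)
            records.append(
                {
                    "well": f"{rows[r]}{c + 1}",
                    "row": rows[r],
                    "col": c + 1,
                    "condition": condition,
                    "dose_gy": dose if dose is not None else np.nan,
                    "od562": od,
                }
            )
            i += 1
    return pd.DataFrame.from_records(records)


def _g2_fraction_at(
    t: float, baseline_g2: float, peak_g2: float, peak_time: float, resolve_time: float
) -> float:
    if t <= 0:
        return baseline_g2
    if t <= peak_time:
        return baseline_g2 + (peak_g2 - baseline_g2) * t / peak_time
    if t < resolve_time:
        return peak_g2 + (baseline_g2 - peak_g2) * (t - peak_time) / (
            resolve_time - peak_time
        )
    return baseline_g2


def simulate_g2_kinetics(
    baseline: Mapping[str, float],
    peak_g2: float,
    peak_time: float,
    resolve_time: float,
    timepoints: Sequence[float],
    events_per_point: int,
    seed: int,
    template: CellCycleTruth | None = None,
) -> list[TimedEvents]:
    """One event table per timepoint with a transient G2 accumulation.

    The G2 fraction rises linearly from baseline to ``peak_g2`` at
    ``peak_time`` and returns linearly to baseline at ``resolve_time``;
    G1 and S shrink proportionally so fractions keep summing to 1
    (sub-G1 and polyploid stay fixed).
    """
    base = _validate_fractions(baseline)
    if len(timepoints) == 0:
        raise InputError("timepoints must be non-empty")
    if not peak_g2 > base["G2"]:
        raise InputError("peak_g2 must exceed the baseline G2 fraction")
    if not resolve_time > peak_time > 0:
        raise InputError("need resolve_time > peak_time > 0")
    if events_per_point <= 0:
        raise InputError("events_per_point must be > 0")
    fixed = base["subG1"] + base["polyploid"]
    if peak_g2 + fixed > 1.0:
        raise InputError("peak_g2 leaves no room for the fixed populations")

    template = template or CellCycleTruth(fractions=base)
    seeds = np.random.SeedSequence(seed).spawn(len(timepoints))
    out = []
    for t, child in zip(timepoints, seeds):
        g2 = _g2_fraction_at(float(t), base["G2"], peak_g2, peak_time, resolve_time)
        scale = (1.0 - g2 - fixed) / (base["G1"] + base["S"])
        fractions = {
            "subG1": base["subG1"],
            "G1": base["G1"] * scale,
            "S": base["S"] * scale,
            "G2": g2,
            "polyploid": base["polyploid"],
        }
        truth_t = replace(template, fractions=fractions)
        events = simulate_flow_events(
            truth_t, events_per_point, seed=int(child.generate_state(1)[0] % 2**31)
        )
        out.append(TimedEvents(time_h=float(t), events=events))
    return out
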