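"""DNA-content (PI) histogram analysis.

The analysis chain is: doublet gating on pulse width vs area, linear
binning of the gated areas into a fluorescence histogram, a stepwise
five-Gaussian deconvolution (G1 located first, the remaining populations
seeded stoichiometrically at fixed multiples of the G1 peak, then a joint
bound-constrained least-squares refit), phase-fraction extraction from the
component areas, and a t-test based G2-arrest kinetics read-out.

The optimiser contract is the constrained least-squares optimum of

    SSE = sum_b ( count_b - sum_k A_k exp(-(c_b - mu_k)^2 / (2 sigma_k^2)) )^2

subject to mu ordering (enforced through non-overlapping per-component mu
windows), sigma > 0 and A >= 0. Any bound-constrained solver reaching that
optimum qualifies; we use ``scipy.optimize.least_squares`` (TRF) with an
analytic Jacobian.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .errors import InputError, NumericalError
from .stats import standard_error, t_test
from .synthetic import DEFAULT_RELATIVE_MEANS, PHASES

log = logging.getLogger(__name__)

__all__ = [
    "DoubletGate",
    "PIHistogram",
    "GaussianComponent",
    "MixtureFit",
    "KineticsResult",
    "gate_doublets",
    "build_histogram",
    "estimate_g1_peak",
    "initialize_components",
    "fit_mixture",
    "phase_fractions",
    "fractions_from_events",
    "g2_kinetics",
]

#: Default initial sigma as a fraction of the component mean.
DEFAULT_CV = 0.05

#: Default S-phase sigma multiple of the G1 sigma (S spans G1 -> G2 content).
S_SIGMA_SCALE = 2.0


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoubletGate:
    """Linear width-vs-area gate: keep events with width <= slope*area + intercept."""

    slope: float = 0.0
    intercept: float = 130.0

    @classmethod
    def calibrate(cls, events: pd.DataFrame, factor: float = 1.3) -> "DoubletGate":
        """Horizontal gate at ``factor`` x the median pulse width.

        Doublets carry roughly double width, singlets cluster tightly, so
        the median is a robust singlet anchor.
        """
        if events.empty:
            raise InputError("cannot calibrate a gate on an empty event table")
        return cls(slope=0.0, intercept=factor * float(events["width"].median()))


def gate_doublets(events: pd.DataFrame, gate: DoubletGate | None = None) -> pd.DataFrame:
    """Remove doublet events above the width-vs-area gate line."""
    if events.empty:
        raise InputError("gate_doublets: empty event table")
    gate = gate or DoubletGate.calibrate(events)
    keep = events["width"] <= gate.slope * events["area"] + gate.intercept
    removed = int((~keep).sum())
    log.info("gate_doublets: removed %d of %d events", removed, len(events))
    gated = events.loc[keep].reset_index(drop=True)
    if gated.empty:
        raise InputError("gate_doublets: gate removed every event")
    return gated


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PIHistogram:
    """Binned fluorescence distribution on half-open linear bins [e_i, e_{i+1})."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise InputError("histogram needs len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(edges) <= 0):
            raise InputError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise InputError("bin counts must be >= 0")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.centers, "count": self.counts})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PIHistogram":
        centers = np.asarray(frame["channel"], dtype=float)
        if centers.size < 2:
            raise InputError("histogram frame needs >= 2 channels")
        step = np.diff(centers)
        if not np.allclose(step, step[0]):
            raise InputError("histogram channels must be evenly spaced")
        edges = np.concatenate([centers - step[0] / 2, [centers[-1] + step[0] / 2]])
        return cls(bin_edges=edges, counts=np.asarray(frame["count"], dtype=float))


def build_histogram(
    events: pd.DataFrame, n_bins: int = 256, range_max: float = 1024.0
) -> PIHistogram:
    """Linear binning of event areas on [0, range_max); overflow lands in the last bin."""
    if n_bins < 64:
        raise InputError("n_bins must be >= 64")
    if range_max <= 0:
        raise InputError("range_max must be > 0")
    area = np.asarray(events["area"], dtype=float)
    if area.size == 0:
        raise InputError("build_histogram: empty event table")
    edges = np.linspace(0.0, range_max, n_bins + 1)
    overflow = int((area >= range_max).sum())
    if overflow:
        log.info("build_histogram: %d overflow events folded into last bin", overflow)
    clipped = np.minimum(area, np.nextafter(range_max, 0.0))
    counts, _ = np.histogram(clipped, bins=edges)
    return PIHistogram(bin_edges=edges, counts=counts.astype(float))


# ---------------------------------------------------------------------------
# peak finding and initialisation
# ---------------------------------------------------------------------------


def _smoothed(counts: np.ndarray, window: int = 5) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(counts, kernel, mode="same")


def _local_modes(hist: PIHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Channels and heights of local maxima of the lightly smoothed histogram."""
    smooth = _smoothed(hist.counts)
    idx, _ = find_peaks(smooth, prominence=0.05 * smooth.max())
    if idx.size == 0:
        idx = np.array([int(np.argmax(smooth))])
    return hist.centers[idx], smooth[idx]


def estimate_g1_peak(hist: PIHistogram, user_estimate: float | None = None) -> float:
    """Locate the G1 peak channel.

    With a user estimate, the nearest local mode wins; otherwise the tallest
    mode in the lower half of the occupied channel range (G2 sits at ~2x G1,
    so the G1 mode lives in the lower half). Ties break toward lower channels.
    """
    if hist.counts.sum() == 0:
        raise InputError("estimate_g1_peak: all-zero histogram")
    modes, heights = _local_modes(hist)
    if user_estimate is not None:
        dist = np.abs(modes - user_estimate)
        return float(modes[int(np.argmin(dist))])
    occupied = np.flatnonzero(hist.counts > 0)
    lo = hist.centers[occupied[0]]
    hi = hist.centers[occupied[-1]]
    mid = 0.5 * (lo + hi)
    in_lower = modes <= mid
    cand_modes = modes[in_lower] if in_lower.any() else modes
    cand_heights = heights[in_lower] if in_lower.any() else heights
    best = np.flatnonzero(cand_heights == cand_heights.max())[0]
    return float(cand_modes[best])


@dataclass(frozen=True)
class GaussianComponent:
    """One named population: A * exp(-(c - mu)^2 / (2 sigma^2))."""

    name: str
    mu: float
    sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InputError(f"component {self.name}: sigma must be > 0")
        if self.amplitude < 0:
            raise InputError(f"component {self.name}: amplitude must be >= 0")

    def profile(self, channels: np.ndarray) -> np.ndarray:
        z = (channels - self.mu) / self.sigma
        return self.amplitude * np.exp(-0.5 * z * z)

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)


def _model(channels: np.ndarray, components: Sequence[GaussianComponent]) -> np.ndarray:
    total = np.zeros_like(channels, dtype=float)
    for comp in components:
        total += comp.profile(channels)
    return total


def _sse(hist: PIHistogram, components: Sequence[GaussianComponent]) -> float:
    resid = _model(hist.centers, components) - hist.counts
    return float(resid @ resid)


def initialize_components(
    hist: PIHistogram, g1_peak: float, cv: float = DEFAULT_CV
) -> list[GaussianComponent]:
    """Stoichiometric initial components at {0.5, 1, 1.5, 2, 4} x the G1 peak.

    Amplitudes come from histogram heights at those channels (floored at a
    small positive value); sigmas from a default CV, with the S component
    twice as broad as G1.
    """
    centers = hist.centers
    if not (centers[0] <= g1_peak <= centers[-1]):
        raise InputError("g1_peak outside histogram range")
    amp_floor = max(1e-3, 1e-4 * float(hist.counts.max()))
    comps = []
    g1_sigma = cv * g1_peak
    for name in PHASES:
        mu = float(np.clip(DEFAULT_RELATIVE_MEANS[name] * g1_peak, centers[0], centers[-1]))
        height = float(hist.counts[int(np.argmin(np.abs(centers - mu)))])
        sigma = S_SIGMA_SCALE * g1_sigma if name == "S" else cv * mu
        comps.append(
            GaussianComponent(
                name=name, mu=mu, sigma=sigma, amplitude=max(height, amp_floor)
            )
        )
    return comps


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureFit:
    """Result of the constrained Gaussian-sum fit."""

    components: tuple[GaussianComponent, ...]
    sse: float
    sse_init: float
    n_iterations: int
    converged: bool
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    def component(self, name: str) -> GaussianComponent:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "components": [
                {"name": c.name, "mu": c.mu, "sigma": c.sigma, "amplitude": c.amplitude}
                for c in self.components
            ],
            "sse": self.sse,
            "sse_init": self.sse_init,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def _pack(components: Sequence[GaussianComponent]) -> np.ndarray:
    return np.array([v for c in components for v in (c.mu, c.sigma, c.amplitude)])


def _unpack(
    params: np.ndarray, names: Sequence[str]
) -> tuple[GaussianComponent, ...]:
    comps = []
    for i, name in enumerate(names):
        mu, sigma, amp = params[3 * i : 3 * i + 3]
        comps.append(GaussianComponent(name=name, mu=mu, sigma=sigma, amplitude=amp))
    return tuple(comps)


def _residual_and_jac(channels: np.ndarray, counts: np.ndarray, k: int):
    def residual(p: np.ndarray) -> np.ndarray:
        total = np.zeros_like(channels)
        for i in range(k):
            mu, sigma, amp = p[3 * i : 3 * i + 3]
            z = (channels - mu) / sigma
            total += amp * np.exp(-0.5 * z * z)
        return total - counts

    def jac(p: np.ndarray) -> np.ndarray:
        cols = np.empty((channels.size, 3 * k))
        for i in range(k):
            mu, sigma, amp = p[3 * i : 3 * i + 3]
            d = channels - mu
            e = np.exp(-0.5 * (d / sigma) ** 2)
            cols[:, 3 * i] = amp * e * d / sigma**2
            cols[:, 3 * i + 1] = amp * e * d**2 / sigma**3
            cols[:, 3 * i + 2] = e
        return cols

    return residual, jac


def _mu_windows(
    mus: Sequence[float], lo: float, hi: float
) -> list[tuple[float, float]]:
    """Non-overlapping mu boxes with cut points midway between neighbours.

    Keeping each component inside its own window enforces the population
    ordering subG1 < G1 < S < G2 < polyploid as a box constraint.
    """
    bounds = []
    for i, mu in enumerate(mus):
        left = lo if i == 0 else 0.5 * (mus[i - 1] + mus[i])
        right = hi if i == len(mus) - 1 else 0.5 * (mus[i] + mus[i + 1])
        bounds.append((left, right))
    return bounds


def _fit_gaussian_sum(
    hist: PIHistogram,
    init: Sequence[GaussianComponent],
    max_nfev: int = 500,
) -> tuple[tuple[GaussianComponent, ...], float, int, bool]:
    """Bound-constrained least-squares fit of a sum of Gaussians to a histogram."""
    channels = hist.centers
    counts = hist.counts
    k = len(init)
    names = [c.name for c in init]
    mus = [c.mu for c in init]
    if any(b <= a for a, b in zip(mus, mus[1:])):
        raise InputError("initial component means must be strictly increasing")

    span = channels[-1] - channels[0]
    bin_w = float(np.diff(hist.bin_edges).mean())
    windows = _mu_windows(mus, channels[0], channels[-1])
    lower, upper = [], []
    for (wl, wr), comp in zip(windows, init):
        lower += [wl, bin_w / 4.0, 0.0]
        upper += [wr, span / 3.0, max(3.0 * float(counts.max()), 1.0)]
    lb, ub = np.array(lower), np.array(upper)

    p0 = np.clip(_pack(init), lb + 1e-12, ub - 1e-12)
    residual, jac = _residual_and_jac(channels, counts, k)
    if not np.all(np.isfinite(residual(p0))):
        raise NumericalError("fit_mixture: non-finite residuals at initialization")

    res = least_squares(
        residual,
        p0,
        jac=jac,
        bounds=(lb, ub),
        method="trf",
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    comps = _unpack(res.x, names)
    sse = float(2.0 * res.cost)
    converged = bool(res.status > 0) and res.nfev < max_nfev
    return comps, sse, int(res.nfev), converged


def fit_mixture(
    hist: PIHistogram,
    init: Sequence[GaussianComponent] | None = None,
    g1_estimate: float | None = None,
) -> MixtureFit:
    """Stepwise five-Gaussian deconvolution of a PI histogram.

    Stage 1 refines the G1 component alone on a window around the G1 peak
    estimate; stage 2 re-seeds the remaining components stoichiometrically
    from the refined G1; stage 3 is the joint bound-constrained refit. The
    reported SSE never exceeds the SSE of the initialization (the fit falls
    back to the better parameter set).
    """
    if init is None:
        g1_peak = estimate_g1_peak(hist, g1_estimate)
        init = initialize_components(hist, g1_peak)
    init = list(init)
    if [c.name for c in init] != list(PHASES):
        raise InputError(f"init must provide the five components in order {PHASES}")
    sse_init = _sse(hist, init)
    if not np.isfinite(sse_init):
        raise NumericalError("fit_mixture: non-finite SSE at initialization")

    # stage 1: G1 alone on its neighbourhood
    g1 = init[1]
    half = 0.25 * g1.mu
    sel = np.abs(hist.centers - g1.mu) <= half
    nfev_total = 0
    if sel.sum() >= 5:
        sub = PIHistogram(
            bin_edges=np.append(
                hist.bin_edges[:-1][sel], hist.bin_edges[1:][sel][-1]
            ),
            counts=hist.counts[sel],
        )
        try:
            (g1_ref,), _, nfev1, _ = _fit_gaussian_sum(sub, [g1])
            nfev_total += nfev1
            g1 = g1_ref
        except (InputError, NumericalError):  # pragma: no cover - defensive
            log.warning("fit_mixture: G1 pre-fit failed; keeping initial G1")

    # stage 2: stoichiometric re-seed around the refined G1
    centers = hist.centers
    reseed = []
    for comp in init:
        if comp.name == "G1":
            reseed.append(g1)
            continue
        mu = float(
            np.clip(
                DEFAULT_RELATIVE_MEANS[comp.name] / DEFAULT_RELATIVE_MEANS["G1"] * g1.mu,
                centers[0],
                centers[-1],
            )
        )
        height = float(hist.counts[int(np.argmin(np.abs(centers - mu)))])
        sigma = (
            S_SIGMA_SCALE * g1.sigma
            if comp.name == "S"
            else g1.sigma / g1.mu * mu
        )
        reseed.append(
            GaussianComponent(
                name=comp.name,
                mu=mu,
                sigma=sigma,
                amplitude=max(height, 1e-3),
            )
        )
    mus = [c.mu for c in reseed]
    if any(b <= a for a, b in zip(mus, mus[1:])):  # clipped into collision: keep init
        reseed = init

    # stage 3: joint refit
    comps, sse, nfev3, converged = _fit_gaussian_sum(hist, reseed)
    nfev_total += nfev3
    if sse > sse_init:  # optimiser must never be worse than its initialization
        log.warning("fit_mixture: fit SSE exceeded initialization; reverting")
        comps, sse, converged = tuple(init), sse_init, False
    return MixtureFit(
        components=tuple(comps),
        sse=sse,
        sse_init=sse_init,
        n_iterations=nfev_total,
        converged=converged,
        diagnostics={"g1_peak": g1.mu},
    )


def phase_fractions(fit: MixtureFit) -> dict[str, float]:
    """Per-population fractions proportional to component areas A*sigma."""
    weights = {c.name: c.amplitude * c.sigma for c in fit.components}
    total = sum(weights.values())
    if total <= 0:
        raise NumericalError("phase_fractions: all component areas are zero")
    return {name: float(weights[name] / total) for name in PHASES}


def fractions_from_events(
    events: pd.DataFrame,
    n_bins: int = 256,
    range_max: float = 1024.0,
    g1_estimate: float | None = None,
    gate: DoubletGate | None = None,
    apply_gate: bool = True,
) -> dict[str, float]:
    """Convenience chain: gate -> histogram -> deconvolve -> fractions."""
    gated = gate_doublets(events, gate) if apply_gate else events
    hist = build_histogram(gated, n_bins=n_bins, range_max=range_max)
    fit = fit_mixture(hist, g1_estimate=g1_estimate)
    return phase_fractions(fit)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsResult:
    """G2-arrest kinetics summary.

    ``series`` maps time (h) to the mean +/- SE G2 fraction of the
    irradiated arm; ``resolution_time`` is None when the arrest never
    stops being significant within the observed window.
    """

    series: dict[float, tuple[float, float]]
    peak_time: float
    resolution_time: float | None
    p_values: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "series": {
                str(t): {"g2_mean": m, "g2_se": s} for t, (m, s) in self.series.items()
            },
            "peak_time_h": self.peak_time,
            "resolution_time_h": self.resolution_time,
            "p_values": {str(t): p for t, p in self.p_values.items()},
        }


def _g2_replicates(
    series: Mapping[float, Sequence[Mapping[str, float]]]
) -> dict[float, list[float]]:
    return {
        float(t): [float(frac["G2"]) for frac in reps] for t, reps in series.items()
    }


def g2_kinetics(
    series: Mapping[float, Sequence[Mapping[str, float]]],
    control_series: Mapping[float, Sequence[Mapping[str, float]]],
    alpha: float = 0.05,
) -> KineticsResult:
    """Locate the G2-arrest peak and its resolution time.

    ``series`` / ``control_series`` map time (h) to replicate phase-fraction
    dicts for the irradiated and mock-irradiated arms. The peak is the
    timepoint with the highest mean irradiated G2 fraction; the resolution
    time is the earliest timepoint at/after the peak where irradiated and
    control G2 fractions no longer differ significantly (two-sample t-test).
    """
    irr = _g2_replicates(series)
    ctl = _g2_replicates(control_series)
    if set(irr) != set(ctl):
        diff = sorted(set(irr) ^ set(ctl))
        raise InputError(f"unmatched timepoints between arms: {diff}")
    if len(irr) < 3:
        raise InputError("g2_kinetics needs >= 3 timepoints")

    times = sorted(irr)
    means = {t: standard_error(irr[t]) for t in times}
    peak_time = min(times, key=lambda t: (-means[t].mean, t))

    p_values: dict[float, float] = {}
    resolution: float | None = None
    for t in times:
        if t < peak_time:
            continue
        p_values[t] = t_test(irr[t], ctl[t])
        if resolution is None and p_values[t] >= alpha:
            resolution = t
    if resolution is not None and resolution < peak_time:  # defensive
        raise NumericalError("resolution before peak")
    return KineticsResult(
        series={t: (means[t].mean, means[t].se) for t in times},
        peak_time=peak_time,
        resolution_time=resolution,
        p_values=p_values,
    )
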