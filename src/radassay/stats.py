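"""Shared descriptive statistics and hypothesis tests.

Standard errors are sample-sd based (``sd / sqrt(n)``); the two-sample
t-test defaults to the Welch (unequal-variance) form, with a pooled
Student's variant available via ``pooled=True``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError

log = logging.getLogger(__name__)

__all__ = ["GroupSummary", "standard_error", "t_test", "combine_groups"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard error and size of one replicate group.

    For a single observation the standard error is undefined and stored
    as ``nan`` (never 0).
    """

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError("GroupSummary requires n >= 1")
        if self.n >= 2 and not (self.se >= 0):
            raise InputError("standard error must be >= 0")

    @property
    def se_defined(self) -> bool:
        return not math.isnan(self.se)

    @property
    def sd(self) -> float:
        return self.se * math.sqrt(self.n)


def standard_error(values: Iterable[float]) -> GroupSummary:
    """Summarise ``values`` as mean +/- standard error.

    With fewer than two values the SE is reported as ``nan`` (explicitly
    undefined) rather than 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InputError("standard_error: empty input")
    if not np.all(np.isfinite(arr)):
        raise InputError("standard_error: non-finite values in input")
    mean = float(arr.mean())
    if arr.size < 2:
        return GroupSummary(mean=mean, se=float("nan"), n=1)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return GroupSummary(mean=mean, se=se, n=int(arr.size))


def combine_groups(groups: Sequence[GroupSummary]) -> GroupSummary:
    """Pool replicate groups as if their underlying observations were merged.

    Uses the exact grouped decomposition of the total sum of squares
    (within-group + between-group), so the result equals the summary one
    would get from the concatenated raw observations.
    """
    if not groups:
        raise InputError("combine_groups: no groups to pool")
    n_total = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n_total
    if n_total < 2:
        return GroupSummary(mean=mean, se=float("nan"), n=n_total)
    ss = 0.0
    for g in groups:
        sd = 0.0 if g.n < 2 else g.sd
        ss += (g.n - 1) * sd * sd + g.n * (g.mean - mean) ** 2
    pooled_sd = math.sqrt(ss / (n_total - 1))
    return GroupSummary(mean=mean, se=pooled_sd / math.sqrt(n_total), n=n_total)


def t_test(a: Iterable[float], b: Iterable[float], *, pooled: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch by default).

    Degenerate input (zero variance in both groups) yields ``p = 1`` when
    the means coincide and ``p = 0`` otherwise, by convention; both cases
    are logged.
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise InputError("t_test: each group needs n >= 2")
    if xa.std(ddof=1) == 0.0 and xb.std(ddof=1) == 0.0:
        p = 1.0 if xa.mean() == xb.mean() else 0.0
        log.warning("t_test: zero variance in both groups; p=%g by convention", p)
        return p
    res = sps.ttest_ind(xa, xb, equal_var=pooled)
    return float(res.pvalue)
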