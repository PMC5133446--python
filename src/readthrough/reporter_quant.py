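"""Quantification of readthrough from reporter and imaging measurements.

Dual-reporter readthrough: the test construct's luminescence/fluorescence
ratio (hRluc/Venus, blank-subtracted) is expressed as a percentage of the
mean ratio of a 100% control construct.  Western readthrough is the
densitometric fraction of the extended band; import efficiency is the
fluorescence retained after cytosol washout.  Group comparisons use the
two-sided equal-variance Student's t-test with significance at p < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ReporterMeasurement:
    """One replicate of a dual-reporter readout (arbitrary units)."""

    construct: str
    replicate: int
    venus: float
    hrluc: float
    blank_venus: float = 0.0
    blank_hrluc: float = 0.0


@dataclass(frozen=True)
class WesternPair:
    """Densitometric intensities of the readthrough (x) and main bands."""

    intensity_x: float
    intensity_0: float

    def __post_init__(self) -> None:
        if self.intensity_x < 0 or self.intensity_0 < 0:
            raise ValueError("band intensities must be non-negative")
        if self.intensity_x == 0 and self.intensity_0 == 0:
            raise ValueError("both band intensities are zero")


@dataclass(frozen=True)
class ImportPair:
    """Mean cell fluorescence before/after cytosol washout, with background."""

    pre: float
    post: float
    background: float = 0.0
    n_cells: int = 1

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.pre - self.background <= 0:
            raise ValueError("pre-wash signal must exceed background")


@dataclass(frozen=True)
class Summary:
    mean: float
    sem: float
    n: int
    values: tuple[float, ...] = ()


def _ratio(m: ReporterMeasurement) -> Optional[float]:
    venus = m.venus - m.blank_venus
    if venus <= 0:
        warnings.warn(
            f"{m.construct} replicate {m.replicate}: Venus at or below blank; dropped",
            stacklevel=3,
        )
        return None
    return (m.hrluc - m.blank_hrluc) / venus


def _ratios(measurements: Sequence[ReporterMeasurement]) -> list[float]:
    ratios = [r for m in measurements if (r := _ratio(m)) is not None]
    if not ratios:
        raise ValueError("all replicates dropped (Venus at or below blank)")
    return ratios


def readthrough_percent(
    test: Sequence[ReporterMeasurement], control100: Sequence[ReporterMeasurement]
) -> Summary:
    """Readthrough of a test construct as percent of the 100% control.

    Per replicate: 100 × (hRluc/Venus)_test divided by the mean control
    ratio (both channels blank-subtracted first).  Returns mean ± SEM over
    test replicates.
    """
    if not test or not control100:
        raise ValueError("at least one replicate required per construct")
    control_ratio = float(np.mean(_ratios(control100)))
    if control_ratio == 0:
        raise ValueError("control ratio is zero")
    percents = [100.0 * r / control_ratio for r in _ratios(test)]
    n = len(percents)
    sem = float(stats.sem(percents, ddof=1)) if n > 1 else float("nan")
    return Summary(mean=float(np.mean(percents)), sem=sem, n=n, values=tuple(percents))


def western_readthrough(pair: WesternPair) -> float:
    """Percent readthrough from band densitometry: 100·Ix/(Ix+I0)."""
    return 100.0 * pair.intensity_x / (pair.intensity_x + pair.intensity_0)


def import_efficiency(pair: ImportPair) -> float:
    """Organellar import efficiency: background-subtracted post/pre ratio.

    Clipped to [0, 1]; a post-wash signal above pre-wash (ratio > 1) is
    measurement noise and triggers a warning before clipping.
    """
    eff = (pair.post - pair.background) / (pair.pre - pair.background)
    if eff > 1.0:
        warnings.warn("post-wash signal exceeds pre-wash; efficiency clipped to 1", stacklevel=2)
        return 1.0
    return max(eff, 0.0)


def relative_efficiency_percent(e1: float, e2: float) -> float:
    """Percent difference of two efficiencies: 100·(e1/e2 − 1)."""
    if e2 == 0:
        raise ValueError("reference efficiency is zero")
    return 100.0 * (e1 / e2 - 1.0)


@dataclass(frozen=True)
class Comparison:
    t: float
    p: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    significant: bool
    fold_change: float  # mean_b / mean_a


def compare(group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05) -> Comparison:
    """Two-sample equal-variance two-sided Student's t-test.

    Degenerate case: with zero pooled variance and equal means (e.g. a
    group compared against an identical copy) the statistic is defined as
    t=0, p=1; zero variance with unequal means gives t=±inf, p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, a.mean() - b.mean())
            p_val = 0.0
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p_val = float(t_stat), float(p_val)
    return Comparison(
        t=t_stat,
        p=p_val,
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a, ddof=1)),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b, ddof=1)),
        n_a=len(a),
        n_b=len(b),
        significant=p_val < alpha,
        fold_change=float(b.mean() / a.mean()) if a.mean() != 0 else float("nan"),
    )
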