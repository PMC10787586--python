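"""Growth-rate fitting and implant-vs-control group comparisons.

The doubling interval T_d is estimated by least squares on log2(density)
versus incubation day, so that T_d = 1/slope; the standard error is
propagated from the slope error.  Group comparisons mirror the study's
statistical protocol: a Kolmogorov–Smirnov normality check per group, a
one-way ANOVA across groups when more than two are given, and a two-sided
Mann–Whitney rank test for the pairwise implant-vs-control comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GrowthFit:
    """Exponential-growth fit on the log2 scale."""

    rate_per_day: float          # slope of log2(density) vs day
    doubling_interval_days: float
    doubling_interval_se: float
    intercept: float
    residual: float
    n: int
    flags: tuple[str, ...] = ()


@dataclass
class GroupComparison:
    """Normality, global and pairwise test results with their sample sizes."""

    n: tuple[int, ...]
    normality_p: tuple[float, ...]
    normal: tuple[bool, ...]
    anova_p: float | None
    pairwise_test: str
    pairwise_p: float
    significant: bool
    alpha: float
    meta: dict = field(default_factory=dict)


def fit_doubling_interval(days: np.ndarray, densities: np.ndarray
                          ) -> GrowthFit:
    """Fit the doubling interval of a density time series.

    Least-squares line on log2(density) vs day; T_d = 1/slope.  A zero or
    negative slope yields a non-finite doubling interval with a flag.
    """
    days = np.asarray(days, dtype=float)
    dens = np.asarray(densities, dtype=float)
    if days.size != dens.size:
        raise ValueError("days and densities must have equal length")
    if days.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(dens <= 0):
        raise ValueError("densities must be positive")
    y = np.log2(dens)
    res = sps.linregress(days, y)
    slope, stderr = res.slope, res.stderr
    flags = []
    if slope > 0:
        td = 1.0 / slope
        td_se = stderr / slope ** 2 if np.isfinite(stderr) else float("nan")
    else:
        td, td_se = float("inf"), float("nan")
        flags.append("non-positive-growth")
    resid = float(np.sum((y - (res.intercept + slope * days)) ** 2))
    return GrowthFit(rate_per_day=float(slope),
                     doubling_interval_days=float(td),
                     doubling_interval_se=float(td_se),
                     intercept=float(res.intercept), residual=resid,
                     n=days.size, flags=tuple(flags))


def relative_increase(days: np.ndarray,
                      implant_densities: np.ndarray,
                      control_densities: np.ndarray
                      ) -> tuple[np.ndarray, GrowthFit]:
    """Per-day implant/control density ratio and its doubling fit."""
    implant = np.asarray(implant_densities, dtype=float)
    control = np.asarray(control_densities, dtype=float)
    if implant.shape != control.shape:
        raise ValueError("implant and control series must match")
    if np.any(control == 0):
        raise ValueError("control density of zero makes the ratio undefined")
    ratios = implant / control
    return ratios, fit_doubling_interval(days, ratios)


def compare_groups(sample_a: np.ndarray, sample_b: np.ndarray,
                   alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison: per-group normality, rank test, significance.

    Normality is a Kolmogorov–Smirnov test against a Gaussian with the
    sample's own mean and sd; the pairwise test is the two-sided
    Mann–Whitney U.  Each group needs n >= 3.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    norm_p = []
    for s in (a, b):
        sd = s.std(ddof=1)
        if sd == 0:
            norm_p.append(0.0)
        else:
            norm_p.append(float(sps.kstest((s - s.mean()) / sd, "norm").pvalue))
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        mw_p = 1.0
    else:
        mw_p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    anova_p = float(sps.f_oneway(a, b).pvalue) \
        if a.std() > 0 or b.std() > 0 else 1.0
    return GroupComparison(
        n=(a.size, b.size),
        normality_p=tuple(norm_p),
        normal=tuple(p > alpha for p in norm_p),
        anova_p=anova_p,
        pairwise_test="mann-whitney-u",
        pairwise_p=mw_p,
        significant=bool(mw_p < alpha),
        alpha=alpha,
        meta={"normality_test": "kolmogorov-smirnov"})


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
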