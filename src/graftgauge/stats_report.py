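"""Summary statistics, correlations and linear fits for cohort reports.

Thin, validated wrappers around scipy.stats: mean ± SEM summaries, Pearson
and Spearman correlations with two-sided p-values, and ordinary
least-squares fits with coefficient standard errors (n−2 degrees of
freedom). The significance threshold (0.05 by default) is reported, never
used to filter data; no multiple-testing correction is applied unless
requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StatsError",
    "PairedSample",
    "CorrelationResult",
    "LinearFitResult",
    "mean_sem",
    "pearson",
    "spearman",
    "linear_fit",
    "adjust_pvalues",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSample:
    """Two paired numeric vectors, e.g. a geometry ratio vs a WSS ratio."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise StatsError("x and y must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise StatsError("sample contains non-finite values")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    p_slope: float
    p_intercept: float
    r_value: float
    n: int


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD / sqrt(n), ddof=1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise StatsError("mean_sem requires at least 2 values")
    if not np.all(np.isfinite(values)):
        raise StatsError("values must be finite")
    return float(values.mean()), float(stats.sem(values, ddof=1))


def _check_correlatable(sample: PairedSample) -> None:
    if len(sample) < 3:
        raise StatsError("correlation requires at least 3 pairs")
    if np.ptp(sample.x) == 0 or np.ptp(sample.y) == 0:
        raise StatsError("correlation undefined for zero-variance input")


def pearson(sample: PairedSample) -> CorrelationResult:
    """Product-moment correlation; two-sided p via the t transform (n−2 df)."""
    _check_correlatable(sample)
    res = stats.pearsonr(sample.x, sample.y)
    return CorrelationResult(
        rho=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(sample),
        method="pearson",
    )


def spearman(sample: PairedSample) -> CorrelationResult:
    """Rank correlation with mid-rank (average) tie handling."""
    _check_correlatable(sample)
    res = stats.spearmanr(sample.x, sample.y)
    return CorrelationResult(
        rho=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(sample),
        method="spearman",
    )


def linear_fit(sample: PairedSample) -> LinearFitResult:
    """Ordinary least squares y = slope*x + intercept with standard errors."""
    if len(sample) < 3:
        raise StatsError("linear fit requires at least 3 pairs")
    if np.ptp(sample.x) == 0:
        raise StatsError("linear fit undefined for constant x")
    res = stats.linregress(sample.x, sample.y)
    n = len(sample)
    dof = n - 2
    if res.intercept_stderr > 0:
        t_int = res.intercept / res.intercept_stderr
        p_int = 2.0 * stats.t.sf(abs(t_int), dof)
    else:
        p_int = 0.0 if res.intercept != 0 else 1.0
    return LinearFitResult(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        p_slope=float(res.pvalue),
        p_intercept=float(p_int),
        r_value=float(res.rvalue),
        n=n,
    )


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Optional Benjamini–Hochberg adjustment (off by default everywhere)."""
    if method != "bh":
        raise StatsError(f"unknown adjustment method {method!r}")
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))
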