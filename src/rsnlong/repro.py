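"""Reproducibility statistics: coefficient of variation, equal-variance
F-tests between datasets, and multiple-comparison correction.

A longitudinal single-subject study has no subject 'class', so test-retest
reliability is summarized by the coefficient of variation of each weekly
outcome measure, and compared against a reference multi-session dataset with
a variance-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import InvalidArgumentError, UndefinedStatisticError


@dataclass
class CVResult:
    mean: float
    sd: float
    cv: float  # percent
    near_zero_mean: bool  # CV may be artificially inflated


@dataclass
class VarianceTestResult:
    F: float
    p: float
    df: tuple[int, int]
    q: float | None = None
    direction: str = "n.s."  # set after correction


def cv(series: np.ndarray, ddof: int = 1) -> CVResult:
    """Coefficient of variation, 100*SD/mean (sample SD, n-1 denominator).

    Flags near-zero means (|mean| < 2*SD), where the CV is artificially
    inflated and the SD should be read alongside it.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=ddof))
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return CVResult(
        mean=mean, sd=sd, cv=100.0 * sd / mean, near_zero_mean=abs(mean) < 2 * sd
    )


def variance_ratio_test(x: np.ndarray, y: np.ndarray) -> VarianceTestResult:
    """Two-sided equal-variance F-test: F = var(x)/var(y), df (n_x-1, n_y-1)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise InvalidArgumentError("both series need length >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise UndefinedStatisticError("zero variance: F-test undefined")
    dfx, dfy = x.size - 1, y.size - 1
    f = vx / vy
    cdf = stats.f.cdf(f, dfx, dfy)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return VarianceTestResult(F=float(f), p=p, df=(dfx, dfy))


def adjust_pvalues(p: list[float] | np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up FDR or Bonferroni adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    return multipletests(p, method=method)[1]


def compare_reproducibility(
    longitudinal: np.ndarray,
    reference: np.ndarray,
    alpha: float = 0.05,
    method: str = "bonferroni",
    n_tests: int = 1,
) -> VarianceTestResult:
    """F-test with a direction verdict after multiplicity correction.

    Direction is 'longitudinal-more-reproducible' when the longitudinal
    series has significantly smaller variance than the reference,
    'longitudinal-less-reproducible' for the opposite, 'n.s.' otherwise.
    ``n_tests`` is the size of the correction family (e.g. 14 networks).
    """
    res = variance_ratio_test(longitudinal, reference)
    q = float(min(1.0, res.p * n_tests)) if method == "bonferroni" else res.p
    res.q = q
    if q < alpha:
        res.direction = (
            "longitudinal-more-reproducible"
            if res.F < 1
            else "longitudinal-less-reproducible"
        )
    return res
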