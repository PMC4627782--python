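"""Temporal structure of weekly outcome series on an irregular calendar:
linear trend, annual periodicity, seasonal-covariate correlation, and
ARMA persistence.

All estimators operate on the observed weeks only; missed weeks are gaps in
the week index, never zero-filled or imputed. The spectral estimator
regresses the observed samples on sine/cosine pairs frequency by frequency,
so it tolerates non-uniform sampling where the plain periodogram does not,
and reduces exactly to the periodogram (up to scale) when no week is
missing. Periodicity is tested with Fisher's exact g-test on the spectral
shares; persistence with an ARMA(p, q) model whose MA part is derived from
a long autoregression (Durbin's reduced-statistics method), which again
only needs lagged products of observed samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.tsa.arima_process import arma_acovf

from .core import (
    EstimationError,
    InvalidArgumentError,
    OutcomeSeries,
)
from .synthetic import ANNUAL_PERIOD_WEEKS, DEFAULT_START_DATE, week_dates

#: Annual frequency in weeks^-1 (1/52.18), the default periodicity target.
ANNUAL_FREQUENCY = 1.0 / ANNUAL_PERIOD_WEEKS


# ---------------------------------------------------------------------------
# linear trend

@dataclass
class TrendResult:
    intercept: float
    slope: float
    F: float
    p: float
    n: int
    se_slope: float
    q: float | None = None


def fit_linear_trend(series: OutcomeSeries) -> TrendResult:
    """OLS of the outcome on the calendar week index, F-test for the slope.

    The regressor is the acquisition week (t = 0 at the first session), so
    missed weeks stretch the gaps between consecutive samples. The slope's
    F statistic is referred to F(1, n-2).
    """
    t = series.weeks.astype(float)
    y = series.values
    n = y.size
    if n < 3:
        raise InvalidArgumentError("need at least 3 observed weeks")
    if np.all(t == t[0]):
        raise InvalidArgumentError("degenerate calendar: all weeks identical")
    if np.ptp(y) == 0:
        return TrendResult(
            intercept=float(y[0]), slope=0.0, F=0.0, p=1.0, n=n, se_slope=0.0
        )
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    slope = float(np.sum(tc * y) / sxx)
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    rss = float(np.sum(resid**2))
    if rss == 0:
        f_stat = np.inf if slope != 0 else 0.0
        se = 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        s2 = rss / (n - 2)
        se = float(np.sqrt(s2 / sxx))
        f_stat = (slope / se) ** 2
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return TrendResult(
        intercept=intercept, slope=slope, F=float(f_stat), p=p, n=n, se_slope=se
    )


def _batch_slope_t(weeks: np.ndarray, values: np.ndarray) -> np.ndarray:
    """|t statistic of the OLS slope| for each row of ``values``."""
    t = weeks.astype(float)
    n = t.size
    tc = t - t.mean()
    sxx = np.sum(tc**2)
    y = np.atleast_2d(values)
    yc = y - y.mean(axis=1, keepdims=True)
    slope = yc @ tc / sxx
    rss = np.sum(yc**2, axis=1) - slope**2 * sxx
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (n - 2) / sxx)
        tval = np.where(se > 0, np.abs(slope) / se, np.where(slope == 0, 0.0, np.inf))
    return tval


def trend_statistic(weeks: np.ndarray, values: np.ndarray) -> float:
    """Permutation statistic for trend: absolute slope t statistic."""
    return float(_batch_slope_t(weeks, values)[0])


# ---------------------------------------------------------------------------
# permutation tests

def permutation_null(
    series: OutcomeSeries,
    statistic_fn,
    n_iter: int = 1000,
    seed: int = 0,
    batch_statistic_fn=None,
) -> float:
    """One-sided permutation p-value with the add-one estimator.

    Values are permuted across the observed weeks; ``statistic_fn(weeks,
    values)`` returns a scalar (larger = more extreme). p = (1 + #{permuted
    >= observed}) / (1 + n_iter). A vectorized ``batch_statistic_fn(weeks,
    values_matrix)`` may be supplied to evaluate all permutations at once.
    """
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    y = series.values
    if y.size < 3:
        raise InvalidArgumentError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn(series.weeks, y))
    perms = np.array([rng.permutation(y) for _ in range(n_iter)])
    if batch_statistic_fn is not None:
        stats_perm = np.asarray(batch_statistic_fn(series.weeks, perms), dtype=float)
    else:
        stats_perm = np.array(
            [float(statistic_fn(series.weeks, row)) for row in perms]
        )
    return float((1 + np.sum(stats_perm >= observed)) / (1 + n_iter))


# ---------------------------------------------------------------------------
# robust spectral estimation + Fisher's g-test

@dataclass
class SpectrumResult:
    frequencies: np.ndarray  # weeks^-1, Fourier grid of the full span
    power: np.ndarray
    flat: bool = False  # constant input: spectrum carries no information

    def argmax_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.power))])


def fourier_grid(total_weeks: int) -> np.ndarray:
    """Positive Fourier frequencies of the full study span, Δf = 1/total_weeks."""
    n_bins = (total_weeks - 1) // 2
    return np.arange(1, n_bins + 1) / float(total_weeks)


def _spectrum_projectors(weeks: np.ndarray, total_weeks: int) -> list[np.ndarray]:
    freqs = fourier_grid(total_weeks)
    t = weeks.astype(float)
    projectors = []
    for f in freqs:
        d = np.column_stack(
            [np.ones_like(t), np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]
        )
        projectors.append(np.linalg.pinv(d))
    return projectors


def robust_spectrum(series: OutcomeSeries, rank_transform: bool = False) -> SpectrumResult:
    """Regression-based spectral estimate on the full-span Fourier grid.

    For each grid frequency, the observed samples are regressed (least
    squares, with intercept) on a cosine/sine pair evaluated at the observed
    week indices; the power is (n/4)(beta_c^2 + beta_s^2). With no missing
    weeks this equals the classical periodogram. ``rank_transform`` replaces
    the values by their ranks first, for outlier robustness.
    """
    y = series.values.astype(float)
    n = y.size
    if n < 8:
        raise InvalidArgumentError("need at least 8 observed weeks")
    if np.all(y == y[0]):
        freqs = fourier_grid(series.calendar.total_weeks)
        return SpectrumResult(frequencies=freqs, power=np.zeros_like(freqs), flat=True)
    if rank_transform:
        y = stats.rankdata(y).astype(float)
    projectors = _spectrum_projectors(series.weeks, series.calendar.total_weeks)
    power = np.empty(len(projectors))
    for i, p in enumerate(projectors):
        beta = p @ y
        power[i] = n / 4.0 * (beta[1] ** 2 + beta[2] ** 2)
    return SpectrumResult(
        frequencies=fourier_grid(series.calendar.total_weeks), power=power
    )


def spectrum_batch(
    weeks: np.ndarray, total_weeks: int, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spectra of many series sharing one calendar (rows of ``values``)."""
    y = np.atleast_2d(values).astype(float)
    n = y.shape[1]
    projectors = _spectrum_projectors(np.asarray(weeks), total_weeks)
    power = np.empty((y.shape[0], len(projectors)))
    for i, p in enumerate(projectors):
        beta = p @ y.T  # 3 x R
        power[:, i] = n / 4.0 * (beta[1] ** 2 + beta[2] ** 2)
    return fourier_grid(total_weeks), power


def fisher_g_pvalue(g: float, m: int) -> float:
    """Exact null P(max periodogram share > g) among m white-noise bins.

    Truncated alternating sum: sum_{j=1}^{floor(1/g)} (-1)^{j-1} C(m, j)
    (1 - j g)^{m-1}.
    """
    if not 0 <= g <= 1:
        raise InvalidArgumentError("g must lie in [0, 1]")
    if m < 1:
        raise InvalidArgumentError("need m >= 1 bins")
    if g == 0:
        return 1.0
    jmax = min(m, int(np.floor(1.0 / g)))
    total = 0.0
    for j in range(1, jmax + 1):
        if 1.0 - j * g <= 0:
            break
        log_term = (
            gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)
            + (m - 1) * np.log1p(-j * g)
        )
        total += (-1.0) ** (j - 1) * np.exp(log_term)
    return float(np.clip(total, 0.0, 1.0))


@dataclass
class PeriodicityResult:
    frequencies: np.ndarray
    power: np.ndarray
    target_frequency: float  # as requested
    snapped_frequency: float  # nearest grid frequency actually evaluated
    g_statistic: float  # spectral share at the snapped target bin
    g_max: float  # largest spectral share (the tested statistic)
    argmax_frequency: float
    peak_at_target: bool  # spectral argmax sits on the target bin
    p: float  # exact Fisher g-test p-value (white-noise null)
    q: float | None = None

    @property
    def detected(self) -> bool:
        """Periodicity at the target: significant g-test AND peak on target."""
        crit = self.q if self.q is not None else self.p
        return bool(crit < 0.05 and self.peak_at_target)


def fisher_g_test(
    spectrum: SpectrumResult, target_frequency: float = ANNUAL_FREQUENCY
) -> PeriodicityResult:
    """Fisher's exact g-test for a periodic component, localized to a target.

    The test statistic is the maximal spectral share (classical Fisher g),
    whose exact white-noise null is the truncated-sum formula — this keeps
    the test exactly calibrated. The share at the (grid-snapped) target
    frequency is reported as ``g_statistic``, and a detection at the target
    additionally requires the spectral peak to fall on the target bin.
    """
    power = spectrum.power
    m = power.size
    if m < 3:
        raise InvalidArgumentError("need a spectrum with at least 3 bins")
    total = float(power.sum())
    idx = int(np.argmin(np.abs(spectrum.frequencies - target_frequency)))
    snapped = float(spectrum.frequencies[idx])
    if spectrum.flat or total == 0:
        return PeriodicityResult(
            frequencies=spectrum.frequencies,
            power=power,
            target_frequency=target_frequency,
            snapped_frequency=snapped,
            g_statistic=1.0 / m,
            g_max=1.0 / m,
            argmax_frequency=snapped,
            peak_at_target=False,
            p=1.0,
        )
    shares = power / total
    g_target = float(shares[idx])
    imax = int(np.argmax(shares))
    g_max = float(shares[imax])
    # an off-grid target sits between two bins and leaks into both, so the
    # peak counts as on-target anywhere within one grid step of it
    df = float(spectrum.frequencies[1] - spectrum.frequencies[0])
    on_target = abs(float(spectrum.frequencies[imax]) - target_frequency) <= df
    return PeriodicityResult(
        frequencies=spectrum.frequencies,
        power=power,
        target_frequency=target_frequency,
        snapped_frequency=snapped,
        g_statistic=g_target,
        g_max=g_max,
        argmax_frequency=float(spectrum.frequencies[imax]),
        peak_at_target=on_target,
        p=fisher_g_pvalue(g_max, m),
    )


# ---------------------------------------------------------------------------
# seasonal covariate

@dataclass
class CovariateResult:
    r: float
    p_perm: float
    n_pairs: int


def correlate_covariate(
    series: OutcomeSeries,
    covariate: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    start: date = DEFAULT_START_DATE,
) -> CovariateResult:
    """Pearson correlation with a dated daily covariate, permutation p-value.

    Each observed week is matched to the covariate value of the nearest day;
    the permutation statistic is |r| (two-sided).
    """
    if not isinstance(covariate.index, pd.DatetimeIndex):
        raise InvalidArgumentError("covariate must be indexed by dates")
    dates = pd.to_datetime(week_dates(series.calendar, start=start))
    cov_sorted = covariate.sort_index()
    idx = cov_sorted.index.get_indexer(dates, method="nearest")
    matchable = idx >= 0
    if int(matchable.sum()) < 3:
        raise InvalidArgumentError("fewer than 3 date-matched pairs")
    x = series.values[matchable]
    c = cov_sorted.to_numpy()[idx[matchable]]
    if x.std() == 0 or c.std() == 0:
        raise InvalidArgumentError("constant series: correlation undefined")
    r = float(np.corrcoef(x, c)[0, 1])
    rng = np.random.default_rng(seed)
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    xc = (x - x.mean()) / x.std()
    cc = (c - c.mean()) / c.std()
    perms = np.array([rng.permutation(xc) for _ in range(n_perm)])
    r_perm = np.abs(perms @ cc / x.size)
    p = float((1 + np.sum(r_perm >= abs(r))) / (1 + n_perm))
    return CovariateResult(r=r, p_perm=p, n_pairs=int(x.size))


# ---------------------------------------------------------------------------
# ARMA persistence

@dataclass
class ARMAModel:
    """ARMA(p, q) persistence model in the sign convention
    ``y_t + a1 y_{t-1} + a2 y_{t-2} + a3 y_{t-3} = e_t + c1 e_{t-1} + c2 e_{t-2} + c3 e_{t-3}``.
    """

    ar_order: int
    ma_order: int
    ar_coeffs: np.ndarray  # a_1..a_p
    ma_coeffs: np.ndarray  # c_1..c_q
    sigma2: float
    criterion: float  # BIC of the selected model
    candidates: dict = field(default_factory=dict)  # (p, q) -> BIC

    @property
    def has_persistence(self) -> bool:
        return self.ar_order > 0 or self.ma_order > 0


def _pairwise_autocovariance(
    weeks: np.ndarray, values: np.ndarray, max_lag: int, min_pairs: int = 5
) -> np.ndarray:
    """Autocovariance at integer week lags from observed index pairs only."""
    x = values - values.mean()
    pos = {int(w): i for i, w in enumerate(weeks)}
    gamma = np.zeros(max_lag + 1)
    gamma[0] = float(np.mean(x**2))
    for k in range(1, max_lag + 1):
        prods = [
            x[i] * x[pos[int(w) + k]] for w, i in pos.items() if int(w) + k in pos
        ]
        if len(prods) < min_pairs:
            return gamma[:k]
        gamma[k] = float(np.mean(prods))
    return gamma


def _psd_project(gamma: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Project an autocovariance sequence onto the positive-definite cone.

    Pairwise-lag estimates from gappy sampling need not be a valid
    autocovariance; clipping their spectral density at a small positive
    floor (on a fine frequency grid) restores validity while barely moving
    the low lags that carry the signal.
    """
    L = gamma.size - 1
    n_grid = max(8 * (L + 1), 64)
    seq = np.zeros(n_grid)
    seq[0] = gamma[0]
    seq[1 : L + 1] = gamma[1:]
    seq[-L:] = gamma[1:][::-1]
    spec = np.real(np.fft.fft(seq))
    floor = floor_frac * max(np.mean(np.abs(spec)), 1e-300)
    spec = np.clip(spec, floor, None)
    fixed = np.real(np.fft.ifft(spec))[: L + 1]
    if fixed[0] > 0:
        fixed *= gamma[0] / fixed[0]  # preserve the variance
    return fixed


def _levinson(gamma: np.ndarray, order: int) -> np.ndarray:
    """Levinson–Durbin AR coefficients phi (x_t = sum phi_i x_{t-i} + e).

    Reflection coefficients are clamped to (-0.998, 0.998) so that a
    slightly non-positive-definite pairwise autocovariance still yields a
    stationary long AR model.
    """
    phi = np.zeros(order)
    prev = np.zeros(order)
    err = gamma[0]
    for k in range(1, order + 1):
        acc = gamma[k] - np.dot(prev[: k - 1], gamma[k - 1 : 0 : -1])
        kappa = float(np.clip(acc / err, -0.998, 0.998)) if err > 0 else 0.0
        phi[: k - 1] = prev[: k - 1] - kappa * prev[: k - 1][::-1]
        phi[k - 1] = kappa
        err = err * (1 - kappa**2)
        prev[:k] = phi[:k]
    return phi


def _durbin_ma(alpha: np.ndarray, p: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """ARMA(p, q) from a long AR polynomial A(z) = 1 + alpha_1 z + ...

    Solves conv(c, A)_k = 0 for k in p+1..L (least squares) for the MA
    polynomial c, then reads off a_k = conv(c, A)_k for k <= p.
    """
    big_a = np.r_[1.0, alpha]  # A_0..A_L
    L = alpha.size
    m = np.zeros((max(L - p, 0), q))
    rhs = np.zeros(m.shape[0])
    for r, k in enumerate(range(p + 1, L + 1)):
        rhs[r] = -big_a[k]
        for j in range(1, q + 1):
            if 0 <= k - j <= L:
                m[r, j - 1] = big_a[k - j]
    if m.shape[0] < q:
        raise EstimationError("long AR order too small for requested MA order")
    c, *_ = np.linalg.lstsq(m, rhs, rcond=None)
    a = np.array(
        [
            big_a[k] + sum(c[j - 1] * big_a[k - j] for j in range(1, q + 1) if k - j >= 0)
            for k in range(1, p + 1)
        ]
    )
    return a, c


def _poly_ok(coeffs: np.ndarray) -> bool:
    """Roots of 1 + c1 z + ... outside the unit circle (with small margin)."""
    if coeffs.size == 0:
        return True
    roots = np.roots(np.r_[1.0, coeffs][::-1])
    return bool(np.all(np.abs(roots) > 1.001))


def _gaussian_loglik(
    weeks: np.ndarray,
    x: np.ndarray,
    a: np.ndarray,
    c: np.ndarray,
    lagmat: np.ndarray | None = None,
) -> tuple[float, float]:
    """Exact Gaussian log-likelihood of irregularly observed ARMA samples.

    Builds the model autocovariance at the observed week separations and
    profiles out the innovation variance. Returns (loglik, sigma2_hat).
    """
    from scipy.linalg import cholesky as _chol, solve_triangular

    n = x.size
    if lagmat is None:
        lagmat = np.abs(weeks[:, None] - weeks[None, :])
    max_lag = int(lagmat.max())
    acov = arma_acovf(np.r_[1.0, a], np.r_[1.0, c], nobs=max_lag + 1, sigma2=1.0)
    r = acov[lagmat] + 1e-10 * acov[0] * np.eye(n)
    try:
        ch = _chol(r, lower=True, check_finite=False)
    except Exception as exc:
        raise EstimationError("model covariance not positive definite") from exc
    z = solve_triangular(ch, x, lower=True, check_finite=False)
    quad = float(z @ z)
    logdet = 2.0 * float(np.sum(np.log(np.diag(ch))))
    sigma2 = quad / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, sigma2


def _shrink_to_valid(coeffs: np.ndarray) -> np.ndarray | None:
    """Shrink a coefficient vector toward 0 until its polynomial is valid."""
    if _poly_ok(coeffs):
        return coeffs
    for f in (0.8, 0.6, 0.4, 0.2):
        if _poly_ok(coeffs * f):
            return coeffs * f
    return None


def _refine_candidate(
    weeks: np.ndarray,
    x: np.ndarray,
    lagmat: np.ndarray,
    p: int,
    q: int,
    a0: np.ndarray,
    c0: np.ndarray,
    maxfev: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Polish Durbin starting values by exact-likelihood ascent (Nelder–Mead)."""
    from scipy.optimize import minimize

    def nll(theta: np.ndarray) -> float:
        a, c = theta[:p], theta[p:]
        if not (_poly_ok(a) and _poly_ok(c)):
            return 1e10
        try:
            ll, _ = _gaussian_loglik(weeks, x, a, c, lagmat)
        except EstimationError:
            return 1e10
        return -ll

    res = minimize(
        nll,
        np.r_[a0, c0],
        method="Nelder-Mead",
        options=dict(maxfev=maxfev, xatol=tol, fatol=tol),
    )
    if res.fun < 1e9:
        return res.x[:p].copy(), res.x[p:].copy()
    return a0, c0


def deseasonalize(series: OutcomeSeries, period: float = ANNUAL_PERIOD_WEEKS) -> np.ndarray:
    """Residuals after regressing out intercept, line, and annual sine/cosine."""
    t = series.weeks.astype(float)
    d = np.column_stack(
        [
            np.ones_like(t),
            t,
            np.sin(2 * np.pi * t / period),
            np.cos(2 * np.pi * t / period),
        ]
    )
    beta, *_ = np.linalg.lstsq(d, series.values, rcond=None)
    return series.values - d @ beta


def fit_arma(
    series: OutcomeSeries,
    max_p: int = 3,
    max_q: int = 3,
    detrend: bool = True,
    long_ar_order: int | None = None,
    min_n: int = 30,
    refine: bool = True,
) -> ARMAModel:
    """Fit an ARMA(p, q) persistence model to an irregular weekly series.

    Steps: (1) remove line + annual sinusoid (``detrend=True``); (2) long AR
    via Levinson–Durbin on the pairwise-lag autocovariance, which uses only
    observed index pairs at each lag; (3) for each candidate (p, q) up to
    (max_p, max_q), derive coefficients from the long AR by Durbin's
    reduced-statistics method; (4) polish each candidate by exact Gaussian
    likelihood ascent (``refine=True``; a cheap pass for all candidates,
    then a thorough pass for the leading ones — Durbin values are the
    starting point, so AR and mixed candidates compete on equal, near-ML
    footing); (5) select the candidate minimizing the BIC computed from the
    exact Gaussian likelihood of the observed samples under the candidate's
    autocovariance. Only stationary/invertible candidates compete; white
    noise (0, 0) is always admissible.
    """
    if not (0 <= max_p <= 3 and 0 <= max_q <= 3):
        raise InvalidArgumentError("max_p and max_q must be in 0..3")
    n = series.values.size
    if n < min_n:
        raise EstimationError(f"need at least {min_n} observed weeks, got {n}")
    x = deseasonalize(series) if detrend else series.values - series.values.mean()
    if np.all(x == 0):
        raise EstimationError("degenerate series: no residual variance")
    if long_ar_order is None:
        long_ar_order = int(min(15, n // 5))
    long_ar_order = max(long_ar_order, max_p + max_q + 1)
    gamma = _pairwise_autocovariance(series.weeks, x, long_ar_order)
    if gamma.size - 1 < max_p + max_q + 1:
        raise EstimationError("too few overlapping lag pairs for estimation")
    gamma = _psd_project(gamma)
    L = gamma.size - 1
    phi_long = _levinson(gamma, L)
    alpha = -phi_long  # A(z) = 1 + alpha_1 z + ... (residual-whitening polynomial)
    weeks = series.weeks
    lagmat = np.abs(weeks[:, None] - weeks[None, :])

    fits: dict[tuple[int, int], tuple[float, np.ndarray, np.ndarray, float]] = {}
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            if p == 0 and q == 0:
                a = np.empty(0)
                c = np.empty(0)
            elif q == 0:
                a = -_levinson(gamma, p)
                c = np.empty(0)
            else:
                try:
                    a, c = _durbin_ma(alpha, p, q)
                except EstimationError:
                    continue
            a = _shrink_to_valid(a)
            c = _shrink_to_valid(c) if c is not None else None
            if a is None or c is None:
                continue
            if refine and p + q > 0:
                a, c = _refine_candidate(
                    weeks, x, lagmat, p, q, a, c, maxfev=40 * (p + q), tol=5e-3
                )
            try:
                ll, sigma2 = _gaussian_loglik(weeks, x, a, c, lagmat)
            except EstimationError:
                continue
            bic = -2.0 * ll + (p + q + 1) * np.log(n)
            fits[(p, q)] = (float(bic), a, c, sigma2)

    if not fits:
        raise EstimationError("no stationary/invertible ARMA candidate")

    if refine:
        # thorough pass for the leading candidates so close calls are decided
        # at (near-)ML fits rather than at partially polished ones
        leaders = sorted(fits, key=lambda k: fits[k][0])[:4]
        for p, q in leaders:
            if p + q == 0:
                continue
            _, a, c, _ = fits[(p, q)]
            a, c = _refine_candidate(
                weeks, x, lagmat, p, q, a, c, maxfev=300 * (p + q), tol=1e-5
            )
            try:
                ll, sigma2 = _gaussian_loglik(weeks, x, a, c, lagmat)
            except EstimationError:
                continue
            bic = -2.0 * ll + (p + q + 1) * np.log(n)
            if bic < fits[(p, q)][0]:
                fits[(p, q)] = (float(bic), a, c, sigma2)

    (p, q), (bic, a, c, sigma2) = min(fits.items(), key=lambda kv: kv[1][0])
    return ARMAModel(
        ar_order=p,
        ma_order=q,
        ar_coeffs=a,
        ma_coeffs=c,
        sigma2=sigma2,
        criterion=bic,
        candidates={k: v[0] for k, v in fits.items()},
    )
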