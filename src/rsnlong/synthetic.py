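"""Synthetic study generator with full ground-truth bookkeeping.

Emulates the structure of a weekly single-subject resting-state fMRI study:
a multi-year weekly calendar with missed sessions (default 158 observed of
185 weeks), small 4D echo-planar-like volumes built from known compact
spatial sources mixed by known time courses, realignment-parameter tables,
a phantom (scanner-stability) intensity series, and a daily seasonal
covariate (e.g. maximum temperature). Weekly outcome-measure series carry a
configurable linear trend, an annual sinusoid (period 52.18 weeks) and
ARMA(p,q) noise, so every temporal-structure estimator downstream can be
checked against known truth.

Not modelled (deliberately): hemodynamics, physiological noise, scanner
artifacts — see the methods note.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .core import InvalidArgumentError, OutcomeSeries, SessionCalendar

#: Mean tropical-year length in weeks; the annual frequency is 1/52.18 wk^-1.
ANNUAL_PERIOD_WEEKS = 52.18

#: Nominal first-session date used to attach ISO dates to week indices.
DEFAULT_START_DATE = date(2007, 1, 3)

ARMA_BURN_IN = 500  # recursion warm-up samples discarded before week 0


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one weekly outcome series.

    The deterministic part is ``intercept + slope*t +
    annual_amplitude*sin(2*pi*t/annual_period + annual_phase)`` with t in
    weeks. AR/MA coefficients follow the convention
    ``y_t + a1*y_{t-1} + ... = e_t + c1*e_{t-1} + ...`` (the sign convention
    used for reported persistence models), so ``ar_coeffs=(-0.5,)`` is a
    positively autocorrelated AR(1).
    """

    intercept: float = 0.0
    slope: float = 0.0
    annual_amplitude: float = 0.0
    annual_phase: float = 0.0
    annual_period: float = ANNUAL_PERIOD_WEEKS
    ar_coeffs: tuple[float, ...] = ()
    ma_coeffs: tuple[float, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_period <= 0:
            raise InvalidArgumentError("annual_period must be > 0")
        if len(self.ar_coeffs) > 3 or len(self.ma_coeffs) > 3:
            raise InvalidArgumentError("AR/MA orders above 3 are not supported")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.ar_coeffs and not _is_stationary(self.ar_coeffs):
            raise InvalidArgumentError(
                "AR polynomial has roots inside the unit circle (non-stationary)"
            )

    def mean_function(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.intercept
            + self.slope * t
            + self.annual_amplitude
            * np.sin(2 * np.pi * t / self.annual_period + self.annual_phase)
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _is_stationary(ar_coeffs: tuple[float, ...]) -> bool:
    # roots of 1 + a1 z + a2 z^2 + ... must lie outside the unit circle
    poly = np.r_[1.0, ar_coeffs]
    roots = np.roots(poly[::-1])  # np.roots wants highest degree first
    return bool(roots.size == 0 or np.all(np.abs(roots) > 1.0))


@dataclass
class SyntheticStudy:
    """A complete generated study with its ground truth."""

    calendar: SessionCalendar
    sessions: list[np.ndarray]  # 4D (x, y, z, t) volumes
    mask: np.ndarray  # boolean (x, y, z)
    true_sources: np.ndarray  # n_sources x n_voxels (in-mask)
    true_timecourses: list[np.ndarray]  # per session, n_sources x n_frames
    motion_params: list[np.ndarray] = field(default_factory=list)
    phantom_series: OutcomeSeries | None = None
    covariate_series: pd.Series | None = None
    baseline: float = 1000.0

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise InvalidArgumentError("mask is empty")
        for s in self.sessions:
            if not np.all(np.isfinite(s)):
                raise InvalidArgumentError("session volumes must be finite")


def week_dates(calendar: SessionCalendar, start: date = DEFAULT_START_DATE) -> list[date]:
    """ISO dates of the observed weeks (one scan per week, 7-day spacing)."""
    return [start + timedelta(weeks=int(t)) for t in calendar.observed_weeks]


def make_calendar(total_weeks: int, n_observed: int, seed: int = 0) -> SessionCalendar:
    """Draw a weekly calendar with ``n_observed`` of ``total_weeks`` weeks scanned.

    Missing weeks are exchangeable (uniform random without replacement);
    the first and last weeks are always observed when ``n_observed >= 2`` so
    the calendar spans the full study period.
    """
    if not 1 <= n_observed <= total_weeks:
        raise InvalidArgumentError(
            f"n_observed must be in [1, {total_weeks}], got {n_observed}"
        )
    rng = np.random.default_rng(seed)
    if n_observed == total_weeks:
        observed = np.arange(total_weeks)
    elif n_observed == 1:
        observed = np.array([int(rng.integers(total_weeks))])
    else:
        interior = rng.choice(
            np.arange(1, total_weeks - 1), size=n_observed - 2, replace=False
        )
        observed = np.sort(np.r_[0, interior, total_weeks - 1])
    return SessionCalendar(total_weeks=total_weeks, observed_weeks=observed)


def arma_noise(
    n: int,
    ar_coeffs: tuple[float, ...],
    ma_coeffs: tuple[float, ...],
    noise_sd: float,
    rng: np.random.Generator,
    burn_in: int = ARMA_BURN_IN,
) -> np.ndarray:
    """Direct-recursion ARMA sample in the ``y_t + a1 y_{t-1} ... = e_t + c1 e_{t-1} ...``
    convention, with a burn-in to reach the stationary distribution."""
    if ar_coeffs and not _is_stationary(tuple(ar_coeffs)):
        raise InvalidArgumentError("non-stationary AR coefficients")
    p, q = len(ar_coeffs), len(ma_coeffs)
    total = n + burn_in
    e = rng.normal(0.0, noise_sd, size=total)
    y = np.zeros(total)
    for t in range(total):
        acc = e[t]
        for j in range(q):
            if t - 1 - j >= 0:
                acc += ma_coeffs[j] * e[t - 1 - j]
        for i in range(p):
            if t - 1 - i >= 0:
                acc -= ar_coeffs[i] * y[t - 1 - i]
        y[t] = acc
    return y[burn_in:]


def simulate_outcome_series(
    calendar: SessionCalendar,
    truth: GroundTruth,
    measure_kind: str = "generic",
    network: str | None = None,
) -> OutcomeSeries:
    """Weekly outcome series = trend + annual sinusoid + ARMA noise, at observed weeks."""
    rng = np.random.default_rng(truth.seed)
    noise_full = arma_noise(
        calendar.total_weeks, truth.ar_coeffs, truth.ma_coeffs, truth.noise_sd, rng
    )
    t_obs = calendar.observed_weeks
    values = truth.mean_function(t_obs) + noise_full[t_obs]
    return OutcomeSeries(
        calendar=calendar,
        values=values,
        measure_kind=measure_kind,
        network=network,
        ground_truth=truth,
    )


def _blob_sources(n_sources: int, dims: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Compact Gaussian blobs at well-separated centres; rows ~ unit RMS.

    Voxels are indexed x-fastest (Fortran order), matching the flattening
    convention of the analysis chain.
    """
    nx, ny, nz = dims
    v = np.arange(nx * ny * nz)
    grid = np.column_stack([v % nx, (v // nx) % ny, v // (nx * ny)]).astype(float)
    sources = np.zeros((n_sources, grid.shape[0]))
    # centres on a jittered lattice so blobs barely overlap (near-orthogonal)
    centres = []
    for i in range(n_sources):
        for _ in range(200):
            c = rng.uniform([1, 1, 1], [nx - 2, ny - 2, nz - 2])
            if all(np.linalg.norm(c - np.asarray(o)) > min(dims) / 2.2 for o in centres):
                break
        centres.append(c)
        width = min(dims) / 6.0
        d2 = np.sum((grid - c) ** 2, axis=1)
        blob = np.exp(-d2 / (2 * width**2))
        sources[i] = blob
    sources /= np.sqrt(np.mean(sources**2, axis=1, keepdims=True))
    return sources


def simulate_sessions(
    calendar: SessionCalendar,
    n_sources: int = 3,
    dims: tuple[int, int, int] = (15, 15, 10),
    n_frames: int = 200,
    snr: float = 10.0,
    seed: int = 0,
    baseline: float = 1000.0,
) -> SyntheticStudy:
    """Generate one small 4D volume per observed week from known sources.

    Each session is ``baseline + sources^T @ timecourses + noise`` with
    session-specific random Gaussian time courses; ``snr`` is the ratio of
    per-voxel signal RMS to noise SD (``np.inf`` for noiseless sessions).
    """
    if n_sources >= n_frames:
        raise InvalidArgumentError("need n_sources < n_frames")
    rng = np.random.default_rng(seed)
    sources = _blob_sources(n_sources, dims, rng)  # S x V
    n_vox = sources.shape[1]
    mask = np.ones(dims, dtype=bool)
    signal_rms = float(np.sqrt(np.mean(sources**2)))
    noise_sd = 0.0 if np.isinf(snr) else signal_rms / snr

    sessions, timecourses, motion = [], [], []
    for _ in range(calendar.n_observed):
        tc = rng.normal(size=(n_sources, n_frames))
        data = sources.T @ tc  # V x T
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, size=(n_vox, n_frames))
        vol = baseline + data.reshape(*dims, n_frames, order="F")
        sessions.append(vol)
        timecourses.append(tc)
        motion.append(simulate_motion(n_frames, drift_sd=0.02, seed=int(rng.integers(2**31))))

    return SyntheticStudy(
        calendar=calendar,
        sessions=sessions,
        mask=mask,
        true_sources=sources,
        true_timecourses=timecourses,
        motion_params=motion,
        baseline=baseline,
    )


def simulate_motion(n_frames: int, drift_sd: float = 0.02, seed: int = 0) -> np.ndarray:
    """Random-walk realignment parameters: 3 translations (mm), 3 rotations (rad).

    Rotation steps are scaled by 1/50 so that, at the conventional 50 mm brain
    radius, rotational displacement is commensurate with translational.
    """
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    if drift_sd < 0:
        raise InvalidArgumentError("drift_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if drift_sd == 0:
        return np.zeros((n_frames, 6))
    steps = rng.normal(0.0, drift_sd, size=(n_frames, 6))
    steps[0] = 0.0
    steps[:, 3:] /= 50.0
    return np.cumsum(steps, axis=0)


def simulate_covariate(
    calendar: SessionCalendar,
    mean: float = 18.0,
    annual_amplitude: float = 12.0,
    annual_phase: float = 0.0,
    noise_sd: float = 3.0,
    seed: int = 0,
    start: date = DEFAULT_START_DATE,
) -> pd.Series:
    """Daily seasonal covariate (temperature-like): annual sinusoid + noise.

    Returns a pandas Series indexed by calendar date covering the full study
    span, with the annual cycle expressed at the same 52.18-week period used
    for weekly series (phase is relative to the first session's date).
    """
    rng = np.random.default_rng(seed)
    n_days = calendar.total_weeks * 7
    days = np.arange(n_days)
    period_days = ANNUAL_PERIOD_WEEKS * 7
    values = (
        mean
        + annual_amplitude * np.sin(2 * np.pi * days / period_days + annual_phase)
        + rng.normal(0.0, noise_sd, size=n_days)
    )
    idx = pd.to_datetime([start + timedelta(days=int(d)) for d in days])
    return pd.Series(values, index=idx, name="covariate")


def simulate_phantom_series(
    calendar: SessionCalendar,
    mean_intensity: float = 500.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> OutcomeSeries:
    """Trendless scanner-stability series: constant + white noise (negative control)."""
    truth = GroundTruth(intercept=mean_intensity, noise_sd=noise_sd, seed=seed)
    return simulate_outcome_series(calendar, truth, measure_kind="phantom")
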