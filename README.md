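# rsnlong

Longitudinal single-subject resting-state fMRI network analysis: group ICA
outcome measures, their reproducibility, and the temporal structure of
weekly outcome series.

## What this package is for

Dense single-subject designs — one person scanned (nearly) every week for
years — ask different questions than group studies: how reproducible are a
subject's resting-state networks (RSNs) from week to week, and do the
network measures drift, cycle with the seasons, or carry week-to-week
persistence? `rsnlong` implements that analysis chain for a study design of
158 weekly sessions spread over 185 calendar weeks:

1. **Group spatial ICA** — per-session PCA reduction of the voxel × time
   data (time dimension reduced to `session_k` components), temporal
   concatenation, second PCA to `n_components` (order chosen by the
   minimum-description-length criterion; `session_k` defaults to twice
   that), extended Infomax ICA, a stability screen over randomized
   restarts, and **GICA3 backreconstruction** of session-specific maps and
   time courses, whose defining identity — the mean of the session maps
   equals the aggregate map — holds exactly.
2. **Outcome measures** per network and session:
   * spatial similarity of a session map *a* to the study mean map *b*,

     η² = 1 − Σᵢ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σᵢ[(aᵢ−M̄)² + (bᵢ−M̄)²],

     with mᵢ = (aᵢ+bᵢ)/2 and M̄ the grand mean of m; η² ∈ [0, 1], 1 iff the
     images are identical;
   * temporal fluctuation magnitude: RMS of the backreconstructed time
     course in % signal change;
   * between-network connectivity (BNC): Pearson r between network time
     courses;
   * overlap maps: % of sessions in which a voxel's z-score exceeds 1.
3. **Reproducibility**: mean, SD and CV (= 100·SD/mean) per network, with
   equal-variance F-tests against a reference multi-session dataset and
   Bonferroni/FDR correction.
4. **Time-series structure** of each weekly outcome series, on its
   irregular calendar (missed weeks are gaps, never imputed):
   * linear trend by OLS on the calendar week index, F-test + FDR;
   * annual periodicity (1/52.18 weeks ≈ 0.0192 weeks⁻¹) via a
     regression-based spectral estimate on the full-span Fourier grid and
     Fisher's exact g-test, plus permutation-tested correlation with a
     dated seasonal covariate such as daily maximum temperature;
   * persistence via ARMA(p ≤ 3, q ≤ 3) models in the sign convention
     yₜ + a₁yₜ₋₁ + a₂yₜ₋₂ + a₃yₜ₋₃ = eₜ + c₁eₜ₋₁ + c₂eₜ₋₂ + c₃eₜ₋₃,
     estimated from a long autoregression on pairwise-lag autocovariances
     (Durbin's reduced-statistics method) with exact-Gaussian-likelihood
     BIC order selection.
5. **Confound QC**: framewise displacement from realignment parameters
   (FDₜ = Σ|Δtrans| + 50 mm · Σ|Δrot|) and a phantom intensity series, each
   with its own trend check.

Because weekly single-subject fMRI data of this kind are not generally
available, the package ships a first-class synthetic-study generator
(`rsnlong.synthetic`) that reproduces the study's structure — the gappy
weekly calendar, small 4D sessions mixed from known compact sources, and
outcome series with configurable trend, annual cycle and ARMA noise — with
complete ground-truth bookkeeping, so every estimator is testable against
known truth.

## Worked example

```python
import numpy as np
from rsnlong import (GroundTruth, make_calendar, simulate_outcome_series,
                     fit_linear_trend, robust_spectrum, fisher_g_test,
                     fit_arma, cv)

cal = make_calendar(total_weeks=185, n_observed=158, seed=1)
truth = GroundTruth(intercept=0.77, slope=1.94e-4, annual_amplitude=0.02,
                    ar_coeffs=(-0.3,), noise_sd=0.015, seed=1)
eta = simulate_outcome_series(cal, truth, measure_kind="eta_sq",
                              network="Smot-dor")

r = cv(eta.values)
print(f"mean = {r.mean:.3f}, SD = {r.sd:.4f}, CV = {r.cv:.2f}%")

tr = fit_linear_trend(eta)
print(f"slope = {tr.slope:.3e} per week (F = {tr.F:.1f}, p = {tr.p:.2e})")

per = fisher_g_test(robust_spectrum(eta))
print(f"annual peak at {per.argmax_frequency:.4f} wk^-1, "
      f"g = {per.g_statistic:.3f}, p = {per.p:.2e}, "
      f"peak_at_target = {per.peak_at_target}")

m = fit_arma(eta)
print(f"ARMA order = ({m.ar_order},{m.ma_order}), "
      f"a = {np.round(m.ar_coeffs, 3).tolist()}, "
      f"c = {np.round(m.ma_coeffs, 3).tolist()}")
```

prints

```
mean = 0.787, SD = 0.0259, CV = 3.29%
slope = 1.713e-04 per week (F = 21.9, p = 6.09e-06)
annual peak at 0.0162 wk^-1, g = 0.151, p = 1.25e-09, peak_at_target = True
ARMA order = (0,1), a = [], c = [0.386]
```

Reading the output: the weekly spatial-similarity series sits around 0.79
with a CV of 3.3%; the fitted slope 1.7·10⁻⁴/week recovers the generating
1.94·10⁻⁴ within its standard error and is highly significant; the spectral
peak lands on the Fourier bin adjacent to the annual frequency (which falls
between two grid bins of the 185-week span) with a decisive Fisher g-test;
and after removing trend and annual cycle, the residual persistence is
described by a first-order model — at 158 samples a weak AR(1) and a weak
MA(1) are statistically interchangeable descriptions, and the information
criterion picked the MA form here.

## Command line

The `rsnlong` CLI wraps the library stage by stage (`simulate`, `gica`,
`repro`, `timeseries`, `qc`) or end to end:

```bash
rsnlong all --out results/ --seed 1          # full synthetic study
rsnlong all --config my_study.yaml --out results/
```

Each run writes per-measure weekly series, a CV reproducibility table,
trend/periodicity/persistence tables and sign/flag/order matrices, QC trend
checks, and a provenance record (config hash + seed). Runs with the same
seed are byte-identical.

## Layout

```
src/rsnlong/
  synthetic.py   calendars, sessions, outcome series, motion, covariates
  gica.py        PCA / MDL / Infomax / stability / GICA3 / scaling
  outcomes.py    eta-squared, overlap maps, RMS %BOLD, BNC
  repro.py       CV, variance-ratio tests, multiple-testing correction
  timeseries.py  trend, spectra + Fisher g, covariates, ARMA persistence
  qc.py          framewise displacement, phantom series
  pipeline.py    run_study orchestration
  cli.py         click command line
docs/methods.md  model and estimator details, design choices, limitations
```
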