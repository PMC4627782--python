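# Methods

This note documents the models and estimators implemented in `rsnlong`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not establish.

## Study design and data model

The target design is a longitudinal single-subject resting-state fMRI
study: one participant scanned weekly, with some weeks missed, over a span
of `total_weeks` calendar weeks (default 185, with 158 observed). All
weekly series are indexed by the *calendar week* t of acquisition (t = 0 at
the first session), not by session ordinal, so a missed scan widens the gap
between consecutive samples. Missing weeks are treated as exchangeable:
estimators use the observed samples at their true time positions and never
zero-fill or impute.

## Group ICA chain

**Per-session reduction.** Each session's voxels × frames matrix is
centered per voxel and reduced along time to `session_k` principal
components by SVD; the retained spatial components are whitened (singular
values carried separately for time-course reconstruction). Whether
per-session variance normalization precedes concatenation is a genuinely
open choice; we whiten per session.

**Order selection.** The number of components is guided by the
Wax–Kailath minimum-description-length cost on the eigenvalue spectrum of
the frames × frames covariance, with the effective sample size set to the
number of frames and no i.i.d. correction for spatial smoothness (the
synthetic data are not smoothed). Candidates run over 1..frames−1; the
argmin is returned. `session_k` defaults to twice the selected order, a
standard margin for robust backreconstruction.

**ICA.** Spatial ICA of the group-reduced data uses extended Infomax:
natural-gradient updates in blocks, sub/super-Gaussian source switching by
a running kurtosis-sign estimate, learning-rate annealing when the update
trajectory oscillates, a tolerance of 1e-6 on the relative weight change,
and at most 512 iterations; non-convergence is flagged on the result, not
silently ignored. ICA indeterminacies are fixed deterministically:
components are scaled to unit variance over voxels, sign-flipped to
positive skewness, and ordered by explained variance.

**Stability screen.** ICA is rerun `n_runs` times from different random
initializations; components are matched to the first run's by absolute
spatial correlation (Hungarian assignment), and each cluster's index is
(within-cluster mean |r|) − (between-cluster max |r|), clipped to [0, 1],
with a default reliability threshold of 0.8. This is a deliberately
simplified restart-clustering index; a full canonical-correlation
clustering of restarts is out of scope. Note the index reaches 1 only when
distinct components are spatially uncorrelated, which holds to good
approximation for well-separated sources.

**GICA3 backreconstruction.** With R_i the session-reduced data, G_i the
session blocks of the second-stage PCA basis, X = Σᵢ R_i G_i the
group-reduced data, W the unmixing and A = W⁻¹ the mixing matrix, session
maps are S_i = n_sessions · W (R_i G_i)ᵀ and session time courses
TC_i = B_i G_i A, where B_i is the session's scaled temporal basis. The
aggregate maps are computed from the *uncentered* X so that
mean_i(S_i) = W Xᵀ holds exactly (verified to 1e-14 on noiseless data).
Backreconstructed maps are then standardized to mean 0 / SD 1 over in-mask
voxels. We deliberately use plain standardization rather than a
correlation-style variance-stabilizing transform: the map values are
unbounded regression weights, for which such a transform is undefined; the
choice is recorded in the output metadata. Time courses are expressed in %
signal change by scaling with 100 / (session mean signal).

## Outcome measures

* **η² spatial similarity** is computed over in-mask voxels between each
  session's z-scored map and the study mean map (mean over all
  backreconstructed sessions in the run; the averaging set is
  configurable). The formula's denominator uses the grand mean of the
  mean image for both maps — the formula governs, not its looser verbal
  gloss as a variance fraction.
* **Overlap maps** threshold each session map at z > 1 (configurable), sum
  the binary maps, and scale by 100/n_sessions.
* **RMS %BOLD** is the quadratic mean of the %-scaled time course.
* **BNC** is the Pearson correlation of %-scaled network time courses
  (correlation is scale-invariant, so the scaling is cosmetic; recorded
  for transparency). Pairs involving a constant time course are flagged
  undefined rather than silently set to 0.

## Reproducibility statistics

CV = 100·SD/mean with the sample SD (n−1). Because CV inflates near zero
mean, results with |mean| < 2·SD carry a warning flag and the SD should be
read alongside. Dataset comparisons use the two-sided variance-ratio
F-test, F = var(x)/var(y) on (n_x−1, n_y−1) degrees of freedom, with
family-wise correction across the tested networks (Bonferroni by default
for the F-tests; both Bonferroni and Benjamini–Hochberg step-up are
available and BH-FDR is the default for the time-series families). The
first-N-sessions robustness check is an option (`--subset-first`), not a
separate code path. Intra-class correlation is deliberately absent: a
single-subject longitudinal design has no subject class to correlate over.

## Time-series analysis

**Trend.** OLS of the outcome on the calendar week; the slope's F statistic
is referred to F(1, n−2). q-values per outcome measure are corrected across
the network family. Permutation versions (statistic: |slope t|; 1000
iterations by default; add-one p-estimator p = (1+k)/(1+n_iter)) guard the
parametric results.

**Spectral estimate.** For each frequency on the Fourier grid of the full
span (Δf = 1/total_weeks, positive frequencies below Nyquist), the observed
samples are regressed on an intercept and a cosine/sine pair evaluated at
the observed week indices; power = (n/4)(β_c² + β_s²). With no missing
weeks this reduces exactly to the classical periodogram; with gaps it
remains well defined where the periodogram does not. An optional rank
transform of the values provides outlier robustness. This per-frequency
regression honors the published method's contract (robust spectral
estimation for non-uniform sampling) without being a bit-level port of any
particular implementation.

**Fisher's g-test.** The tested statistic is the classical Fisher g — the
maximal spectral share — whose exact white-noise null is the truncated
alternating sum P(g > x) = Σⱼ (−1)^(j−1) C(m, j)(1−jx)^(m−1). This keeps
the test exactly calibrated (verified: 5% type-I error within the binomial
band over 2000 null replicates). The share at the target (annual)
frequency is reported alongside as `g_statistic`, and a *detection at the
target* additionally requires the spectral peak to lie within one grid
step of the target frequency. The one-grid-step tolerance is deliberate:
the annual frequency 1/52.18 ≈ 0.0192 weeks⁻¹ falls between bins 3 and 4 of
a 185-week grid (0.0162 and 0.0216), so a genuine annual component leaks
into both and noise can tip the argmax to either neighbour. Off-grid
targets are snapped to the nearest bin and the snap is recorded.

**Seasonal covariate.** Each observed week's date is matched to the nearest
day of the dated covariate series; the Pearson correlation is tested by
permutation (statistic |r|).

**ARMA persistence.** Models follow the sign convention
yₜ + a₁yₜ₋₁ + a₂yₜ₋₂ + a₃yₜ₋₃ = eₜ + c₁eₜ₋₁ + c₂eₜ₋₂ + c₃eₜ₋₃.
By default the series is first detrended and de-seasonalized (regression on
line + annual sine/cosine), since trend, periodicity and persistence are
reported as separate structures; both removals are exposed as flags.
Estimation, designed for gappy sampling, proceeds in stages:

1. autocovariances at integer week lags from *pairs of observed weeks*
   only (time-aligned products), up to lag min(15, n/5);
2. projection of that sequence onto the positive-definite cone by clipping
   its spectral density at a small positive floor — pairwise estimates
   from gappy calendars need not be a valid autocovariance, and without
   this step the subsequent recursion is unstable;
3. a long AR model via Levinson–Durbin;
4. candidate ARMA(p, q) coefficients, p,q ≤ 3, derived from the long AR by
   Durbin's reduced-statistics construction (least squares on the
   convolution equations c(z)·A(z) ≈ a(z)); pure-AR candidates come from
   the Levinson recursion directly;
5. each candidate is polished by maximizing the exact Gaussian likelihood
   of the observed samples under the candidate's autocovariance (a cheap
   Nelder–Mead pass for all candidates, then a thorough pass for the four
   leaders), so AR and mixed candidates compete at near-ML fits — without
   this, Yule–Walker-optimal AR candidates systematically beat noisily
   initialized mixed candidates;
6. selection by BIC = −2 logL + (p+q+1) log n, with only stationary and
   invertible candidates admitted; white noise (0,0) is always admissible.

The exact likelihood is computed by building the model autocovariance at
the observed week separations (the innovation variance is profiled out);
it agrees with a Kalman-filter evaluation of the same model to 1e-4, which
the test suite checks against an independent implementation.

Measured operating characteristics at n = 158/185 (test suite): white
noise selects (0,0) in ≈ 90% of runs — the same rate full-ML BIC selection
attains, i.e. the BIC's own finite-sample boundary; an identifiable
ARMA(1,1) with a₁ = −0.7, c₁ = 0.7 is recovered with the correct order in
≈ 95% of runs with coefficient bias well inside the sampling spread. The
identifiability experiment deliberately uses a mixed model whose AR(∞) and
MA(∞) expansions both decay slowly; weak-MA models (e.g. c₁ = 0.3) are
information-theoretically indistinguishable from pure AR at this sample
size, for any estimator.

## Confound QC

Framewise displacement from a frames × 6 realignment table (translations
in mm, rotations in radians, SPM column convention):
FDₜ = Σ|Δtrans| + r·Σ|Δrot| with r = 50 mm; FD₁ = 0 by convention. The
per-session summary is the mean FD over frames (the max is also reported;
the choice of summary is not dictated by the design and mean was chosen as
the less outlier-driven of the two). The phantom series is the mean in-mask
intensity of weekly stability scans. Both series feed the same trend test
as the outcome measures; they are negative controls — a trend in an outcome
measure is only interpretable if neither control shows one.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the study: the gappy weekly
calendar (uniform-random missingness, endpoints observed), 4D sessions
composed of compact, near-orthogonal Gaussian-blob sources mixed by
session-specific Gaussian time courses over a positive baseline plus white
noise at a configurable SNR, random-walk realignment parameters, a
constant-plus-noise phantom (trendless by construction, matching its
negative-control role), and a daily sinusoid-plus-noise seasonal
covariate. Weekly outcome series are mean function (intercept + slope·t +
annual sinusoid of period 52.18 weeks) plus ARMA noise generated by direct
recursion with a 500-sample burn-in. Default outcome-series parameters
(level ≈ 0.78, weekly SD ≈ 0.015, mild positive persistence) are chosen to
resemble reported weekly spatial-similarity series.

Not emulated: hemodynamic response, physiological (cardiac/respiratory)
noise, scanner artifacts, spatial smoothness of the noise, slow scanner
drift within sessions, or anatomically realistic network geometry.
Consequently, passing tests establish the *estimators'* correctness and
calibration under the study's sampling design, not robustness to real
acquisition artifacts; the preprocessing that would remove such artifacts
(slice timing, motion correction, normalization, filtering) is explicitly
out of scope, and manual network-vs-nuisance labeling is left as a hook
(the stability screen flags unreliable components, but anatomical judgment
is not automated).

## Numerical choices and degenerate inputs

* PCA/SVD throughout; eigenvalues clipped at 1e-12 of the leading one
  inside the MDL cost.
* Infomax restarts with a halved learning rate on numeric blow-up.
* η² is undefined (error) when both maps are constant and equal; CV is
  undefined at mean 0; BNC pairs with a constant series are NaN + flag.
* Constant series short-circuit: zero slope/F with p = 1 for the trend,
  flat-spectrum flag for the spectrum, estimation error for ARMA.
* Permutation p-values use the add-one estimator, so p ≥ 1/(1+n_iter).
* Stationarity/invertibility are enforced with a 0.1% root margin;
  reflection coefficients are clamped at |κ| ≤ 0.998.
* Problem sizes in the test suite (10×10×6 voxel sessions, 40-frame runs,
  3–5 sources, 2000-replicate calibration loops, 200-replicate order-
  selection runs) are the package's chosen desk-scale experiment sizes:
  large enough for the statistical bands asserted, small enough to run
  routinely.

## Known limitations

* The spectral estimator's grid is the full-span Fourier grid; frequencies
  between bins are localized only to the nearest bin (one-bin tolerance in
  detection, as above).
* Durbin-based ARMA candidates require the long-AR order to exceed p + q;
  very short series (< 30 observed weeks) are rejected rather than fitted.
* The exact-likelihood machinery scales as O(n³) per evaluation; for
  n ≫ 500 the likelihood polish should be disabled (`refine=False`), where
  Yule–Walker/Durbin accuracy is adequate.
* Only linear trends are tested; richer trend shapes (and sub-annual
  rhythms) are out of scope.
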