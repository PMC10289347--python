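# Methods

## Data model and timing conventions

A specimen's curve is sampled on a uniform grid with the first sample at
t = Δ (the end of the first acquisition interval), contrast injection at
t = 0. The native acquisition is Δ = 1.6 s with 513 samples, so the
recording ends at exactly 513 × 1.6 = 820.8 s. Intensities are arbitrary
units and are never rescaled implicitly. Curve files are long-format
delimited text (`specimen_id`, `time_s`, `intensity`); the original
scanner-software export format is proprietary and undocumented, so an open
format is used instead.

Tissue labels are restricted to `cancer` and `normal` peripheral-zone
tissue; anything else (e.g. prostatitis) is rejected at load time. A
subject may own at most one specimen of each tissue type.

## Acquisition-setting grid

Coarser temporal resolutions (3.2, 4.8, 6.4, 8.0, 16.0, 30.4 s) are
emulated by decimation on the 1.6 s master grid — keeping every k-th
sample, which reproduces exactly what a scanner sampling every k·1.6 s
would record of the piecewise-linear signal. A `block_mean` mode (mean
over each k-sample block) is available for scanners that integrate over
the repetition time, but decimation is the default and the reference.
Shorter measurement lengths (2–13 min) truncate the curve, keeping a
sample that falls exactly on the boundary. Sample counts floor
(e.g. 780 s / 1.6 s → 487); there is no interpolation anywhere.

The cell (2 min, 30.4 s) retains only 3 samples; fewer than 4 samples
cannot support the six descriptors, so such cells are reported as missing
with a reason rather than imputed or guessed.

## Descriptor extraction

Onset detection is deliberately explicit, since no published rule exists
for it: the baseline is all samples before 20 s (a time-based window so it
survives downsampling), S₀ is the baseline mean, and enhancement starts at
the first sample opening a run of 2 consecutive samples above
S₀ + 3·sd(baseline). At 16.0 s and 30.4 s resolution fewer than two
samples precede 20 s and no standard deviation can be estimated; the
detector then uses the single first sample as S₀ with a 10% relative-rise
threshold. Without this fallback every cell of the 30.4 s column would be
undetectable, which contradicts the observation that coarse acquisitions
still discriminate; with it, coarse-resolution onset (and hence wash-in
slope) is biased late — an inherent cost of coarse sampling, not an
artefact.

The peak search for the wash-in quantities (RSI, wash-in slope, peak
enhancement) is restricted to the first minute after onset; passing
`wash_in_window_s=None` removes the restriction (the sensitivity-analysis
variant). Ties at the maximum resolve to the earliest sample. Wash-out and
wash-out slope use the last sample of the (possibly truncated)
measurement and are signed with the S_final − Sₘ numerator, so declining
curves give negative values, matching the reported sign convention (the
defining formulas are sometimes written in positive form). Peak
enhancement is the raw maximum Sₘ, not Sₘ − S₀. Degenerate geometries
(Tₚ = T₀, or Tₚ = T_max so no wash-out phase exists) flag the affected row
invalid rather than emitting infinities; invalid rows are excluded from
all model fitting but stay in the feature table with a reason.

## Synthetic cohort generator

The generator emulates the study conditions: 97 specimens (47 cancer, 50
normal) from 54 subjects, 43 of whom contribute both tissues; ROI sizes of
2 vs 3 measuring points in the published 57:40 proportion, entering only
through noise suppression (noise sd divided by √n_roi). Each specimen's
noiseless curve is piecewise linear — baseline S₀ to (T₀, S₀), linear
wash-in to (Tₚ, Sₘ), linear wash-out to the end of the recording — sampled
on the native grid with additive Gaussian noise (sd = 1% of S₀ before ROI
averaging) and clipping at zero. This family realises the six descriptors
exactly, so the extractor can be verified against closed-form ground truth.

Directly drawn per specimen are S₀, T₀, wash-in slope, the onset-to-peak
time d = Tₚ − T₀, and the wash-out slope: independent median-parameterised
log-normals (T₀: normal, median 32 s, sd 5 s, truncated positive). RSI,
Sₘ and S_final are derived. Two calibration constraints shape this design:

* **The reference medians pin the median rise time at the window edge.**
  With S₀ median = 67·100/422 and the reference RSI and wash-in-slope
  medians, the implied median of d is S₀(RSI/100 − 1)/slope ≈ 58.8 s for
  the cancer group — just under the 60 s wash-in search window. Any family
  with meaningful spread in d therefore puts about half the specimens'
  peaks beyond the window, and the extracted median RSI drops ~10% below
  target. The generator instead draws d narrowly (log-sd 0.05, capped at
  60 s), making RSI a derived quantity whose median is exact by the
  log-symmetry of products of independent log-normals. The peak median
  (a sum of two log-normals) is exact to ~1%, verified by Monte-Carlo.
* **Median reproducibility fixes the spread.** The study reports only
  group medians, no dispersions. The generator's contract is that all
  extracted group medians land within 5% of target for ~95% of seeds at
  n = 47/50. The relative SE of a log-normal sample median is
  ≈ 1.25·σ_log/√n, RSI compounds two draws, and the band must hold
  jointly for six-plus medians (~2.7σ headroom each), giving
  σ_log ≤ ~0.09; the default is 0.08.

The quantitative comparison arm draws the four pharmacokinetic-map
features (blood volume, transit time, perfusion, extravascular volume) as
mean-parameterised log-normals around the reference group means with
coefficient of variation 0.3, on the same cohort structure.

What the generator does **not** emulate: within-subject correlation
between a subject's cancer and normal specimens (draws are independent),
spatial ROI structure (averaging is reduced noise only), realistic
inter-patient dispersion (see above — the spread is chosen for median
reproducibility and is far narrower than clinical data), scanner drift,
motion, or non-linear contrast kinetics. Consequently passing tests show
that the pipeline recovers what the curve family encodes, not that it
would reach any particular discrimination level on patient data.

## Score development and cross-validation

The logistic ML fit is a damped Newton solver (convergence when the score
norm falls below 1e-8, at most 100 iterations, step-halving, Wald p-values
from coefficient/SE against the standard normal). It matches statsmodels
to numerical precision on non-separated data — the test suite asserts
this — and exists as its own implementation because leave-one-pair-out
over the grid performs on the order of a million small fits.

Backward elimination removes one covariate per refit (the largest Wald p,
while p > 0.2); no re-entry step is implemented, as only a removal rule is
specified. Two boundary behaviours matter:

* An **empty final model** is allowed; its score is the constant
  intercept, so under the strict tie rule every pair it judges counts
  non-concordant.
* Under **complete separation** the likelihood has no maximiser, every
  standard error diverges (Hauck–Donner) and all Wald p-values approach 1,
  which would absurdly eliminate even a perfectly discriminating
  covariate. The solver detects separation (all fitted probabilities
  within 1e-3 of their labels), stops, flags the fit non-converged, and
  elimination halts with the current covariate set; the last iterate's
  score ranking is used. This matters for the synthetic cohort: its narrow
  spread makes the groups nearly separable, so grid C-statistics sit near
  1 — clean-simulation behaviour, not a claim about patient data, where
  reported C-statistics are ~0.66–0.75 and separation does not arise.

Leave-one-pair-out validation forms every (cancer specimen, normal
specimen) pair; the training set excludes **all specimens of both involved
subjects** (default), so a subject owning both tissues never trains a
model tested on itself — the strictest reading of the pairing protocol; a
`specimen` leave-out mode (drop only the two held-out specimens) is
available. The pair is concordant iff score(case) > score(control)
strictly; ties and failed training fits count as non-concordant with the
denominator fixed at n_cases × n_controls (a 0.5-credit tie rule is
available behind a flag, off by default). Linear trends of C on
temporal resolution and on measurement length are two univariate OLS fits
with normal-theory 95% CIs by default (the full factorial grid is
balanced, so a joint bivariate fit — available via `joint=True` — gives
identical slopes).

## Problem sizes and numerical choices

The default full experiment is 112 settings × 97 specimens = 10,864
resampled curves and 112 × 2,350 leave-one-pair-out folds, each refitting
the stepwise model; it completes in a few minutes on one CPU. Tests use a
47 + 50 cohort for calibration checks, ≤ 12-specimen cohorts for exact
oracle comparisons, and 200 label permutations at 20 + 20 for the null
calibration of the C-statistic. Time comparisons use a 1e-9 absolute
tolerance (grid arithmetic), truncation boundaries 1e-9, the baseline-sd
floor is 1e-12, and the optional ridge stabiliser (default off) is 1e-6
per unit penalty on non-intercept coefficients.

## Known limitations

* The original study's per-patient curves are not available in a
  documented format, so its headline C-statistics (0.743 best setting,
  0.656 quantitative arm, 0.750 unrestricted wash-in) and trend slope are
  not reproduced here; the synthetic cohort reproduces descriptor medians
  and pipeline structure, not discrimination levels.
* Onset detection is an invented, configurable rule; reported onset times
  snap to the sampling grid and are biased late by up to one interval plus
  the threshold-crossing time.
* Wash-out percent is emergent rather than calibrated (its median on
  synthetic data, ≈ −40% cancer / −50% normal, is more negative than the
  reference −30%/−23%): with slope, peak and measurement length fixed by
  the other calibration targets, the wash-out fraction is over-determined
  and cannot be matched simultaneously with the wash-out slope.
* The stepwise-selected covariate sets on near-separable synthetic data
  are not informative about which descriptors would be selected on
  clinical data.
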