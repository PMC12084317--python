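# Methods

## Overview

`metica` extracts temporally independent, physiologically meaningful (BOLD)
signal components from multi-echo naturalistic fMRI and relates them to
stimulus content and clinical covariates. The analysis has five stages:

1. **Per-subject trilinear (tensor) ICA.** Each subject's 4-D data
   (voxels × echoes × time) is masked, smoothed, de-meaned per
   voxel/echo, unfolded to an (echo·time) × voxel matrix, PCA-whitened
   to an automatically selected order, and decomposed by spatial
   fixed-point ICA (tanh contrast, symmetric decorrelation). Each
   component's mixing column, reshaped to echoes × time, is split by its
   leading rank-1 SVD into a TE loading and a time course — the
   trilinear structure the multi-echo acquisition implies.
2. **TE-profile BOLD classification.** A ΔR2\*-driven (BOLD) signal scales
   approximately as TE·exp(−TE/T2\*), which is bell-shaped across echo
   times and peaks near tissue T2\*; S0-driven artifacts decay
   monotonically. A quadratic is fitted to the four TE loadings;
   a component is BOLD iff the fit is concave with vertex in the closed
   window [20, 50] ms. No goodness-of-fit gate is applied by default
   (an optional `min_r_squared` exists for noisy data).
3. **Group temporal ICA with ICASSO stabilization.** BOLD-labeled time
   courses from all subjects are smoothed (centered moving average,
   window 5, shrinking at the edges), z-scored, concatenated row-wise,
   and decomposed by temporal ICA (sources independent along time) run
   20 times from random starts. Pooled estimates are clustered by
   average linkage on 1 − |Pearson r|; each cluster's best exemplar is a
   group temporal component (GTC) whose stability index is mean
   intra-cluster minus mean extra-cluster similarity.
4. **Stimulus correlation.** GTC time courses are Pearson-correlated with
   HRF-convolved annotation/feature regressors; p-values (t distribution,
   T − 2 df) are Benjamini–Hochberg adjusted over the full GTC × regressor
   matrix; a correlation is flagged when |cc| > 0.35 and q < 0.05.
5. **GLM mapping and group inference.** Echoes are combined with fixed
   weights [1 2 2 2] (normalized), the first 10 volumes discarded, all
   GTCs entered simultaneously in a voxelwise OLS (plus intercept and
   linear drift). Second-level one-/two-sample t-maps are thresholded at
   voxelwise p < 0.001 (two-sided); cluster-extent family-wise error is
   controlled by max-statistic permutation (group-label permutations, or
   sign flips for one-sample maps), with 26-connected clusters. Peak
   betas from significant clusters are correlated with symptom scores.

## Synthetic cohorts

No public dataset accompanies this analysis, so the package ships a
forward simulator whose defaults define the study conditions at desk
scale: grid 16×16×8 voxels, 310 volumes (10 leading dummy volumes),
TR = 1 s, echoes at 13/28/43/57 ms, 8 subjects per group (HC vs MDD),
4 BOLD + 3 non-BOLD sources.

The signal model is
`y(v,e,t) = baseline(v,e) + Σ_c a_sc · m_c(v) · b_c(TE_e) · s_c(t) + drift + noise`:

- **Baseline**: a smooth positive ellipsoidal "brain" with exp(−TE/40 ms)
  echo decay; voxels outside the ellipsoid contain noise only.
- **Maps** `m_c`: compact connected Gaussian blobs (max 1).
- **TE profiles** `b_c`: BOLD sources use TE·exp(−TE/T2\*) with T2\*
  uniform in 30–48 ms; non-BOLD sources use exp(−TE/T2\*) with T2\* in
  20–60 ms, plus one TE-constant profile. The 30–48 ms BOLD range is the
  gray-matter-like band whose quadratic-fit vertex stays inside both the
  sampled range and the [20, 50] ms classification window at these echo
  times (the vertex of the fitted parabola is a biased estimate of T2\*:
  ≈16.5 ms for T2\* = 20 ms, ≈48.6 ms for T2\* = 50 ms).
- **Time courses** `s_c`: half of the BOLD sources are stimulus-locked —
  HRF-convolved per-TR aggregates of blockwise binary annotation tracks
  (language, face, music, negative face; runs of 1–30 s). The remainder
  are smooth *super-Gaussian* (cubed smoothed Gaussian) series,
  residualized against all earlier sources. Two properties were
  deliberate: mutual |r| < 0.2 (so recovery is well-posed) and
  heavy-tailed marginals (Gaussian sources are unidentifiable for
  temporal ICA; bursty spontaneous fluctuations are the realistic
  analogue).
- **Subject amplitudes** `a_sc = exp(0.2·z)`; the patient group's loading
  on one source (default: the first, language-locked) is multiplied by
  the planted ratio (default 0.5).
- **Symptom scores**: BDI-like (mean 15, SD 10) with exact sample
  correlation −0.4 to the planted amplitude (noise residualized against
  the amplitude before mixing).
- **Noise**: iid Gaussian per voxel/echo/time with SD = 1/SNR
  (default SNR 2, interpreted as peak source amplitude SD over thermal
  noise SD — sensory-driven components in naturalistic viewing are
  strong after spatial smoothing), plus a per-voxel linear + quadratic
  drift with coefficient SD 0.3 × noise SD. SNR = inf gives the exact
  noiseless forward model (up to float32 storage).

What the simulator does **not** emulate: head motion, slice timing,
physiological (cardiac/respiratory) noise structure, distortion, and
spatial autocorrelation of thermal noise. Passing tests therefore show
the *pipeline logic* recovers planted structure under well-behaved
noise; they do not certify performance on real scanner data.

## Numerical choices

- **Model order (per subject)**: Wax–Kailath MDL on the PCA eigenvalues
  of the *unsmoothed* unfolded data with n = number of masked voxels.
  Smoothing correlates the voxel samples and breaks the iid assumption
  behind MDL (it drove the estimate to the cap); the unsmoothed spectrum
  gives calibrated orders (≈ sources + drift dimensions). Orders are
  clipped to `max_order` (default 40).
- **Model order (group)**: `number_of_components` implements the same MDL
  on the row-space covariance (n = T). On concatenated cohort rows the
  noise floor is far from flat (Marchenko–Pastur spread at p/T ≈ 0.2–0.4
  plus moving-average coloring), and MDL over-selects several-fold —
  while temporal ICA degrades sharply once the order exceeds the true
  shared dimension. The pipeline therefore defaults to counting
  eigenvalues above the Marchenko–Pastur edge (1 + √(p/T))², computed on
  unsmoothed rows; MDL remains available via `group_k="mdl"`.
- **ICA**: scikit-learn FastICA, parallel (symmetric) updates, logcosh
  contrast, tol 1e-4 (1e-6 for the group stage), max 1000 iterations.
  Non-convergence triggers a restart with a new random start and a 10×
  relaxed tolerance: symmetric tanh updates oscillate indefinitely on
  near-Gaussian tail dimensions of the whitened data while genuine
  sources settle within the first iterations; the tolerance actually
  used is recorded in the diagnostics. After `max_restarts` the stage
  raises, naming the seed.
- **Sign conventions**: TE loading mean ≥ 0; spatial maps unit norm with
  nonnegative skew; group time courses sign-fixed to positive skew;
  stability and flagging use |r| and are sign-invariant.
- **HRF**: canonical double-gamma (response delay 6 s, undershoot delay
  16 s, dispersions 1, ratio 6, 32 s support), peak-normalized —
  the de facto standard form.
- **Degenerate TE fits**: the fit itself reports an undefined vertex only
  for numerically zero curvature; the *classifier* additionally labels a
  profile degenerate (flat) when the fitted parabola's swing across the
  sampled TE range, |a|·span(TE)², is below `min_relative_curvature`
  (default 0.2) × the peak loading. Both bounds are scale-invariant, so
  classification is unchanged by positive rescaling. The 0.2 default
  sits midway (geometrically) between the swings of recovered
  TE-constant artifacts (≤ 0.09) and of genuine BOLD profiles (≥ 0.45 at
  these echo times; 0.74–0.89 in the noiseless model) — TE dependence
  below it is at component-estimation-noise level and cannot support a
  peak-vs-decay call.
- **Sound envelope**: computed literally as the squared magnitude of the
  analytic signal of the SPL series; `envelope_on="waveform"` provides
  the conventional waveform-based variant. SPL uses a full-scale
  reference with a −100 dB silence floor.
- **Permutation inference**: FWE p = (1 + #{null ≥ observed})/(1 + n_perm),
  so p ≥ 1/(1 + n_perm); when fewer distinct relabelings exist than
  requested permutations the count is capped with a warning.
  Permutation replaces parametric random-field cluster correction: it is
  exact under exchangeability and makes no smoothness assumptions, at
  desk scale a strictly better-calibrated choice.
- **Correlation p-values** use the plain t approximation with T − 2 df,
  with no autocorrelation correction — matching the analysis being
  reproduced; with smooth time series these p-values are optimistic, a
  known limitation.

## Problem sizes used in tests and the acceptance script

Generate-and-recover checks run the full pipeline on the default
16×16×8 / 310-volume / 16-subject cohort (10 seeds in the test suite,
5 in the acceptance script; 300 permutations). The permutation type-I
check uses pure-noise cohorts at 12×12×6 / 165 volumes / 12 subjects
with 200 permutations (100 seeds in the suite, 50 in the script).
These sizes were chosen so a complete verification cycle runs on a
single CPU in minutes while leaving every inferential step identical in
structure to a full-scale analysis.

## Known limitations

- The age-matched two-sample t printed in the source study (−0.56) is not
  reproducible from its rounded printed summaries (the pooled formula
  gives ≈ −0.60); no check asserts it.
- Temporal ICA assumes non-Gaussian shared sources; components that are
  nearly Gaussian (heavily low-pass signals) are recovered only up to
  rotation, which is an intrinsic identifiability limit, not an
  implementation artifact.
- ICASSO stability uses random restarts only (no bootstrap), matching a
  20-run restart protocol.
- The flagging threshold |cc| > 0.35 and FDR q < 0.05 are conventions of
  the reproduced analysis, not calibrated quantities of this package.
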