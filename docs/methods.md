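# Methods

This document records the models, conventions and parameter defaults used
throughout `netresp`, and the rationale behind them.

## 1. Haemodynamic model and design matrices

Condition regressors are unit-height boxcars (one per event) convolved with
a canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s,
peak:undershoot ratio 6, 32 s support) on a 16× oversampled time grid and
sampled at volume acquisition times.

The kernel is normalized to **unit area** (`sum(h)·dt = 1`), so the
response to a long block plateaus at exactly 1 (after a transient overshoot
before the undershoot accumulates). This fixes the physical scale of the
regressors: the connectivity module's condition mask applies an absolute
threshold (0.05) to regressor values, which is only meaningful when the
regressor scale is pinned down.

## 2. Group spatial ICA

- **Reduction.** Runs are stacked in time (temporal concatenation) and
  reduced by a single group PCA (SVD of the voxel-mean-centered stack).
  A single-stage reduction is exact and simpler than per-subject cascades;
  at the data sizes targeted here the SVD is cheap.
- **Estimation.** FastICA (logcosh contrast) on the reduced data,
  re-estimated from `n_repeats` random initializations. Non-convergent
  repeats are dropped (warning); if more than half drop the decomposition
  is declared unstable.
- **Stability clustering.** All estimated maps are pooled and clustered by
  average-linkage agglomeration on `1 − |spatial correlation|` into k
  clusters. Each cluster is represented by its **centrotype** (member with
  the largest within-cluster similarity sum) and scored with
  `Iq = mean intra-cluster − mean extra-cluster similarity`.
- **Sign convention.** Each group map is flipped so its skewness is
  positive. ICA signs are arbitrary; skew-positive makes runs reproducible
  and makes "activation" loadings positive for blob-like sources.
- **Back-reconstruction (GICA3-style).** Subject time-courses are the
  subject's rows of `G @ A` (PCA basis times mixing matrix); subject maps
  are the least-squares regression of the subject's centered data on those
  time-courses. On data exactly spanned by the group model the subject maps
  average to the group map, which the tests verify.
- **Order selection.** An optional scan over candidate orders runs ICA on
  each task separately and on the joint concatenation and scores each order
  by the mean matched |spatial r| between joint and single-task components
  (Hungarian one-to-one matching); ties break to the smaller order.

## 3. Component classification

A component is kept as neural only if all three hold:

| metric | threshold | notes |
| --- | --- | --- |
| low/high frequency power ratio | ≥ 0.65 | Welch spectrum, unit total power; low band 0.01–0.10 Hz, high band 0.15–0.25 Hz |
| spectral dynamic range | ≥ 0.0175 | peak power minus the minimum power above the peak |
| grey-matter overlap | ≥ 0.75 | loading-weighted overlap of the thresholded map |

Maps are thresholded with a two-Gaussian mixture (EM, posterior > 0.5 for
the larger-mean class) with a z > 2 fallback when EM fails or degenerates.
Spectral metrics are averaged over subject/task time-courses; infinite
ratios (no high-band power) are capped at 1e6 before averaging. Components
with empty thresholded maps are auto-excluded. A `motor_exclude` list
allows judgment-based removal of response-execution components without
marking them non-neural.

Default-mode components are identified by loading-weighted overlap (≥ 0.5)
with a template that unions medial prefrontal, posterior cingulate,
precuneus and bilateral inferior parietal regions; a `dm_medial` subset
drops members dominated by the lateral parietal regions.

## 4. Responsivity, MCR/MTR and the k-scan

For each subject, component and task, the component time-course and every
condition regressor are z-scored and jointly regressed (with intercept).
Responsivity is the difference of standardized betas,
`r = β(more demanding) − β(less demanding)`; standardization makes the
index invariant to time-course and regressor scaling, and the index is
antisymmetric under contrast reversal.

**MCR** is the per-subject mean responsivity over a component set. The
task-positive set is found by ranking components on **signed** cohort-mean
responsivity (suppressed components are treated separately via the DM
analysis, not folded into the task-positive set) and scanning k = 1..K for
the top-k set whose MCR correlates best with task score on covariate
residuals (education, handedness, gender by default; optionally partialling
age). Ties go to the smaller k. **MTR** is the MCR at the winning k.

## 5. Statistics

- Pearson correlations carry Fisher-z 95% CIs
  (`tanh(atanh r ± 1.96/√(n−3))`) and t-test p-values on n−2 df.
- Independent correlations are compared with the Fisher-z test; dependent
  correlations sharing one variable with the Williams/Steiger t on n−3 df.
- Moderation: OLS with mean-centered `x`, `z` and their product; the
  interaction is reported as partial R² = (SSE_red − SSE_full)/SSE_red with
  a 1-df F-test.
- Mediation: product of coefficients on two OLS fits (`m ~ x + cov`,
  `y ~ x + m + cov`), ACME = a·b, ADE = c′, total = c, with percentile
  bootstrap CIs (1000 reps by default). For linear OLS,
  ACME + ADE = total holds to machine precision (tested at 1e-8).
  Proportion mediated = ACME/total is reported as undefined when the total
  effect is numerically zero. For a standardized trivariate system the
  mediator–outcome correlation implied by a target proportion has the
  closed form `r_my = b(1 − r_xm²) + r_xy·r_xm` with
  `b = proportion·r_xy / r_xm` (`implied_mediator_outcome_corr`), verified
  analytically to round-trip.
- Compensation screens: per component, (1) responsivity–age correlation
  within the older group for positively activated components, (2) a
  responsivity × age interaction predicting score; both at uncorrected
  α = 0.01 by design (the screens are sensitivity checks; a
  Benjamini–Hochberg helper is provided but off by default). Within the
  older subgroup, covariate columns that are constant there (e.g. a binary
  covariate with a single level) are dropped — they are absorbed by the
  intercept.
- Behavioural outliers: a subject is excluded when its score deviates from
  the mean of its ±15-year age window by more than 2.5 window standard
  deviations (sample s.d., window must have ≥ 3 members, subject included,
  no iterative re-exclusion).

## 6. Condition-specific functional connectivity

Component time-courses are residualized on an intercept, the 24-parameter
motion expansion (6 realignment parameters, their first-difference
derivatives, and squares of both) and the HRF-convolved conditions of
non-interest (collinear columns dropped with a warning). Connectivity is
`atanh(r)` over volumes where either condition-of-interest regressor
exceeds 0.05 (≥ 10 volumes required); |r| = 1 is clipped to 1 − 1e-15 so z
stays finite. Under a full mask this reduces bit-exactly to ordinary
full-run FC, which the tests check.

## 7. Synthetic generator

### Geometry and tissue model

Components are isotropic Gaussian blobs (σ = 1.3 voxels) on a 16×16×12
grid. Neural and default-mode blobs sit at z = 4–8 lattice positions inside
the grey-matter zone; vascular and white-noise blobs sit at z = 1, inside
the white-matter/CSF zone, so the grey-matter-overlap rule flags them
regardless of spectral estimates (robust on short runs). σ = 1.3 keeps all
pairwise map correlations below 0.3 (measured maximum 0.265), preserving
approximate spatial orthogonality for ICA.

### Signal model

For subject s with standardized age `z_s` and latent efficiency `g_s ~
N(0,1)`, the more-demanding condition amplitude of component c is

```
A_cs = base + contrast_c + slope_c · z_s + loading_c · g_s + sd_c · ε_cs
```

while other conditions stay at base. Component time-courses are the
amplitude-weighted design regressors plus kind-specific baseline noise
(band-limited 0.01–0.10 Hz for neural/DM, 0.15–0.25 Hz for vascular, white
for noise components) plus a shared low-frequency factor entering with
weight +0.6 (signal components) or −0.6 (DM), planting the task-positive /
default-mode anticorrelation. BOLD is the map-weighted sum of time-courses
plus i.i.d. voxel noise (sd 1.0; optional AR(1)). Behavioural scores are
driven by the same `z_s` and `g_s`, which is what makes responsivity a true
mediator of the age–performance path.

### Default fluid-intelligence scenario calibration

The default scenario (30 components: 4 signal, 6 DM, 14 other neural,
4 vascular, 2 noise) is calibrated so that the planted k = 4 task-positive
set is recoverable by construction. The planted cohort-level correlation
structure is anchored to the study conditions the package targets
(r(age, MTR) ≈ −0.72, r(age, score) = −0.68, implied r(MTR, score) ≈
0.708). Within that constraint the per-component parameters were chosen by
a small design-time grid scan (before the acceptance runs were frozen):

- signal contrasts (1.3, 1.2, 1.1, 1.0), age slopes (−0.50, −0.65, −0.80,
  −0.95), performance loadings (0.35, 0.50, 0.65, 0.80), idiosyncratic sd
  0.55 — the *graded* loadings ensure the k-scan correlation strictly
  increases up to k = 4 and drops at k = 5;
- the 14 non-signal neural components get near-zero contrasts and a large
  idiosyncratic sd (1.8), so adding any of them to the set dilutes the
  MCR–score correlation sharply;
- DM components: negative contrast (−0.5) with positive age slope (+0.25)
  — suppression that weakens with age — and negative performance loading.

With these defaults the k-scan selects k = 4 in 47/50 seeds (94%) at
n = 98 subjects.

### Realism limits

The generator is a test harness, not a biophysical simulator: no spatial
noise correlation, no susceptibility artifacts, no HRF variability across
subjects or regions, simplistic motion (random walks, not injected into the
images), uniform age distribution, and tissue masks that partition the
grid exactly. Conclusions about estimator behaviour on real data should be
drawn accordingly.

## 8. Numerical and reproducibility conventions

- All randomness flows from integer seeds through
  `numpy.random.default_rng([seed, tag, ...])` with fixed stream tags per
  module (cohort 101, amplitudes 7, time-courses 13, BOLD 29, behaviour 41,
  trivariate sampler 53), so e.g. the cohort's latent factor is identical
  between the BOLD and behaviour generators under the same seed.
- OLS is solved with `numpy.linalg.lstsq`; rank-deficient designs raise
  `CollinearityError` rather than silently pseudo-inverting (except the FC
  cleanup, which drops collinear nuisance columns with a warning, since
  motion expansions are routinely collinear).
- The pipeline writes every stage as TSV plus a `summary.json` rounded to
  10 decimals with sorted keys, so byte-identical reruns are testable.

## 9. Known limitations

- The mixture-model map threshold assumes a dominant null Gaussian; maps
  with heavy bilateral tails fall back to z > 2.
- Spectral metrics need ≥ 64 volumes; at 150 volumes the dynamic-range
  estimate is noisy, which is why the synthetic non-neural components are
  additionally placed outside grey matter.
- Tissue-mean regression (WM/CSF cleanup) removes variance shared with
  spatially coherent non-neural sources; this is intended (they should not
  survive into the neural analysis) but means the cleanup stage is not
  variance-preserving for those sources.
- The mediation model is linear; no exposure–mediator interaction is
  modelled.
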