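# Methods

`cvrkit` implements a breath-hold BOLD-fMRI cerebrovascular reactivity
(CVR) analysis end to end — expired-CO₂ trace → PetCO₂ regressor →
voxel-wise GLM → tissue-median CVR → cohort statistics → TFCE permutation
inference — together with a synthetic-data layer that generates every
input with known ground truth. This note records the model, the defaults
and why, the numerical choices, and what the synthetic data does and does
not establish.

## Signal model

The forward model for a voxel's BOLD time course is linear in the
end-tidal CO₂ regressor:

    y(v, t) = s0(v) · [ 1 + (CVR(v)/100) · x̃(t) + d(v, t) + ε(v, t) ]

where `x̃(t)` is the processed PetCO₂ regressor minus its temporal mean
(mmHg), `CVR(v)` is the true reactivity in %BOLD/mmHg, `d` a slow drift
polynomial and `ε` i.i.d. Gaussian fractional noise. This is the minimal
generative model whose maximum-likelihood estimate is exactly the
voxel-wise OLS the estimation pipeline performs, which makes the
estimator's target identifiable and the noiseless round trip exact to
machine precision.

## PetCO₂ regressor

1. **End-tidal detection.** Per-breath expiratory maxima: local maxima
   with a refractory interval (default 2 s) and a prominence gate
   (default 5 mmHg). The refractory interval rejects cardiogenic
   oscillations riding on the expiratory plateau; the prominence gate
   rejects the flat apnea segments, so the single deliberate post-hold
   expiration supplies the end-of-hold PetCO₂ sample.
2. **Resampling.** Linear interpolation of the end-tidal samples onto the
   volume-acquisition midpoints, with constant extrapolation outside the
   first/last breath. Linear interpolation between end-tidal values is
   standard PetCO₂ practice; during an apnea there are simply no samples,
   and the interpolant ramps toward the post-hold value.
3. **Quadratic detrending.** OLS residuals against {1, t, t²}. This
   removes slow drifts of the breathing baseline while leaving the
   ~50 s task cycle (>90% of its energy) untouched.
4. **cHRF convolution.** Causal convolution with a double-gamma canonical
   HRF: peak delay 6 s, undershoot delay 16 s, unit dispersions,
   peak:undershoot ratio 6, truncated at 32 s, sampled at the TR. The
   kernel is normalized to **unit sum**, so a sustained step of A mmHg
   produces a response of amplitude A and regression coefficients keep
   %BOLD/mmHg units. All parameters are configurable (`HRFParams`).

No PetCO₂→BOLD lag optimization is performed; the regressor timing is
fixed by the cHRF. Peak timing diagnostics (`block_peak_lags`) use
parabolic interpolation through the discrete maximum and its neighbours,
because the 3 s TR is coarse relative to the ~6 s hemodynamic delay.

## Preprocessing and estimation

- **Fractional BOLD**: percent change about each voxel's temporal mean;
  voxels with nonpositive mean are flagged invalid and excluded.
- **Temporal high-pass**: subtract-the-Gaussian-smoothed-signal with
  σ = 60 s (reflective boundaries). At the 50 s task period the Gaussian
  smoother's gain is ≈ 0, so the task response passes essentially
  unattenuated.
- **Design filtering**: the same high-pass is applied to the design
  regressor before the GLM. This mirrors how FEAT-style GLM tools filter
  the model alongside the data, and removes any filter-induced amplitude
  bias: with matched filtering the noiseless round trip recovers the true
  CVR exactly rather than to a few percent.
- **GLM**: per-voxel OLS of the filtered percent signal on
  [demeaned regressor, intercept] (optional drift/confound columns;
  rank-deficient designs are rejected naming the collinear columns).
  β is the CVR estimate, with t-statistic, residual SD and dof recorded.
- **Tissue masks**: per-voxel argmax of the GM/WM/CSF probability maps;
  ties broken in the fixed order GM > WM > CSF; voxels with all
  probabilities < 0.05 are background. Tissue summaries are **medians**
  of the unsmoothed β map within GM and WM, with enhancing-lesion voxels
  excluded; the lesion CVR is the median within the lesion mask. Medians
  use the midpoint convention for even counts.
- **Normalized volumes**: scaling · voxel volume · Σ(probability), in
  cm³. Synthetic subjects share one grid, so the scaling factor stands in
  for normalization to a standard intracranial volume.
- Spatial smoothing (σ = 4 mm, per-axis in voxel units, reflective
  boundaries) is applied only at the group level, before voxel-wise
  inference — never before ROI medians.
- Motion correction and registration are out of scope: the synthetic
  subjects are motion-free on a common grid. Real-data users must
  realign and register upstream.

## Synthetic data

- **Phantom**: concentric shells (WM core, GM shell, CSF rim) with
  sigmoid transitions in normalized radius (boundaries at 0.55 / 0.8 /
  1.0, width 0.06), probability maps summing to ≤ 1, and a smooth
  baseline-signal field. Lesions are disjoint spheres placed wholly
  inside the WM-argmax region (greedy placement with reshuffling
  retries; an explicit error names the WM constraint when the core is too
  small). The default desk-scale grid is 16³ at 3 mm; lesion-bearing
  subjects use 32³ so that two radius-3 lesions (≈250 voxels) fit in the
  WM core and the lesion median is stable at realistic noise.
- **Capnograph trace**: raised-cosine breaths (trough ≈ 0 mmHg,
  end-tidal peak = 40 mmHg baseline) at a 4 s paced period, flat
  ~1 mmHg segments during the 16 s holds, and a single post-hold
  expiration peaking at baseline + `bh_rise`. Defaults: 20 Hz sampling
  (resolves individual breaths; the acquisition hardware is only
  described as analogue-to-digital), `bh_rise` = 8 mmHg (a typical
  excursion for a 16 s end-expiration hold; the true value varies by
  subject and is configurable), additive Gaussian noise 1 mmHg. The task
  is 5 × (16 s hold + 34 s recovery) with a 26 s lead-in, which exactly
  fills the 92-volume, TR = 3 s acquisition.
- **Cohort**: per-subject tissue CVRs drawn from group/session normal
  distributions whose defaults are the reference study conditions
  (HC GM 0.105 ± 0.026, WM 0.068 ± 0.020; patient pre-treatment GM
  0.091 ± 0.026, WM 0.055 ± 0.020; on-treatment GM 0.107, WM 0.066
  %BOLD/mmHg). Sessions 1–2 add within-subject jitter (default
  0.008 %BOLD/mmHg, subtracted in quadrature from the marginal SD so the
  cross-subject session SDs match the group SDs). The on-treatment
  change is Δᵢ = meanΔ + slope·(preᵢ − mean_pre) + ηᵢ with slope = −0.6
  and total SD matching the reference change SDs (GM 0.030, WM 0.022) —
  the "restoration" structure in which larger recovery follows larger
  initial impairment. The session-3 marginal SD is then determined by
  the construction (≈ 0.028 for GM) rather than set independently.
- **Enhancing lesions**: positivity counts 12/8/3 across sessions with
  nested persistence (session-3 positives ⊆ session-2 ⊆ session-1).
  Whether the same patients stay positive across sessions is not
  observable from counts alone; nestedness is the simplest longitudinal
  structure consistent with a monotone reduction, and is flagged in the
  generation config. Lesion truth defaults to 0.5 × the surrounding WM
  truth (depressed reactivity); magnitude configurable.
- **Volumes**: per-subject volume scaling ~ 5% SD; in patients the GM
  scaling is correlated (ρ = 0.6) with the pre-treatment GM CVR,
  emulating the volume–reactivity association. Because the on-treatment
  change is anti-coupled to the pre-treatment level, this association
  weakens at session 3 without any volume change — the same decoupling
  mechanism the analysis is designed to exhibit.
- **Missing sessions**: one patient missing session 2 and two missing
  session 3 by default (indices arbitrary); missing sessions produce no
  data and are flagged in the truth table.

What the synthetic data does **not** emulate: motion and spin-history
artifacts, distortion, physiological aliasing, scanner drift beyond a
polynomial, lesion evolution, registration error, or realistic brain
geometry. Passing tests therefore establish the correctness and
calibration of the estimation and inference machinery under the stated
model, not robustness to real-world artifact.

## Statistics

- Normality: Kolmogorov–Smirnov with Lilliefors correction by default
  (parameters estimated from the sample; testing against a fully known
  normal is rarely what is meant), classical KS available via
  `method="naive"`.
- Unpaired t: classical pooled-variance two-sided; paired t on
  difference scores; both fail explicitly on zero variance.
- Repeated-measures one-way ANOVA: classical within-subject
  sum-of-squares decomposition, F with dof (k−1, (k−1)(n−1)), complete
  cases only with logged exclusions; no sphericity correction by default
  (k = 3 sessions; statsmodels' AnovaRM serves as the cross-check in the
  test suite).
- Pearson correlation with t-based two-sided p; Fisher z = atanh(r).
- The cohort bundle (`analyze_cohort`) runs the full battery with
  listwise missing-data handling per test and an explicit exclusion log;
  p-values are uncorrected and two-sided (recorded in the output
  metadata). The on-treatment change is session 3 minus the
  **pre-treatment average** of sessions 1–2 (when one pre-treatment
  session is missing the other stands in); `delta_reference="session2"`
  is available for the alternative convention.
- Type-I error of every test is verified at 0.05 ± 0.02 over 2000 null
  replicates in the acceptance suite.

## Voxel-wise inference

TFCE with E = 0.5, H = 2, 26-connectivity and dh = max/100 (the standard
settings of the method), computed by connected-component labeling over
the threshold ladder; negative values are enhanced on the negated map
and sign-restored. The threshold ladder is defined as h = k·dh with a
1e-9·dh tie tolerance so that uniform plateaus at the top threshold are
included despite floating-point representation.

Permutation inference: one-sample (paired differences) via sign flips,
two-sample via group-label exchange, exhaustive enumeration whenever the
permutation space fits the requested count (which also makes the p-maps
exactly invariant to subject order). The step dh is fixed from the
observed map so all permutations share one ladder. Corrected
p(v) = (1 + #{perm maxima ≥ TFCE_obs(v)}) / (n_perm + 1), testing the
positive tail; n_perm defaults to 1000 at desk scale (the seed is part
of the scheme). Subject maps are smoothed (σ = 4 mm) before inference.
Family-wise error under a simulated null is verified at ≤ 0.05 + 2·SE in
the acceptance suite (12 subjects × 500 permutations × 50 replicate
datasets).

## Problem sizes

Default grids and replicate counts are chosen so the full test suite and
the analysis drivers run in minutes on one core: 16³ phantoms for
cohort-scale runs (a 41-subject cohort estimates in ~4 s), 32³ for
lesion-bearing subjects, 8³ stat maps for permutation-calibration
replicates, 500–1000 permutations, 2000 replicates for type-I
calibration. All of these scale up by parameter without code changes.

## Known limitations

- The ROI medians are computed on the subject grid; with real data the
  choice of native vs template space for the medians matters and is the
  user's responsibility (the synthetic design shares one grid, making
  the distinction moot).
- The breath-hold trace generator produces an idealized, compliant
  subject; irregular task performance (missed holds, variable effort) is
  not modeled, though `bh_rise`, noise and timing are configurable.
- The two-sample permutation test uses a pooled-variance t; under strong
  variance heterogeneity between groups its calibration degrades.
- Lilliefors p-values use the table approximation, accurate in the
  0.01–0.2 range that matters for screening.
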