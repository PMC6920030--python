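# Methods

## Signal models and units

Three decay models describe liver signal over the 10-b-value scheme
b = {0, 25, 50, 75, 100, 150, 200, 400, 600, 800} s/mm²:

* mono-exponential S(b) = S₀·exp(−b·ADC);
* bi-exponential (IVIM) S(b) = S₀·[f·exp(−b·D*) + (1−f)·exp(−b·D)], with
  the invariant 0 ≤ D < D* so the compartments are identifiable;
* stretched exponential S(b) = S₀·exp(−(b·DDC)^α), α ∈ (0, 1].

All diffusion coefficients are carried internally in mm²/s (liver D ≈
1e-3, D* ≈ 3e-2), so D and D* can never be silently mixed across the
conventional 10⁻³ scale; only the reporting layer multiplies by 10³. The
perfusion fraction f is stored as a fraction and rendered as percent in
reports; cutoffs for f are likewise printed in percent.

## Fitting

* **ADC₂** is closed-form: ln(S(0)/S(800))/800. A rising curve would give a
  negative coefficient; it is clamped to zero and flagged rather than
  propagated, since a negative ADC has no physical reading.
* **ADC₁₀** is unweighted OLS of ln S on b. Unweighted because nothing in
  the measurement protocol motivates a variance model, and noiseless
  round-trips are exact either way.
* **Segmented IVIM**: D first, from the log-linear slope over b ≥ 200 s/mm²
  (4 points). At that threshold a typical hepatic D* ≈ 33e-3 mm²/s has
  decayed by exp(−6.6), so the high-b segment is essentially
  mono-exponential. Then S₀, f, D* by bounded trust-region least squares
  over all ten points with D frozen — refitting over all b rather than
  reading f off the intercept gap is markedly more stable with only ten
  samples. Bounds: D ∈ [0, 5e-3], D* ∈ [3e-3, 500e-3], f ∈ [0, 0.5]
  (parenchymal f above 50% means vessel contamination, not perfusion).
  Initialization is deterministic (f₀ from the intercept gap, D*₀ = 10·D);
  there are no random restarts, so a curve always fits to the same result.
  One inherent limitation: perfusion not fully decayed above the threshold
  biases D upward by an additive slope offset, worst for slow D* with
  large f (≈ 0.014e-3 mm²/s at D* = 20e-3, f = 0.3); f itself stays within
  0.01 absolute on noiseless curves.
* **Stretched exponential**: bounded least squares in (S₀, DDC, α),
  initialized at DDC₀ = ADC₁₀, α₀ = 0.9. A mono-exponential input
  legitimately pins α at its upper bound 1; that is flagged, not treated
  as failure. Non-convergence anywhere is flagged on the result object and
  surfaces as a missing voxel in maps — never an exception mid-volume.

## Synthetic cohort

The generator emulates the study design the analysis assumes: 12 BA and
5 non-BA patients, two single-slice ROI measurements each, magnitude
images with Rician noise (sqrt((S+ε₁)²+ε₂²), ε ~ N(0, σ), σ = S₀/SNR,
default SNR 50 at b = 0 — a realistic parenchymal SNR for free-breathing
EPI at 1.5 T with three averages).

Per-patient ground truths are drawn log-normally (α logit-normally) around
the published group central values (D 0.835 vs 1.025; D* 33.2 vs 55.3; f
13.4% vs 22.1%; DDC 0.889 vs 1.323, all ×10⁻³ mm²/s; α 0.699 vs 0.556).
Dispersions are set so the distribution's central 95% range matches the
printed group intervals; since those intervals are mixed-model CIs of the
group mean rather than patient-level ranges, this is a deliberately
conservative (tight) spread — synthetic cohorts therefore separate more
cleanly than the clinical one, and simulated AUCs sit near the top of the
published CIs. Laboratory panels are log-normal with the published group
medians and IQR-derived sigmas; sex is Bernoulli with the published group
ratios (4/12 vs 4/5 male).

Phantom geometry is schematic by design: an elliptical liver slab
(128×128 matrix, 8 slices, 2 mm pixels from a 256 mm FOV, 3 mm slices)
with 2–4 cylindrical bright vessels following a high-pseudo-diffusion
profile (f = 0.8, D* = 80e-3), background zero. ROIs are circles of
radius 10 px (≈ 1257 mm², matching reported freehand liver ROI areas)
placed on two distinct slices, constrained vessel-free with bounded
retries (shrinking after repeated failures). The default liver decay is
the bi-exponential model; a stretched-exponential mode is available. What
this phantom does **not** model: anatomy, motion/eddy artifacts, partial
volume, spatially varying coil sensitivity, T1/T2 contrast. Passing tests
therefore validate the estimators and statistics under the assumed noise
model, not robustness to those acquisition effects.

Noise is applied once, at the final magnitude stage; ground truth lives
only in `ground_truth.csv` and never feeds the fitted outputs. Seeding:
one master seed; per-patient streams derive from
`SeedSequence((master, patient_index))`, with a separate stream offset for
volume synthesis, so cohorts are reproducible and patients independent.

For cohort-scale simulation studies (e.g. the 100-replicate direction
check) a fast path, `simulate_roi_curves`, draws the per-voxel Rician
noise for each ROI and averages the curves without rendering full
volumes — statistically identical to an ROI mean over homogeneous
parenchyma and ~400× cheaper than voxelwise map fitting.

## ROI measurement

Default mode fits every ROI voxel and averages the resulting maps
(map-mean), mirroring workstations that render multi-parametric maps
first; the alternative mode fits the ROI-averaged curve. Both are exposed
because the measurement protocol does not determine which a vendor tool
uses; on uniform data they agree to optimizer tolerance. Non-converged
voxels become NaN and are excluded from ROI means (zero-filling would
bias means toward zero); a measurement with over half its voxels missing
is flagged. ROI area = voxel count × in-plane pixel area from the NIfTI
geometry.

A practical note visible in full-volume runs: at SNR 50 the voxelwise D*
map is noticeably biased upward relative to truth (D* is the
classically unstable IVIM parameter; the Rician floor flattens the low-b
segment), while ADCs, f, DDC and α are recovered near their ground
truths. Group *directions* are unaffected.

## Statistics

* **Mann-Whitney U**: exact permutation null (all C(n, n₁) labelings of
  the midranked pooled sample, two-sided by distance of U from its null
  mean — valid under ties) whenever combined n ≤ 20, normal approximation
  with tie correction above.
* **Fisher's exact test**: two-sided by summing hypergeometric
  probabilities ≤ the observed table's.
* **Mixed model**: value ~ group with a random intercept per patient
  (statsmodels MixedLM, REML). Group inference is a Wald z test — the
  fitting backend offers no Satterthwaite small-sample correction, and the
  result records `lmm-wald-z` so readers know p-values at n = 17 are
  slightly liberal. A singular fit (e.g. zero residual variance) falls
  back, flagged, to an equal-variance t test on patient means — which is
  also the analytical limit the mixed model converges to in that case.
* **ROC**: empirical, candidate cutoffs at observed values; AUC is the
  Mann-Whitney probability with ties half-weighted. Youden ties break
  toward higher specificity. Cutoffs are reported as "> x" or "≤ x"
  following each marker's fixed orientation (lower indicates BA for
  ADC₁₀, ADC₂, D, D*, f, DDC; higher for α and γGT).
* **Exact binomial (Clopper–Pearson) intervals** for sensitivity and
  specificity, by beta-quantile inversion, with the exact 0/100 endpoints
  at degenerate counts.
* **DeLong**: placement-value (structural components) covariance for AUC
  CIs and paired curve comparisons; degenerate variance (identical or
  perfectly separating scores) yields p = 1 with a flag instead of a
  division by zero.
* **Unit of analysis**: imaging markers enter ROC per measurement (24 vs
  10 rows), laboratory markers per patient (12 vs 5) — the denominators
  that exact sensitivity/specificity CIs for each marker class imply. The
  paired DeLong matrix needs one common set of observations, so lab
  values are broadcast to their patient's measurement rows there. Both
  unit modes are configurable.
* **Logistic combination**: maximum-likelihood logit of the two
  standardized markers; complete separation is detected (non-convergence
  or exploding coefficients) and flagged, with the separating direction
  recovered by a lightly ridge-penalized refit — the AUC of a separating
  score is 1 regardless of the penalty, so the flag, not the number,
  carries the caveat.
* Two-sided tests, significance at 0.05, no multiplicity correction
  (pairwise DeLong p-values are reported raw).

## Problem sizes in the shipped analyses

The numbered analysis scripts run the full design (17 patients, 128×128×8
volumes, ~630 fitted voxels per patient); the replication study and the
test suite use the fast ROI-curve path (100 cohorts) and reduced matrices
(32–48 px) respectively, which exercise identical code paths at smaller
voxel counts. The acceptance script fits four noiseless single curves and
is deterministic; its `--seed` is accepted for interface uniformity.

## Known limitations

* Printed group intervals are treated as patient-level 95% ranges
  (see above): between-patient spread is understated, so simulated
  diagnostic accuracy should be read as an upper bound.
* The segmented-IVIM D bias and the voxelwise D* noise sensitivity are
  properties of the method, reproduced rather than corrected here.
* The mixed model's z-based inference is anti-conservative at very small
  n; with two patients per group the fallback t test is the safer reading.
* No attempt at anatomical realism, DICOM ingestion, or non-segmented
  4-parameter IVIM as a default (the latter only via configuration).
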