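# liverdwi

Quantitative multi-b-value liver diffusion MRI for the work-up of infantile
cholestasis: model fitting, ROI measurement and diagnostic statistics for
discriminating biliary atresia (BA) from non-BA causes, with a synthetic
cohort simulator so the entire analysis runs with no clinical data.

Biliary atresia is a fibro-obliterative disease of the infant bile ducts in
which early diagnosis matters: delayed surgery worsens liver fibrosis and
outcomes. Diffusion-weighted MRI probes that fibrosis quantitatively. This
package implements the full analysis a radiology research group would run
on a 10-b-value liver DWI protocol (b = 0, 25, 50, 75, 100, 150, 200, 400,
600, 800 s/mm²), for researchers evaluating diffusion parameters as
diagnostic markers.

## Models

Signal attenuation S(b) of liver parenchyma is modelled three ways:

* **Mono-exponential:** S/S₀ = exp(−b·ADC). ADC₁₀ is fit by log-linear
  regression over all ten b-values; ADC₂ in closed form from b = 0 and
  800 s/mm² only.
* **Bi-exponential (IVIM):** S/S₀ = f·exp(−b·D*) + (1−f)·exp(−b·D),
  separating slow water diffusion D from perfusion-driven pseudo-diffusion
  D* with perfusion fraction f. Fitting is segmented ("asymptotic"): D from
  the log-linear slope over b ≥ 200 s/mm² where perfusion has decayed, then
  D* and f by bounded nonlinear least squares with D frozen.
* **Stretched exponential:** S/S₀ = exp(−(b·DDC)^α), with distributed
  diffusion coefficient DDC and heterogeneity index α ∈ (0, 1] (α = 1 is
  mono-exponential diffusion).

Each patient contributes two single-slice ROI measurements (vessel-free
liver parenchyma), so group comparisons use a linear mixed model with a
random intercept per patient. Diagnostic accuracy uses empirical ROC
curves: Youden-optimal cutoffs, exact (Clopper–Pearson) sensitivity and
specificity intervals, DeLong AUC confidence intervals and paired DeLong
tests between markers, and a logistic combination of ADC₂ with the serum
marker γ-glutamyl transferase (γGT).

## Worked example

The `analysis/` scripts run the study end to end on a synthetic cohort
(12 BA vs 5 non-BA infants, SNR 50, two ROIs each):

```bash
python analysis/01_simulate_cohort.py --seed 1   # phantom volumes -> scratch/
python analysis/02_fit_parameters.py             # -> results/measurements.csv
python analysis/03_group_statistics.py           # -> results/table{1,2}.csv
python analysis/04_diagnostic_performance.py     # -> results/table{3,4}.csv
python analysis/05_direction_replication.py      # -> results/direction_replication.json
```

Step 03 prints the mixed-model group comparison (seed 1):

```
            variable                           BA                       non-BA  p_value     method
ADC 10 (1e-3 mm^2/s)          0.927 (0.891-0.963)          1.186 (1.129-1.242)    0.000 lmm-wald-z
 ADC 2 (1e-3 mm^2/s)          1.020 (0.974-1.066)          1.381 (1.310-1.452)    0.000 lmm-wald-z
               f (%)       13.548 (12.238-14.858)       22.887 (20.858-24.916)    0.000 lmm-wald-z
   DDC (1e-3 mm^2/s)          0.830 (0.751-0.909)          1.299 (1.176-1.422)    0.000 lmm-wald-z
               alpha          0.638 (0.616-0.660)          0.510 (0.476-0.545)    0.000 lmm-wald-z
```

i.e. the BA group shows lower ADC₁₀, ADC₂, f and DDC and higher α — the
direction the diffusion markers are expected to separate the groups — and
step 05 reports that these median directions replicate in 100/100
independently seeded cohorts. Step 04 prints per-marker ROC rows such as

```
marker  criterion       sensitivity         specificity                auc
GGT     > 166.1         91.7 (61.5-99.8)    100.0 (47.8-100.0)  0.967 (0.890-1.000)
```

(sensitivity/specificity in percent with exact 95% CIs, AUC with its DeLong
CI), followed by the ADC₂ + γGT logistic combination.

The same pipeline is scriptable as a single command (`liverdwi all --seed 1
--out out/`) and the fitters run on any user-supplied NIfTI + `.bval` data
via `liverdwi fit`.

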