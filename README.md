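# ferriscope

Quantitative MRI iron-overload analysis for transfusion-dependent anemias
(β-thalassemia major), from multi-echo signal decays to cohort-level risk
statistics.

In transfusion-dependent thalassemia, excess iron loads the liver,
pancreas and heart; cardiac iron remains the leading cause of death.
Tissue iron shortens the effective transverse relaxation time T2* of
multi-echo gradient-echo MRI, so organ iron is quantified by fitting

    S(TE) = S0 · exp(−TE / T2*) + C

to the ROI-mean signal across echoes (10 echoes, 2.26 ms spacing by
default). Low T2* means high iron: global heart T2* ≤ 20 ms defines
myocardial iron overload (MIO), pancreatic T2* < 26 ms pancreatic
siderosis, and liver T2* converts to liver iron concentration via
LIC = a·R2* + b. Vitamin D modulates the L-type calcium channels through
which non-transferrin-bound iron enters the myocardium, which is why the
cohort statistics here relate vitamin-D status (deficient < 20,
insufficient 20–29, sufficient ≥ 30 ng/mL) to cardiac iron.

The package is organized for people who build or validate such analysis
chains: medical-imaging scientists, biostatisticians reviewing an iron
study, and methodologists who need a fully synthetic, reproducible
test bed.

## What is implemented

* `ferriscope.relaxometry` — ROI-mean decay extraction; offset-model and
  truncation-model T2* fits (with Rician noise-floor handling); automatic
  model selection for heavily iron-loaded tissue; pancreatic 3-ROI global
  value; configurable LIC calibration.
* `ferriscope.cardiac_mapping` — AHA 16-segment partition (6 basal /
  6 mid / 4 apical equiangular sectors from endo/epicardial contours),
  per-segment fitting, global heart T2*, low-segment count
  (≤ 20 ms counts as low), susceptibility-correction hook.
* `ferriscope.ventricular_function` — Simpson's-rule disc summation,
  ejection fraction, LV mass (1.05 g/cm³), Du Bois/Mosteller BSA indexing.
* `ferriscope.classification` — vitamin-D categories, PTH status, organ
  iron-overload flags; YAML-serializable thresholds.
* `ferriscope.cohort_stats` — normality-routed group comparisons with
  Bonferroni post-hocs; Pearson/Spearman correlation; 2×2 odds ratios
  with Woolf CIs; univariate screen + forward-stepwise regression with
  VIF/tolerance; ROC with DeLong CI and Youden-index cutoff.
* `ferriscope.synthetic_data` — Rician multi-echo phantoms (disc, liver,
  pancreas, 16-segment cardiac annulus) with ground truth, and a
  calibrated Gaussian-copula synthetic cohort (n = 278, groups 75/96/107)
  matching the published group moments, cross-organ correlations and MIO
  prevalence (1/3/23 per group).
* `ferriscope.pipeline` / `ferriscope.cli` — batch image → metrics →
  classification → statistics orchestration with per-patient error
  manifests; CLI: `ferriscope synth|measure|analyze|demo`.

The numbered scripts under `analysis/` run the study stages in order
(phantom relaxometry, cardiac mapping, volumetry, cohort generation,
cohort statistics, multi-seed robustness) and write their tables under
`results/`.

## Worked example

```python
>>> import numpy as np
>>> from ferriscope import EchoSeries, select_fit, default_echo_times
>>> te = default_echo_times()                    # 2.26, 4.52, ..., 22.6 ms
>>> signal = 100 * np.exp(-te / 20.0) + 5.0      # a healthy-heart decay
>>> fit = select_fit(EchoSeries(te, signal))
>>> round(fit.t2star, 3), fit.model, fit.n_echoes_used
(20.0, 'offset', 10)
```

The end-to-end demo generates a cardiac phantom and a synthetic cohort and
runs the whole chain:

```bash
$ ferriscope demo --out demo_out --seed 1
cardiac phantom: global T2* 21.85 ms (truth 22.00), max segment error 3.05%
cohort: MIO OR deficient vs insufficient 8.49 (95% CI 2.46-29.30); ROC AUC 0.838; report in demo_out
```

The first line is the 16-segment map recovered from a noisy (σ/S0 = 0.02)
three-slice annulus phantom — each printed segment error is the deviation
of a fitted segmental T2* from its ground truth. The second line is the
statistics stage on a freshly generated 278-patient cohort: patients with
deficient vitamin D have 8.49-times higher odds of myocardial iron
overload than insufficient-vitamin-D patients (that odds ratio follows
from the calibrated group counts 23/107 vs 3/96), and vitamin D
discriminates MIO with an area under the ROC curve of 0.84 on this seed.

`analysis/05_cohort_statistics.py` prints the full odds-ratio panel from
the published count tables, which is seed-independent:

```
MIO deficient vs insufficient: OR 8.49 (95% CI 2.46-29.30)
MIO deficient vs sufficient: OR 20.26 (95% CI 2.67-153.71)
inadequate vit-D vs hepatic overload: OR 3.41 (95% CI 1.93-5.99)
```

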