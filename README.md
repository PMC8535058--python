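# pclt2 — quantitative T2 analysis of the posterior cruciate ligament

`pclt2` implements a complete quantitative-MRI analysis of posterior
cruciate ligament (PCL) functionality under joint loading, for
musculoskeletal imaging researchers who want a tested, reproducible
version of the pipeline: pixel-wise T2 relaxometry with fit-quality
filtering, centerline-based ligament length and subregion analysis,
insertion-site ROI placement, gray-level co-occurrence (GLCM) texture
features, and the paired unloaded-vs-loaded statistical battery. Because
cadaveric multi-echo data of this kind are rarely shared, the package
ships a synthetic phantom-cohort generator with full ground truth that
reproduces the acquisition geometry and the statistical structure of a
paired loading experiment, and the whole analysis is exercised
end-to-end on it.

## The model

Each voxel of a multi spin-echo acquisition (echo times
TE = 13.8/27.6/41.4/55.2/69.0 ms; 0.4 × 0.4 mm pixels, 3.2 mm
center-to-center slices) is fitted with the mono-exponential decay

```
S(TE) = S0 · exp(−TE / T2)
```

by nonlinear least squares (vectorized Levenberg–Marquardt, log-linear
initialization). Fit quality is gated by the adjusted coefficient of
determination, R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1) with n = 5
echoes and p = 2; voxels with R²_adj < 0.9 are excluded from every
downstream statistic.

From the PCL mask a 3D centerline is extracted (two-pass slab-centroid
construction with spline smoothing), giving the ligament length and the
arc-length 25/50/25 % partition into proximal (PR, femoral), central
(CR) and distal (DR, tibial) subregions. Insertion sites are sampled by
0.5 × 1.0 cm² boxes on the central parasagittal slice, oriented parallel
to the cortical bone interface with one quarter of the height bone-side.
Texture is summarized by four Haralick features (entropy, contrast,
homogeneity, variance) of a GLCM pooled over four in-plane orientations
at a 1-pixel offset, with T2 quantized to integer milliseconds over
0–80 ms.

Unloaded (δ0) and loaded (δ1) acquisitions of each specimen are compared
with the two-tailed paired t-test (length), the exact Wilcoxon
signed-rank test (T2 and texture metrics), and Friedman + Dunn tests
across the three subregions, all at α = 0.01. A noncentral-t power
computation reproduces the a-priori minimum sample size.

## Worked example

```python
from pclt2 import PhantomSpec, generate_cohort, run_study, PipelineConfig

cohort = generate_cohort(PhantomSpec(), n=10, seed=1)   # 10 paired specimens
result = run_study(cohort, PipelineConfig())
print(result.stats.query("roi == 'PCL_ENTIRE' and metric == 't2_mean'")
      [["test", "p_value", "significant"]])
```

prints

```
        test   p_value  significant
18  wilcoxon  0.001953         True
```

i.e. the loading-induced increase in entire-PCL mean T2 is significant
at α = 0.01 — all ten specimens moved in the same direction, and
2/2¹⁰ = 0.001953 is the exact two-sided signed-rank p-value for a
uniformly positive paired response at n = 10. The same study reports the
ligament elongation (paired t, p ≈ 7·10⁻¹⁴ on this cohort) and the full
per-ROI/metric table in `result.table`.

The numbered scripts under `analysis/` run the same machinery as a
narrative: `01_simulate_cohort.py` (cohort + ground truth),
`02_run_study.py` (full paired study, tables under `results/study/`),
`03_validate_estimators.py` (estimator bias/validity, elongation,
variance–SD² consistency), `04_power_and_detection.py` (sample size and
multi-seed detection rates). A thin CLI (`pclt2 simulate/fit/analyze/
study`) wraps the same functions for file-based workflows.

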