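# choroidtrace

Automated measurement of the choroid in enhanced-depth-imaging OCT B-scans,
plus the statistical machinery to evaluate it against manual grading and
against longitudinal clinical markers.

The pipeline:

1. **simulate** — generate ground-truth-known synthetic B-scans (layered
   retina/RPE/choroid/sclera intensities, multiplicative gamma speckle, dark
   vessel ellipses, shadowed column spans), simulated manual-grader calipers
   with normally distributed angular error, and longitudinal cohort tables
   with known choroid-to-renal-marker coefficients.
2. **segment** — median denoising, contrast-limited adaptive histogram
   equalization, polarity-selected axial derivative edge maps, then
   Gaussian-process recursive Bayesian edge tracing of the RPE–choroid
   (RPE-C) and choroid–sclera (C-S) junctions from two endpoint pixels.
   The result is a sub-pixel posterior mean row per column with a posterior
   SD that inflates over occlusions (vessel shadows) and interpolates them.
3. **measure** — choroidal thickness perpendicular to the RPE-C junction at
   fovea-referenced locations (subfoveal, ±2000 µm), thickness parallel to a
   caliper (to mimic manual angular error), the signed measurement angle,
   and choroidal area over a fovea-centered ±3000 µm window. All geometry is
   computed in micron space so angles are anatomical despite anisotropic
   pixels.
4. **evaluate** — agreement between paired manual/automated measurements:
   residuals (automated − manual), MAE, Pearson, ICC(3,1), Passing–Bablok
   regression with rank-based 95 % CIs, Bland–Altman limits of agreement,
   major-discrepancy flagging (|residual| > 32 µm, strict), and unsigned
   within-patient angular deviation series relative to baseline.
5. **cohort-stats** — percent change from baseline, paired t-tests,
   marker correlations, and random-intercept linear mixed-effects models
   (REML) with fully standardized coefficients, Wald CIs, and conditional R²
   (fixed + random variance over total).

## CLI

```bash
choroidtrace simulate --out-dir out/sim --seed 1
choroidtrace segment --image out/sim/bscan.png \
    --rpe-endpoints 0,293,767,305 --cs-endpoints 0,411,767,390 \
    --fovea-col 384 --out-dir out/seg
choroidtrace measure --rpe-trace out/seg/trace_rpe_c.csv \
    --cs-trace out/seg/trace_c_s.csv --fovea-col 384 \
    --offsets -2000,0,2000 --out out/measures.csv
choroidtrace evaluate --pairs pairs.csv --threshold 32 --out out/agreement.json
choroidtrace cohort-stats --table out/sim/cohort.csv --response egfr \
    --choroid auto_ct --out out/lme.json
```

Endpoint pixels for `segment` are supplied manually as `x1,y1,x2,y2`
(column, row); `tracer.suggest_endpoints` offers a heuristic but endpoint
selection is by design a manual step. Tracer and preprocessing parameters
can be set in a flat `key=value` config file passed with `--config`.

Conventions: 0-based indices, row 0 at the image top, columns increasing
temporal→nasal (right eye); traces are CSV `(column, row_subpixel, sd_px)`;
all reported lengths are physical (µm, mm²).

## Layout

```
src/choroidtrace/
  core.py        shared dataclasses (BScan, BoundaryTrace, Segmentation, ...)
  synthetic.py   synthetic scans, simulated graders, cohort generator
  preprocess.py  median / CLAHE / edge maps
  tracer.py      GP regression, KDE evidence, recursive Bayesian tracer
  metrics.py     thickness, angle, and area measurements
  agreement.py   residuals, ICC(3,1), Passing–Bablok, Bland–Altman, flags
  longitudinal.py percent change, paired t, correlations, mixed models
  io.py          image/CSV/JSON readers and writers, config parsing
  cli.py         click command group
```
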