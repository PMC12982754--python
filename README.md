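# exposcreen

Untargeted screening of area-level chemical exposures against area-level
diagnosis rates — an ecological, hypothesis-generating exposome scan.

## The problem

Thousands of industrial chemicals are released into air and water, and
most have unknown health consequences. Individual-level exposure data
are scarce, so a practical first pass asks an area-level question: do
zip codes with higher modelled exposure to a chemical also show higher
rates of particular diagnoses? Associations found this way are *not*
causal (ecological fallacy, care-seeking artifacts, co-linear
toxicants), but they prioritize chemicals and diseases for mechanistic
follow-up. `exposcreen` implements that screening engine, end to end,
with a synthetic-data generator so every stage is testable without any
restricted registry data.

## What it computes

1. **Exposure features** (`exposcreen.geo`). Facility releases are
   spread over a 30-mile catchment around each zip centroid with a
   Gaussian distance kernel. Because the zip marks the *provider*, not
   the patient, the kernel width comes from the half-normal mean
   relation: if travel distance is |X|, X ~ N(0, σ²), and the mean trip
   is 8.6 miles, then σ = 8.6·√(π/2) = 10.7785 miles. Exposure of zip
   z to chemical c is the population- and kernel-weighted mean

       E_zc = Σ_i A_ic · P_i · φ(d_zi; σ) / Σ_i P_i · φ(d_zi; σ)

   over facilities i within 30 miles (0 if none). Water measurements
   count only toward the monitor's own zip and are averaged across
   registries; unmonitored zips are absent, not zero.
2. **Diagnosis rates** (`exposcreen.rates`). rate = diagnosis count /
   total billed diagnoses per zip × ICD code × age stratum, with
   registry-style exclusions (zips under 10,000 people, codes under
   10,000 national counts, codes in fewer than 2% of zips).
3. **Non-spatial screen** (`exposcreen.nonspatial`). Per outcome ×
   stratum × medium, a Gaussian elastic net (α = 0.5) over all z-scored
   exposures plus sociodemographic covariates; λ picked by 10-fold
   CV-MSE argmin over a 100-point log path. Any per-zip column
   (deprivation, % ethnicity, redlining score) can be the outcome.
4. **Spatial screen** (`exposcreen.spatial`). A four-level nested
   clustering of centroids (complete linkage on great-circle distances,
   cut at ~81/27/9/3 zips per cluster) feeds a univariate
   negative-binomial mixed model per disease × chemical:
   log μ = offset(log visits) + β·x + covariates + u₁+u₂+u₃+u₄,
   fitted by a Laplace approximation (penalized IRLS inner loop,
   bounded derivative-free outer search over variances and θ).
5. **Association filtering** (`exposcreen.associations`). No p-values
   from the elastic net, so coefficients are flagged when more than
   2 SD from the pooled coefficient mean (5 SD for display), plus ICD
   letter-code tallies.
6. **Enrichment** (`exposcreen.enrichment`). Flagged toxicants are
   tested per protein against a toxin→protein interaction map
   (right-tailed Fisher exact, BH-FDR < 0.05), and the implicated
   proteins against GMT gene-set libraries.

## Worked example

```bash
exposcreen simulate --out demo --seed 11
exposcreen exposure --zips demo/zips.csv --releases demo/releases.csv \
    --medium air --out demo/air.csv
exposcreen rates --counts demo/diagnosis_counts.csv --totals demo/totals.csv \
    --zips demo/zips.csv --min-zip-population 0 --min-national-count 0 \
    --out demo/rates.csv
exposcreen fit-nonspatial --rates demo/rates.csv --exposure demo/air.csv \
    --zips demo/zips.csv --seed 17 --out demo/coefs.csv
exposcreen filter --coefs demo/coefs.csv --out demo/flags.csv
```

which prints, for the bundled default simulation:

```
wrote synthetic dataset to demo
wrote exposure matrix (300 zips x 20 chemicals)
wrote 6000 rate rows
wrote 920 coefficient rows
24 of 920 records pass at 2.0 SD
```

The 6,000 rate rows are 4 diseases × 5 age strata × 300 zips; the 920
coefficient rows are one β (and exp(β), the displayed "odds ratio")
per predictor — 20 chemicals, 21 age bins, deprivation, density,
lat/lon, and the intercept — for each of the 20 outcome × stratum
fits; the 24 records passing the 2-SD filter are the associations the
screen would forward to enrichment. The same library calls are available in Python
(`exposcreen.nonspatial.screen_all`, `exposcreen.spatial.spatial_screen`,
...), which is how the test suite drives them.

## Caveats

Everything this package reports is an area-level association. See
`docs/methods.md` for the model assumptions, the synthetic generator's
scope, and known limitations.
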