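# prsimpact

Tools for quantifying how much a polygenic risk score (PRS) adds to
conventional cardiovascular disease (CVD) risk prediction, and what that
gain could mean for a national statin-allocation screening programme.

The package is aimed at biostatisticians and genetic epidemiologists who
work with survival-type risk prediction models. It implements the full
analytic chain:

1. **Cohort modelling** — cause-specific Cox proportional-hazards models
   stratified by study centre and sex, with Breslow baseline survival and
   t-year absolute risk prediction, plus competing-risk cumulative
   incidence and partial likelihood-ratio tests for nested models.
2. **Incremental-value metrics** — Harrell's C-index pooled over strata
   with jackknife confidence intervals, the change in C (ΔC) when PRSs are
   added, continuous and categorical net reclassification indices (NRI)
   with inverse-probability-of-censoring weighting, and calibration
   (deciles, slope, RMSE, Greenwood–Nam–D'Agostino test) from
   cross-validated predictions.
3. **Recalibration** — rescaling predicted risks so that, within each
   5-year age band × sex group, the mean predicted 10-year risk matches
   the risk expected from an external incidence table (a primary-care
   population), preserving rank order within groups.
4. **Screening impact** — standardizing the risk distribution to a
   population of 100,000 adults aged 40–75, then comparing *blanket* PRS
   assessment with *targeted* assessment of the intermediate-risk band
   (5% to <10% predicted 10-year risk) under guideline statin rules:
   treat at ≥10% risk, treat unconditionally with diabetes or LDL ≥ 5
   mmol/l, assume a 20% relative risk reduction. Outputs are
   reclassification flows, events prevented and the number needed to
   screen (NNS).
5. **Synthetic data** — a generator producing cohorts with the assumed
   statistical structure (correlated risk factors, two PRSs with
   correlation 0.32, per-SD hazard ratios 1.57 for the CHD score and 1.19
   for the stroke score, ≈2% first CVD events over 10 years), so every
   stage runs at desk scale without individual-level biobank data.

## The model in brief

For cause *k* (CHD, stroke, non-CVD death) with predictors *x*, the hazard
for individual *i* in stratum *s* (centre × sex) is

    λ_ks(t | x_i) = λ0_ks(t) · exp(β_k' x_i)

Ten-year risk is `1 − S0_s(t)^exp(β'(x_i − x̄))` with the Breslow baseline
anchored at the training means. The two PRSs enter the CVD model as two
separate linear terms. Recalibration to a target population replaces each
individual's cumulative hazard Λ_i = −log(1 − p_i) with k_g·Λ_i, where k_g
solves `mean(1 − exp(−k_g Λ_i)) = π_g` within group g and π_g comes from
the incidence table. Impact arithmetic: events prevented = RRR × (expected
events among up-movers − among down-movers), reported rounded up;
NNS = screened / unrounded prevented, rounded to the nearest integer.

## Worked example

```bash
prsimpact run --out-dir demo --seed 1
```

runs the whole chain on a default synthetic cohort (n = 10,000, 8 centres)
and prints:

```
PRS incremental-value pipeline summary
cohort n=10000, CVD events=210
C (conventional) = 0.7228, C (+PRS) = 0.7312, delta C = 0.0084 (-0.0066 to 0.0233)
continuous NRI: cases 10.1%, non-cases 17.1%
calibration slope 0.792, GND p 0.253
targeted_prs: screened 22873, prevented 85 events, NNS 271
blanket_prs: screened 100000, prevented 32 events, NNS 3212
```

Reading the output: adding the two PRSs raises the stratified C-index by
0.0084 (the 95% CI spans zero at this small cohort size); about 10% of
future cases saw their predicted risk appropriately move up. After
recalibration to the synthetic primary-care incidence table, screening the
~23,000 intermediate-risk individuals per 100,000 adults with a PRS
prevents one event per 271 screened, roughly twelve times more efficient
than blanket screening of all 100,000 (NNS 3212). A machine-readable
`report.json` with every metric block, the reclassification flow tables and
the recalibration factors is written next to the summary.

The same stages are available as library functions (`generate_cohort`,
`fit_cox`, `delta_c_jackknife`, `continuous_nri`, `recalibrate_model`,
`run_impact`, …) and as individual CLI subcommands `simulate`, `fit`,
`evaluate`, `recalibrate` and `impact`.

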