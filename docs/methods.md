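# Methods

This note records the statistical model, the synthetic-data assumptions,
the numerical conventions and the open design choices behind `prsimpact`.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Survival model

All risks come from cause-specific Cox proportional-hazards models,
stratified by study centre and sex, with time since study entry as the
timescale. Ties are handled with the Efron approximation (the standard
choice for cohort data recorded at daily or coarser resolution). The
baseline cumulative hazard per stratum is the Breslow estimator evaluated
at the per-stratum mean linear predictor, so the t-year absolute risk of an
individual is

    risk_i(t) = 1 − exp(−H0_s(t) · exp(β'(x_i − x̄)))

which makes the "record at the covariate means has risk 1 − S0(t)" identity
exact. Delayed entry is not implemented. A Schoenfeld-residual diagnostic is
exposed (`RiskModel.schoenfeld_diagnostic`) but is advisory, never a gate.
The two polygenic scores always enter the CVD model as two separate linear
terms; they are never combined into a single score beforehand.

Zero-variance predictors are retained with coefficient 0 and infinite
standard error rather than failing the fit; complete separation or
non-convergence raises a `FitError` with the underlying diagnostic.

Competing-risk cumulative incidence uses the discrete product-integral
form on the merged grid of baseline jump times,

    S(u_j) = Π_{l≤j} (1 − dA1_l − dA2_l),   CIF_k = Σ_j S(u_{j−1}) dA_{kj},

so `CIF_CVD + CIF_death + S = 1` holds exactly (to machine precision)
rather than only asymptotically. Against a constant-hazard closed form the
discretization error is far below 1e-3 for grids of ≥500 points.

## Discrimination

Harrell's C is computed within strata and pooled: a pair is comparable only
if both members share a stratum and the earlier follow-up time ends in an
event; ties in follow-up time make a pair non-comparable, and ties in score
count one half. The risk score used is the linear predictor, which is
monotone in t-year risk within a stratum, so C does not depend on the
horizon.

Confidence intervals use the jackknife on the pair-count aggregates:
per-individual numerator and denominator contributions are accumulated
once, so each leave-one-out C is exact at O(1) additional cost. Above
5,000 records a grouped jackknife (default 100 randomly permuted groups,
seedable) replaces exact leave-one-out; within-group pair sums are
subtracted so grouped replicates are also exact. ΔC between nested models
removes the same units from both C computations, giving the paired-
difference variance directly. The grouped construction was chosen because
the "efficient jackknife" cited for this estimator is not specified in
detail anywhere we could follow; exact LOO at small n and grouped LOO at
large n preserves consistency at tractable cost, and the suite checks the
jackknife SE against a 2,000-replicate bootstrap at n = 200 (within 25%).

Internal/external validation fits the model on all-but-one subset (one
recruitment centre, or one random fold) and evaluates C in the held-out
subset, stratified by sex; subset C values are pooled weighted by the
number of events in the subset. Subsets without events are excluded with a
warning.

## Reclassification

Case/non-case status at the horizon uses inverse-probability-of-censoring
weights: cases (event by horizon t) weigh 1/G(T−), known non-cases
(followed beyond t event-free) weigh 1/G(t), with G the Kaplan–Meier
estimate of the censoring distribution; records censored before the
horizon get weight zero. Without censoring this reduces *exactly* to
direct counting, which the tests pin. Confidence intervals come from a
seeded 200-replicate bootstrap. The reclassification horizon defaults to
9 years (risk-model horizon 10), reflecting the shorter follow-up
available for reclassification analyses in the motivating study design.

Risk categories are left-closed, right-open: NICE <5%, 5–<10%, ≥10%;
ACC/AHA <5%, 5–<7.5%, ≥7.5%.

## Calibration

Predictions for calibration come from 10-fold cross-validated refits to
avoid optimism. Observed risk per prediction decile is the Kaplan–Meier
estimate at the horizon with Greenwood variance; the GND statistic is
Σ (KM_g − p̄_g)² / Var(KM_g) on chi-square with (groups − 1) degrees of
freedom. Groups whose KM variance is zero (no events) are merged into the
neighbouring group, with a warning and a count in the report. The
calibration slope is the OLS slope of observed on mean predicted risk
across groups (with intercept); RMSE is over group means. The chi-square
approximation needs reasonably large groups (hundreds of subjects); the
uniformity of its p-values under a correct model is tested at that scale.

## Recalibration

Expected risk in the target population follows attained age across the
incidence table's piecewise-constant bands:
`π(age) = 1 − exp(−Σ_b rate_b · overlap_b)`. Per (5-year age band × sex)
group, a single multiplicative factor k_g on the cumulative-hazard scale is
solved by Brent's method (bracketed from [0, 10^12], xtol 1e-13) so the
group's mean recalibrated risk equals the group's mean table-derived
expected risk. This scale was chosen because it keeps risks in [0, 1],
never reorders individuals within a group, and is idempotent — properties
the tests pin to 1e-6/1e-8. Groups missing from the reference cohort get
factors interpolated linearly over band midpoints within sex, with a
warning. The incidence generator emits bands up to age 90 so that 10-year
horizons of 74-year-olds stay inside the table's support.

## Screening impact

The reference cohort is projected onto a standardized population (default
100,000, UK-like age/sex profile, largest-remainder rounding so totals are
conserved exactly). People with diabetes or LDL ≥ 5.0 mmol/l are treated
unconditionally and leave the screening pool first. Strategies:
`conventional_only` reassesses nobody (screened = 0), `targeted_prs`
reassesses the pool members whose conventional-model risk lies in the
targeting band (default 5% to <10%), `blanket_prs` reassesses the whole
pool but counts the entire standardized population as screened — matching
the two published NNS denominators. Expected events per cell use the best
available predicted risk (the augmented model's where reassessment
happened, the conventional model's elsewhere).

Rounding ledger, pinned by tests because the published worked example is
mutually consistent only under these rules: reported prevented events =
ceiling of RRR × net up-mover events (71.4 → 72; 1,010.8 → 1,011); NNS =
nearest integer of screened / unrounded prevented (335.76 → 336;
5,747.13 → 5,747). A negative net (more expected events de-treated than
treated) is allowed and reported as harm; an NNS with zero or negative
prevented events is explicitly undefined (`None`), never infinity.

## Synthetic-data generator

Continuous predictors are drawn jointly Gaussian with a configurable
correlation matrix; age passes through a truncated-normal copula so it
stays inside 40–75 while preserving rank correlations; smoking and
diabetes threshold latent Gaussians at their prevalences (10.3%, 1.2%).
Defaults emulate a CVD-free, statin-free middle-aged cohort: mean age 56
(SD 8), 57% female, SBP 136.9 (19.1) mm Hg, total cholesterol 5.9 (1.1),
HDL 1.5 (0.4), LDL 3.7 (0.8) mmol/l, ln-CRP 0.3 (1.1). The PRS–PRS
correlation is 0.32; the PRSs are independent of the conventional factors,
and the remaining pairwise correlations (lipids with each other and age,
CRP with adiposity-adjacent factors) are modest, epidemiologically
plausible free parameters — the joint distribution is not identified by
published marginals, so these were fixed once and not tuned.

Event times are cause-specific exponential by default (Weibull optional)
via inverse-transform sampling; the first event before the administrative
censoring horizon (default 10 years) determines the outcome. Per-SD log
hazard ratios default to ln(1.57) for the CHD score on CHD and ln(1.19)
for the stroke score on stroke, with conventional-factor effects in the
familiar ordering (age dominant); baseline hazards are set so a default
cohort accrues roughly 2% first CVD events over the horizon. Centres are
assigned uniformly and carry no true effect, so stratification machinery
is exercised without confounding.

What the generator does *not* emulate: staggered entry and loss to
follow-up (censoring is purely administrative), measurement error,
non-log-linear or time-varying effects, secular trends, regional
differences between centres, and any genotype-level structure (the PRSs
are abstract standardized scores, not sums over variants). Passing tests
therefore demonstrate the correctness of the estimators and the pipeline
under the assumed data-generating model, not the real-world predictive
performance of any particular score.

## Problem sizes and numerical conventions

Default pipeline size is n = 10,000 with 8 centres; unit tests use
2,000–6,000; parameter-recovery checks use single cohorts of 50,000
(hazard ratios) and 100,000 (PRS correlation), and the acceptance script
pools three 50,000-person replicates by inverse variance. These sizes give
standard errors several times smaller than the acceptance tolerances while
keeping a full run in seconds to a couple of minutes on one core. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; reports are JSON with sorted keys so identical
configurations are byte-identical. Degenerate inputs (no events, no
comparable pairs, no cases or non-cases by the horizon, zero-variance
groups) raise informative errors or merge with warnings as described
above rather than returning silent NaNs.

## Known limitations

- The C-index pair counting is quadratic per stratum; it is fast for
  stratified cohorts of tens of thousands but not intended for a single
  stratum of millions.
- The NRI confidence interval is a plain bootstrap; an influence-function
  variance would be cheaper at very large n.
- Recalibration assumes the incidence table refers to the same outcome
  definition as the model's event labels; no harmonisation is attempted.
- The impact model treats statin uptake and adherence as perfect and the
  relative risk reduction as homogeneous; both overstate achievable
  population benefit.
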