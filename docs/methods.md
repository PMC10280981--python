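# Methods

`npsmap` implements an analysis pipeline relating neuropsychiatric
subsyndromes to cortical thickness and white-matter-hyperintensity (WMH)
burden across five diagnostic groups (AD/MCI, ALS, FTD, PD, CVD). This
note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data tests do and do not
demonstrate.

## Subsyndrome scoring

The 12 NPI-Q items carry informant-rated severities 0–3 (0 = absent) and
study-partner distress 0–5. Items are grouped into four composites:

| subsyndrome   | items                                                              | max |
|---------------|--------------------------------------------------------------------|-----|
| hyperactivity | agitation, euphoria, irritability, disinhibition, aberrant motor   | 15  |
| psychotic     | hallucinations, delusions, night-time behaviours                   | 9   |
| affective     | depression, anxiety                                                | 6   |
| apathy        | apathy, appetite                                                   | 6   |

Each subsyndrome score is the sum of its item severities, so total
severity decomposes exactly into the four composites — an identity the
test suite checks on 10,000 random records. Night-time behaviours are
grouped with the psychotic items; variants of the EADC grouping differ on
this point, and the convention here follows the study design the package
emulates. Records with missing items are rejected by default; a
`skip_missing` flag treats missing severities as 0 (documented, off by
default) because the handling of partial questionnaires in the source
analyses is unknown. The vascular-risk burden is the count (0–4) of
hypertension, diabetes, high-cholesterol, and smoked-3-months flags.

## WMH normalization

Periventricular and deep WMH parcels are summed into five regions
(frontal, parietal, temporal, occipital, basal ganglia/thalamus) per
hemisphere. Each regional volume x (mm³) is corrected and transformed as

    log((x / STTIV) + 0.0001)

where STTIV is the supratentorial total intracranial volume. The additive
constant applies to the volume *fraction* (not raw mm³), which makes the
transform invariant to a joint rescaling of x and STTIV and bounds it
below by log(1e-4) ≈ −9.2103, attained exactly at x = 0. The log base is
natural by default — downstream analyses z-score these columns, so base
only changes a constant factor — with base 10 available and recorded in
output metadata. Because it is unstated whether published regional
summaries are hemisphere-summed, `regional_summaries` reports both
per-hemisphere and summed means.

## Contingency comparisons from printed tables

Raw participant data are not redistributable, but the published per-group
symptom frequencies are printed as "count (percent)". Group denominators
are recovered as `round(100·count/percent)`; a warning is attached when
the implied percentage disagrees with the printed one by more than 0.05
points. Group differences use Pearson chi-square with **no continuity
correction** (required to reproduce the published statistics), and
pairwise contrasts use the two-sided Fisher exact test under the
probability-mass convention (all tables with the same margins whose
probability does not exceed the observed table's), the convention of
mainstream statistical software. Two published contrasts (apathy FTD vs
ALS, euphoria FTD vs PD) cannot be reproduced from the printed counts
under any two-sided convention we tried; the report flags them as
discrepant rather than forcing agreement.

The association of vascular burden with total WMH load is an OLS fit of
z-scored outcome on z-scored exposure plus covariates (age, sex), with a
95% t-based CI on the standardized coefficient.

## Consensus elastic net

Each subsyndrome is modelled from 82 predictors: two sex indicators
(female, male — both kept, matching the published coefficient tables),
age, MoCA, 68 Desikan-Killiany thickness values, and 10 normalized WMH
volumes. The procedure per repeat:

1. stratified 75/25 train/test split over the ten sex-by-dx cells,
   largest-remainder rounding so the train size equals round(0.75·n)
   exactly;
2. 10-fold stratified cross-validation on the training portion selects a
   penalty by minimum mean held-out MSE, ties broken toward the larger
   (more parsimonious) lambda;
3. every grid lambda is refit on the training portion and evaluated on
   the held-out quarter; the repeat records the test-MSE-minimizing
   lambda (`selection="test"`, default) or the CV winner
   (`selection="cv"`) — the published description is ambiguous between
   the two, so both are exposed.

Over 500 repeats (default), lambdas recorded in at least
ceil(0.05·repeats) repeats are retained and refit on the full sample; the
union of their non-zero predictors is the consensus variable set, and the
coefficient table has one column per retained lambda headed
"lambda (count/repeats)".

Numerical conventions: the penalty follows the glmnet parameterization
(objective RSS/(2n) + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²)), α = 1 (pure lasso) by
default; predictors are standardized internally (population SD) and
coefficients reported on the original scale; the grid is 100 log-spaced
values from λ_max down to 1e-4·λ_max **plus an explicit sentinel λ =
1000**, far above λ_max, whose full-sample fit is exactly the
intercept-only model (intercept = outcome mean, all coefficients 0).
The grid is computed once from the full sample and shared across repeats:
consensus counting requires repeats to land on identical lambda values,
which a per-repeat data-driven grid cannot produce. Coordinate descent is
scikit-learn's `enet_path`; at λ = 0 on a full-rank overdetermined design
the fit matches OLS to 1e-6 (tested).

A caveat the test suite makes explicit: under a pure-noise outcome with
the full dense grid, internal CV selects a non-trivial lambda in roughly
a quarter to a third of datasets (a chance predictor validates across
folds of the same sample). Intercept-only dominance under the null is
therefore asserted at the consensus level (the sentinel is the modal
retained lambda) and, for the CV step in isolation, under a strong
penalty grid where the parsimony tie-break applies.

## PLS correlation

Both blocks are column-wise z-scored; the cross-block matrix
R = XᵀY/(n−1) is decomposed by SVD, R = U S Vᵀ. Columns of U and V are
the predictor and outcome saliences (orthonormal), the singular values
s₁ ≥ … ≥ s₄ measure shared variance, and variance explained is
sᵢ²/Σsⱼ² (squared base, the standard convention; a raw-singular-value
base is available via `variance_base="raw"`). Latent scores are XU and
YV; cov(Lxᵢ, Lyᵢ) = sᵢ exactly. Signs are fixed so the
largest-magnitude entry of each V column is non-negative. The exact
collinearity of the two sex indicators is tolerated — this is an SVD,
not a regression.

Permutation test: rows of Y are permuted within sex-by-dx strata, the
decomposition refit (z-scores are permutation-invariant, so only the
cross-product is recomputed), and each component's p-value is the add-one
estimator (1 + #{s_perm ≥ s_obs})/(1 + n_perm), comparing null singular
values at the same component index. An optional rotation mode projects
each null cross-block matrix onto the observed saliences
(sᵢ_null = ‖R_perm vᵢ‖); it is off by default as the simplest defensible
choice is index-matched comparison.

Bootstrap ratios: rows are resampled with replacement within strata;
replicate saliences are matched to the original by maximal absolute inner
product of the stacked (U; V) columns (Hungarian assignment) and
sign-aligned; the BSR is the original salience divided by the SD of the
aligned replicate saliences (ddof = 1). |BSR| ≥ 2 marks a stable
contributor. Replicates with a zero-variance column are dropped and
counted; more than 10% dropped is an error. Defaults n_perm = 5000 and
n_boot = 1000 are the package's own choices (the published analysis
states neither); the smallest published component p-value implies at
least ~2,500 permutations were used there.

## Synthetic cohort generator

The generator emulates the tabular structure the analyses assume; it is
the test bed, not a simulation of imaging. Defaults are fixed at the
study conditions: sex-by-dx margins (52/65, 16/23, 19/32, 31/107, 46/99;
n = 490) are exact, not sampled; per-group age and MoCA means/SDs follow
the published cohort summaries; thickness is Gaussian per region
(baseline 2.5 mm, SD 0.15 mm) with a −0.15 mm offset in FTD and AD/MCI
(mild global atrophy, realism only, configurable); raw regional WMH
volumes are log-normal with regional locations ordered
frontal/parietal > occipital/temporal > BGT and a CVD-highest group
offset (+0.8 log units; PD +0.2); STTIV ~ N(1.4e6, 1.3e5) mm³; vascular
flags are Bernoulli at roughly the published marginal prevalences.

NPI-Q items arise from four latent subsyndrome propensities: each is a
linear combination of z-scored predictors (the `effect_spec`, empty by
default = null cohort) plus N(0, noise_sd²) noise, divided by the number
of items k in the subsyndrome, plus per-item N(0, 0.5²) noise, rounded
and clipped to 0–3. Dividing by k preserves the summation identity the
scoring relies on; the item-noise SD of 0.5 puts the default subsyndrome
means in the published 0.5–2 range. Distress is severity plus unit noise,
clipped to 0–5 and zeroed where the symptom is absent. An optional
`wmh_vascular_beta` plants a standardized association between vascular
burden and log total WMH load by scaling volumes with
exp(slope · z_burden), with the slope calibrated so the planted
correlation equals the requested coefficient.

What the generator does **not** emulate: spatial covariance among
neighbouring regions beyond the shared diagnosis offsets, site effects,
missing-data mechanisms (complete data by default; a `missing_rate` is
configurable), longitudinal visits, and any genuine biology linking
thickness to symptoms — effects exist only where planted. Passing
recovery tests therefore show the *machinery* is calibrated and can
detect effects of the stated size under these conditions, not that the
published real-data coefficients are reproducible (they are not, absent
raw data).

One structural consequence worth knowing: the diagnosis offsets make
thickness and WMH columns mutually correlated through group membership,
so once an effect is planted on one predictor, other predictors are
*not* independent of the outcomes. Independence-based checks use a spec
with the group offsets removed.

## Simulation sizes and runtime

Simulation-based checks use sizes chosen as the package's own balance of
Monte-Carlo error against runtime: permutation calibration 200 null
cohorts × 1,000 permutations (rejection rate at α = 0.05 asserted within
[0.03, 0.07]); consensus recovery 20 cohorts × 100 repeats (planted
standardized effect 0.5 selected at every retained non-sentinel lambda
in ≥ 90%); bootstrap recovery 100 cohorts × 500 replicates (planted
contributor at |BSR| ≥ 2 in ≥ 95%). The full production configuration
(500 repeats, 5,000 permutations, 1,000 bootstraps) runs in minutes on a
single CPU via the `npsmap run` pipeline.

## Known limitations

- The published pairwise Fisher p-values that disagree with the printed
  counts (apathy FTD > ALS, euphoria) are flagged, not resolved; the
  discrepancy presumably reflects differing denominators or a one-sided
  convention in the original analysis.
- Consensus counting assumes a shared lambda grid; with per-repeat grids
  the retention rule is undefined.
- BSRs are approximate z-statistics; for weakly identified components
  the alignment step can shrink the bootstrap SD and inflate ratios, so
  stability under a null component should not be over-interpreted.
- The OLS standardized beta treats the exposure as continuous; the
  vascular burden count has only five levels.
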