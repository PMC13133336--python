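# Methods

`pacteval` evaluates avoided-deforestation carbon credits the way independent
impact evaluations do: by constructing an *ex post* counterfactual from
matched untreated pixels and comparing it both to what the project actually
experienced and to what the project's certified (*ex ante*) baseline claimed.
Because no real remote-sensing archive ships with the package, every stage is
validated against a synthetic landscape whose counterfactual is simulated
explicitly and is therefore known exactly.

## The estimation problem

A REDD+ (Reducing Emissions from Deforestation and forest Degradation)
project claims credits for the difference between observed deforestation
inside its boundary and a counterfactual baseline. Certified baselines are
modelled *ex ante* from historic deforestation in project-selected reference
areas; quasi-experimental evaluations instead measure outcomes *ex post* in
statistically matched control areas. The package implements the
pixel-matching estimator of the PACT (Permanent Additional Carbon Tonne)
family, the rate algebra needed to compare heterogeneous measurements, and
the statistics used to quantify and decompose over-crediting.

## Synthetic landscape generator

The generator emulates the features of real evaluation data that matter to
the estimator, in a planar metre-based CRS:

- **Covariates.** Elevation is Gaussian-filtered white noise (length-scale
  `smoothness`, default 1000 m) rescaled to a ~300 m standard deviation
  around 500 m; slope is the gradient of that surface in degrees (so the two
  covary, as in real terrain); accessibility (travel time to the nearest
  population centre, minutes) is an independent log-normal smoothed field
  with median ~60 min. Country and ecoregion are contiguous nearest-seed
  partitions. All fields are spatially autocorrelated; the infinite
  `smoothness` limit flattens them to constants.
- **Hazard.** Each pixel's annual probability of leaving the undisturbed
  class is `expit(intercept + Σ β_k z_k + ε)` on grid-standardised
  covariates, with β = (−0.4, −0.3, −0.5) for elevation, slope and
  accessibility: pressure rises toward low, flat, accessible terrain. The
  static pixel-level log-odds noise ε ~ N(0, 0.1²) stands for drivers the
  covariates do not capture; it is deliberately modest so the matching
  covariates carry most of the confounding. The default intercept puts the
  mean hazard near 2 %/yr.
- **Land-cover dynamics.** Classes follow the annual-change-collection
  convention (undisturbed, degraded, deforested, regrowth, water, other).
  A converting pixel becomes degraded with probability
  `degradation_fraction` (default 0.3) — remaining degraded for 2 annual
  layers (a disturbance shorter than 2.5 years) and classed as regrowth from
  the third year — otherwise it is permanently deforested. Undisturbed is
  never re-created, so deforestation measured as loss of the undisturbed
  class is insensitive to the degradation branch.
- **Treatment and ground truth.** Inside the project polygon, after the
  start year t0, the factual arm's hazard is multiplied by
  `treatment_multiplier` (default 0.5). Factual and counterfactual arms
  consume the same uniform draws (common random numbers), so they are
  identical up to t0 and outside the project at all times, a multiplier of 1
  reproduces the counterfactual exactly, and lowering the multiplier is
  pixel-wise monotone in avoided forest loss. True avoided deforestation is
  the per-year difference in undisturbed area between the arms inside the
  project.
- **Siting bias.** The project rectangle is centred in a neighbourhood whose
  mean hazard is at or below the `siting_bias` quantile of candidate
  neighbourhoods and the reference rectangle at or above the complementary
  quantile — reproducing the field observation that reference areas are more
  exposed to deforestation drivers than projects. The bias quantile is a
  scenario knob (default 0.5), not an estimate of any real project's bias.

What the generator does *not* emulate: leakage/spillover into control areas,
classification error in the land-cover product, biomass or carbon density,
geographic projections, or temporally varying drivers (hazard fields are
static apart from the treatment). Passing tests therefore demonstrate
internal validity of the estimator under covariate-driven confounding with
known functional form — not robustness to hidden confounders or leakage,
which real evaluations must argue separately.

## The matching estimator

Project pixels are sampled on a regular lattice at 0.25 points/ha (0.05
above 250,000 ha). Each unit carries continuous covariates — elevation,
slope, accessibility, and proportional cover of the undisturbed and
deforested classes within a 1 km disc at t0, t−5 and t−10 — and categorical
covariates: country, ecoregion, and land-cover class at the same three
epochs. Untreated candidates must share a country and ecoregion with the
project, lie 5–2000 km from it (and ≥ 5 km from every project), and fall
inside the project's observed covariate ranges widened by fixed tolerances
(±200 m elevation, ±2.5° slope, ±10 min accessibility, ±10 points
proportional cover).

Each of 100 bootstrap iterations matches a fresh random 10 % project
subsample 1:1 to candidates, greedily and without replacement: units are
processed in a seeded random order, each paired with the unused candidate of
identical categorical covariates minimising the Mahalanobis distance over
the continuous covariates. An iteration is kept only if every covariate's
standardised mean difference (SMD, difference of means over the square root
of the mean of the two variances) lies within ±0.25, and if it produced at
least 30 pairs (a small-sample guard). For each kept iteration and year, the
undisturbed proportion of the project and control sides times the project
area gives forest-cover series; their divergence since t0, averaged over
iterations, is the cumulative avoided-deforestation estimate.

Numerical choices:

- The Mahalanobis covariance is estimated once per run from the union of the
  full project sample and the candidate pool, and Cholesky-whitened so the
  greedy step reduces to squared Euclidean distance; a ridge of
  `1e-6 · trace/d` is added if the covariance is not positive definite
  (logged, not fatal).
- Exact distance ties break to the lowest (row, col) of the candidate.
- An SMD with zero pooled variance is treated as balanced only when the
  means are equal; otherwise the iteration is flagged and rejected.
- Degenerate inputs (empty candidate pool, all iterations rejected) raise
  informative errors carrying the balance report rather than returning
  silently empty estimates.

## Rates, over-crediting statistics, diagnostics, decomposition

Forest areas convert to comparable compound annual rates via
`F_t = F_0 (1 − r)^t`, inverted as `r = 1 − (F_t/F_0)^(1/t)`; certified
evaluation windows counted in days divide by 365.25, remote-sensing windows
use whole years. Negative rates (net gain) are retained, total loss is
flagged. Avoided deforestation is annualised by simple division, or
expressed as the rate difference (r_counterfactual − r_project)·100 %/yr.

Per project, quasi-experimental estimates are summarised by mean, SD, CV, SE
and a 95 % t-interval (n−1 df; a single estimate is taken as the mean with
no interval). The mean over-crediting ratio averages certified/mean-QE over
credit-issuing projects with positive means; the global ratio divides summed
certified by summed mean-QE estimates including negative ones. Both get
percentile confidence intervals from 10,000 project resamples; resamples
with non-positive summed means yield non-finite global draws, which are
excluded from the percentiles and counted (this is what produces the heavy
upper tails of such intervals). Paired systematic differences are tested
with a one-tailed Wilcoxon signed-rank test: zeros dropped, mid-ranks on
ties, an exact enumeration-equivalent null distribution for n ≤ 25 without
ties and a tie-corrected normal approximation otherwise.

Balance diagnostics apply the same SMD with the comparison area on the
"control" side (negative accessibility SMD = comparison more accessible),
flag per-covariate values outside ±0.25, and test per-covariate SMD
distributions across projects against zero with two-sided one-sample t-tests
without multiplicity adjustment. The "deforestation at t−5/t−10" covariates
are proportional deforested-class cover at those epochs — an explicit package
convention, since the underlying confounder is not pinned down further.

The substitution decomposition forms five avoided-deforestation rates per
project by swapping one ingredient at a time between the quasi-experimental
and certified assessments (pure QE; certified project rate; certified
reference area; reference rate corrected by k, the median certified/ACC
project-rate ratio; pure certified). Attribution shares are ratios of
*median* differences to the median gap (pure certified minus pure QE) —
defined on medians of combinations rather than medians of per-project shares
because medians are what the combination summaries report and the shares are
then stable under the heavy-tailed per-project distributions. The shares
need not sum to 100 %: the bespoke-correction overlap is reported as its own
bound, not hidden.

## Problem sizes used in validation

The known-effect validation scenario uses a 600×600 grid of 100 m cells
(60 km side), a 100×100-pixel project (10⁴ pixels, 10⁴ ha), mean hazard
≈ 2 %/yr, treatment multiplier 0.5, years 1999–2021 with t0 = 2011 (10-year
horizon, 12 years of pre-project history for the t−10 covariates), and a
candidate pool thinned to a 0.25 pt/ha lattice. The landscape is dimensioned
so the untreated domain contains hundreds of covariate patches comparable to
the project — the synthetic analogue of the method's 2000 km search radius;
on cramped landscapes the balance gate correctly rejects every iteration
rather than returning a biased estimate. The 100 m cell (1 ha) is the
simulation's unit; the grid type defaults to the 30 m / 0.09 ha convention
of the real land-cover product. Estimator recovery and null coverage are
each assessed over 20 scenario seeds.

## Known limitations

- Rectangular default polygons; irregular project shapes are supported by
  the sampling and rate machinery but not by the placement routine.
- The candidate pool lattice (when used) slightly reduces match quality
  relative to the full pixel domain; both modes are supported.
- Matching bias grows when the project sits at the extreme of the covariate
  distribution; the SMD gate detects, but cannot repair, such scenarios.
- The Wilcoxon normal approximation is used whenever absolute differences
  tie, even at small n, where an exact tied-rank enumeration would be
  feasible.
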