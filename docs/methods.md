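# Methods

## The scoring model

The Immunoscore of a patient is the arithmetic mean of four empirical
percentiles — CD3+ and CD8+ T-cell density, each in the center of tumor (CT)
and the invasive margin (IM) — taken against reference density
distributions, binned into pre-defined bands (IS3: Lo [0, 25],
Int (25, 70], Hi (70, 100]; IS2 merges Int and Hi; IS5 splits Lo and Hi at
10 and 95). Two conventions are deliberately fixed:

* **Percentile definition.** P(d) = 100 · #{reference ≤ d}/n. Inclusive
  counting makes the transform a right-continuous step function with
  maximum 100 and gives deterministic tie behavior; no interpolation is
  used. The published methodology does not specify tie or interpolation
  handling.
* **Band edges.** Interior boundaries are closed on the right and open on
  the left, following the ">"-notation of the published band definitions.
  The two-level scheme is written ambiguously in circulation ("Lo 0–25,
  Int+Hi 25–100"); this package resolves a mean of exactly 25 to **Lo**,
  consistent with the three-level definition. At the granularity of a
  1000-point reference the probability mass at exactly 25 is ~10⁻³ per
  patient, so the choice is practically irrelevant but is tested explicitly.

The reference distributions of the consensus assay are not public. The
packaged default is a synthetic stand-in: four log-normal samples
(n = 1000 per marker × region; medians 500/800/150/350 cells/mm² for
CD3-CT/CD3-IM/CD8-CT/CD8-IM, log-SD ≈ 1), generated from a fixed, documented
seed at runtime so every installation sees bit-identical sequences. Because
scoring is rank-based, downstream statistics are invariant to the particular
shape chosen; the medians were picked to be biologically plausible for colon
tumors (CD3 denser than CD8, margin denser than core).

## Quantification and QC

Synthetic slides are homogeneous Poisson point patterns inside simple
polygons (shapely) with per-cell staining intensities Normal(200, 15) AU,
truncated at 0. Density = count inside (or on the boundary of) the region
polygon / polygon area; boundary points count as inside — a deterministic,
testable convention. A slide fails QC when any of the four densities is
missing (`MISSING_REGION`) or either marker's mean intensity is ≤ 152 AU
(`LOW_INTENSITY`). The 152 AU statistic is computed as the per-marker mean
over that marker's cells on the slide; how the original assay aggregates
intensity (per cell, pixel or slide) is not published, so the slide mean is
a declared convention. Image segmentation itself is out of scope.

## Survival statistics

All statistics are implemented from first principles and cross-checked
against independent library oracles in the test suite (max |ΔS| < 1e-10 for
KM, |Δχ²| < 1e-8 for log-rank, |Δβ| < 1e-6 for Cox):

* **Kaplan–Meier** with Greenwood variance; interval estimates on the
  log(−log) scale. The "5-year rate" is the curve value at exactly 60
  months (time unit: months throughout).
* **Log-rank**: k-sample observed-minus-expected against the summed
  hypergeometric covariance (unstratified; the stratified Wald p from the
  Cox model is reported separately). Figure-style log-rank tests in this
  field are typically unstratified, and that default is kept.
* **Cox regression**, optionally stratified by participating center:
  Newton–Raphson with step-halving on the partial likelihood, convergence
  when the largest step falls below 1e-9, at most 50 iterations. Efron tie
  handling by default (Breslow available for cross-checks); monotone
  likelihood is flagged (`converged_ = False` plus a warning), never
  silently reported. Covariates constant within all strata are rejected;
  constant model *terms* (e.g. N-stage in a node-negative cohort) are
  dropped from the design with zero degrees of freedom.
* **Wald tests** are coefficient-block quadratic forms; **likelihood-ratio
  tests** require nested designs on identical data and strata.
* **Harrell's C**: usable pairs are those whose strictly earlier time is an
  event; score ties count ½. The CI uses a normal approximation with a
  degree-2 U-statistic (per-subject influence) standard error. With tied
  event times some libraries additionally count tied-time pairs; the oracle
  comparison therefore uses continuous times.
* **RMST**: area under the KM step function on [0, τ], variance by the
  standard Greenwood-type sum; τ defaults to the shortest maximum observed
  time across compared groups, so every restricted mean is supported by
  data. Differences use summed variances and a two-sided z test.
* **χ² importance**: each term's partial Wald χ² as a percentage of the
  total. The raw χ² (not χ² − df) is the default because it matches the
  headline "contribution to risk" percentages most naturally; the
  df-adjusted variant is a switch.
* p-values are two-sided; no multiplicity correction is applied anywhere.

## The synthetic-cohort generator

The generator's defaults are the study conditions:

| Parameter | Default | Source/rationale |
|---|---|---|
| IS3 proportions | 23.8 / 47.2 / 29.0 % | published category counts (448/890/547 of 1885) |
| 5-yr TTR rates | 78.4 / 88.1 / 93.4 % | published per-category rates; exponential calibration λ = −ln(rate)/60 |
| Censoring | uniform [L, U], L = U/2, solved so the censored-observation median follow-up is 69.5 mo | published median follow-up |
| Centers | 14, uniform | published center count; per-center sizes unpublished |
| Death w/o recurrence | 0.005 /mo | chosen so overall death fraction ≈ published 31% over follow-up |
| Post-recurrence death | 0.029 /mo (median ≈ 24 mo) | plausible relapsed-CC survival |
| Covariates | 52.6% male; age ~ N(68, 12.6) (median 68, IQR 60–77); nodes ~ Poisson(19); Stage I 23.9%; Stage II chemo 21.2% | published marginals |
| MSI | MSS 45.5%, MSI 12%, rest unknown | MSS fraction implied by published subgroup sizes; assay coverage is inconsistent across published tables, so the split is a declared choice |
| T-stage, VELIPI, sidedness, perforation, differentiation | T4 15% of Stage II, VELIPI+ 20%, right 50%, perforation 3%, poor 15% | not published at this granularity; field-typical values, fixed once |

Event times are exponential per category (a Weibull shape parameter is
exposed for sensitivity checks; the published analyses assume only
proportional hazards, and the exponential is the simplest consistent
family). Category hazards are either calibrated from 5-year rates or set as
hazard ratios versus Lo. Death without recurrence is an independent
exponential competing process; it censors TTR at the death time (standard
TTR convention) and feeds DFS/OS through the endpoint rules.

The four percentiles are constructed as the sampled band-uniform mean plus
centered Normal(0, 10) perturbations, clipped to [0, 100] and re-centered so
the mean is exact, then snapped to the grid of percentiles the reference can
represent; if snapping moves a mean across a band edge the offending
percentile is stepped one grid unit back, so **rescoring generated densities
through the scoring module reproduces the sampled category exactly** — a
tested invariant, not an approximation. Densities come from the
inverse-percentile lookup (grid index k → k-th smallest reference value;
percentile 0 → half the reference minimum).

What the generator does *not* emulate: inter-marker biological correlation
beyond the shared mean, covariate–score and covariate–covariate dependence
(all marginals are independent), center-level heterogeneity beyond labels,
informative censoring, and cure fractions. Passing recovery tests therefore
demonstrates correctness of the estimators under proportional hazards and
independent censoring — not robustness to real-data violations of those
assumptions.

## Subgroups and endpoints

High-risk Stage II = VELIPI+ or T4 or perforation or poor differentiation
or < 12 nodes examined; low-risk = T1–3 with none of these (patients with
unknown VELIPI/differentiation are excluded from the risk partition only).
"Very high risk" is implemented as T4 **and** VELIPI+ (the accumulation
reading); the disjunctive reading is a switch, since the defining sentence
is ambiguous. "Untreated" means no chemotherapy — the only treatment
modality recorded. Multivariable models adjust for gender, T-stage, N-stage
and MSI (with an explicit "unknown" level), stratified by center.

## Problem sizes

The recovery studies use 200 replicates at the published cohort sizes
(n = 1885; 652 for the Stage II MSS setting) and 500 replicates of n = 200
for the small-sample T4N0 setting, where the median across replicates is
reported because the HR estimate's finite-sample distribution is markedly
right-skewed at ~60 events. Rate recoveries use 100 replicates with
administrative censoring at 72 months. The round-trip study scores 100 000
patients. These sizes give Monte-Carlo standard errors several times
smaller than the corresponding acceptance tolerances while keeping a full
run in tens of seconds.

## Known limitations

* The reference distribution is synthetic; absolute density thresholds are
  not comparable with the proprietary assay, only the rank pipeline is.
* The C-index CI is a first-order approximation; for small samples a
  bootstrap would be preferable.
* No proportional-hazards diagnostics, competing-risks estimation, frailty,
  or missing-covariate imputation.
* The exclusion funnel is exercised with injected QC failures in tests;
  default generated cohorts are post-exclusion by construction.
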