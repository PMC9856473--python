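# immunoscore

A tested, reusable implementation of the consensus **Immunoscore** analysis
for early-stage (TNM Stage I/II) colon cancer: percentile-based scoring of
CD3+/CD8+ T-cell densities, slide-level QC, survival-endpoint construction,
risk-subgroup stratification, and a from-first-principles survival-statistics
battery — exercised end-to-end on a calibrated synthetic-cohort simulator.

## Who this is for

Biostatisticians and computational pathologists who want to reproduce,
stress-test or extend percentile-based immune-biomarker analyses without
access to patient-level data. Real cohort data for this class of study are
typically available only on request, so the package ships a synthetic-cohort
generator whose defaults encode the published study conditions (category
proportions, 5-year rates, hazard ratios, follow-up, covariate prevalences);
every statistic can then be validated by parameter recovery.

## The score

For each patient, densities (cells/mm²) of CD3+ and CD8+ lymphocytes are
measured in the center of tumor (CT) and the invasive margin (IM). Each of
the four densities *d* is converted to a percentile of a reference
population,

&nbsp;&nbsp;P(d) = 100 · #{reference values ≤ d} / n<sub>ref</sub>,

and the score is the arithmetic mean of the four percentiles, binned into
pre-defined bands:

| Scheme | Bands |
|---|---|
| IS3 | Lo [0, 25] · Int (25, 70] · Hi (70, 100] |
| IS2 | Lo [0, 25] · Int+Hi (25, 100] |
| IS5 | I0 [0, 10] · I1 (10, 25] · I2 (25, 70] · I3 (70, 95] · I4 (95, 100] |

Slides are excluded when a region count is missing or mean staining
intensity is ≤ 152 AU. Endpoints are TTR (time to recurrence; death without
recurrence censors), DFS (first of recurrence or death), and OS (death).
Analyses use Kaplan–Meier with Greenwood/log(−log) intervals, the log-rank
test, Cox proportional-hazards models stratified by participating center
(Efron ties), Harrell's C, restricted mean survival time with tau set to the
shortest group maximum follow-up, likelihood-ratio model comparison, and a
χ² relative-importance decomposition — all implemented in this package, with
lifelines/scikit-survival used only as cross-check oracles in the tests.

## Worked example

```python
import pandas as pd
from immunoscore import (GeneratorConfig, generate_cohort, score_cohort,
                         derive_endpoints, compare_groups)

cfg = GeneratorConfig(n_patients=1885, seed=0)          # study-sized cohort
cohort = derive_endpoints(score_cohort(generate_cohort(cfg)))
block = compare_groups(cohort, "ttr", "is3", strata="center")
print(block.table[["n", "pct", "rate_5yr", "hr"]].round(3))
print(f"logrank p = {block.logrank_p:.2e}, C = {block.c_index:.3f}, "
      f"tau = {block.tau:.1f} mo")
```

Output:

```
         n     pct  rate_5yr     hr
level
Lo     448  23.767    81.716  1.000
Int    876  46.472    90.316  0.485
Hi     561  29.761    94.217  0.306
logrank p = 6.59e-11, C = 0.622, tau = 95.1 mo
```

Reading: 23.8% of the synthetic cohort scores Lo; their 5-year
recurrence-free rate is 81.7%, versus 94.2% for Hi patients, whose
center-stratified hazard of recurrence is 0.31 relative to Lo. These match
the generating conditions (rates 78.4/88.1/93.4%, Hi-vs-Lo hazard ratio
0.27) to within the sampling noise of a single cohort.

The same pipeline is available from the shell:

```bash
immunoscore run --seed 0 -o out/ --subgroup stage2 --endpoint TTR --grouping is3
```

which writes per-subgroup comparison tables, KM curve exports, multivariable
Cox summaries with importance breakdowns, and a run manifest.

## Cohort table columns

`patient_id, cohort (1|2), center, gender, age, stage (I|II), t_stage
(T1–T4), n_stage (0), sidedness, msi (MSI|MSS|unknown), velipi, differentiation,
perforation, ln_examined, chemotherapy, preoperative_treatment,
recurrence_time/observed, death_time/observed, censor_time` (months), plus
ground truth (`true_category`, `true_mean_percentile`) and densities
(`cd3_ct, cd3_im, cd8_ct, cd8_im`, cells/mm²). Scoring appends
`pct_*`, `mean_percentile`, `is2/is3/is5`; endpoint derivation appends
`{ttr,dfs,os}_{time,event}`.

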