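"""Assembly of the per-group univariate survival comparison block.

One block mirrors a published univariate-analysis row group: per category
n (%), 5-year event-free rate with 95% CI, center-stratified unadjusted
hazard ratio versus the low category with Wald p, the overall (unstratified)
log-rank p, Harrell's C for the fitted risk score, and restricted mean
survival times with differences versus the reference at the auto-selected
tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._km import km_curve
from ._logrank import logrank
from ._cox import cox_fit, wald_test
from ._concordance import c_index
from ._rmst import auto_tau, rmst, rmst_difference

GROUP_LEVELS = {
    "is2": ("Lo", "IntHi"),
    "is3": ("Lo", "Int", "Hi"),
    "is5": ("I0", "I1", "I2", "I3", "I4"),
}

#: "5 years" in the time unit used throughout (months).
FIVE_YEARS = 60.0


@dataclass
class SurvivalComparison:
    endpoint: str
    group_col: str
    levels: list
    table: pd.DataFrame  # one row per level
    logrank_p: float
    logrank_chi2: float
    c_index: float
    c_index_ci: tuple
    tau: float
    strata: Optional[str] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        pct = self.table["pct"].sum()
        if abs(pct - 100.0) > 0.1:
            raise ValueError(f"level percentages sum to {pct}, not 100")


def compare_groups(
    cohort: pd.DataFrame,
    endpoint: str,
    grouping: str = "is3",
    strata: Optional[str] = "center",
    rate_time: float = FIVE_YEARS,
) -> SurvivalComparison:
    """Build the univariate comparison block for one endpoint and grouping.

    ``cohort`` must carry derived endpoint columns (``{endpoint}_time``,
    ``{endpoint}_event``) and the grouping label column (``is2``/``is3``/
    ``is5``).  Levels with zero patients are omitted with a warning.
    """
    grouping = grouping.lower()
    if grouping not in GROUP_LEVELS:
        raise ValueError(f"unknown grouping {grouping!r}")
    tcol, ecol = f"{endpoint.lower()}_time", f"{endpoint.lower()}_event"
    for col in (tcol, ecol, grouping):
        if col not in cohort.columns:
            raise KeyError(f"cohort lacks column {col!r}")
    if strata is not None and strata not in cohort.columns:
        raise KeyError(f"cohort lacks strata column {strata!r}")

    notes = []
    levels = []
    for lv in GROUP_LEVELS[grouping]:
        n_lv = int((cohort[grouping] == lv).sum())
        if n_lv == 0:
            msg = f"level {lv!r} has zero patients and is omitted"
            warnings.warn(msg)
            notes.append(msg)
        else:
            levels.append(lv)
    if len(levels) < 2:
        raise ValueError("fewer than two non-empty levels; nothing to compare")
    reference = levels[0]

    sub = cohort[cohort[grouping].isin(levels)].copy()
    n_total = len(sub)
    groups = {
        lv: (sub.loc[sub[grouping] == lv, tcol].to_numpy(),
             sub.loc[sub[grouping] == lv, ecol].to_numpy(dtype=bool))
        for lv in levels
    }

    # overall (unstratified) log-rank across all levels
    chi2, _df, lr_p = logrank(*groups.values())

    # center-stratified unadjusted Cox with the grouping as sole term
    fit = cox_fit(
        sub, [grouping], duration_col=tcol, event_col=ecol, strata=strata,
        reference_levels={grouping: reference},
    )
    summ = fit.summary()

    # Harrell's C of the fitted linear predictor
    design = _design_for_levels(sub[grouping], grouping, levels, reference)
    lp = fit.estimator.predict(design[fit.coef.index])
    c, c_lo, c_hi, _ = c_index(lp, sub[tcol], sub[ecol])

    tau = auto_tau(*groups.values())
    ref_rmst = rmst(*groups[reference], tau=tau)

    rows = []
    for lv in levels:
        t_lv, e_lv = groups[lv]
        km = km_curve(t_lv, e_lv)
        rate, rate_lo, rate_hi = km.rate_at(rate_time)
        r = rmst(t_lv, e_lv, tau=tau)
        if lv == reference:
            hr = 1.0
            hr_lo = hr_hi = np.nan
            wald_p = np.nan
            diff, diff_lo, diff_hi, diff_p = 0.0, np.nan, np.nan, np.nan
        else:
            name = f"{grouping}[{lv}]"
            hr = float(summ.loc[name, "hr"])
            hr_lo = float(summ.loc[name, "hr_lower"])
            hr_hi = float(summ.loc[name, "hr_upper"])
            wald_p = float(summ.loc[name, "p"])
            diff, _se, diff_lo, diff_hi, diff_p, _ = rmst_difference(
                groups[lv], groups[reference], tau=tau
            )
        rows.append({
            "level": lv,
            "n": len(t_lv),
            "pct": 100.0 * len(t_lv) / n_total,
            "rate_5yr": 100.0 * rate,
            "rate_5yr_lower": 100.0 * rate_lo,
            "rate_5yr_upper": 100.0 * rate_hi,
            "hr": hr, "hr_lower": hr_lo, "hr_upper": hr_hi, "wald_p": wald_p,
            "rmst": r.rmst, "rmst_lower": r.ci_lower, "rmst_upper": r.ci_upper,
            "rmst_diff": diff, "rmst_diff_lower": diff_lo,
            "rmst_diff_upper": diff_hi, "rmst_diff_p": diff_p,
        })
    table = pd.DataFrame(rows).set_index("level")
    return SurvivalComparison(
        endpoint=endpoint.upper(), group_col=grouping, levels=levels,
        table=table, logrank_p=lr_p, logrank_chi2=chi2,
        c_index=c, c_index_ci=(c_lo, c_hi), tau=tau, strata=strata,
        warnings=notes,
    )


def _design_for_levels(series: pd.Series, grouping: str, levels, reference):
    """Dummy design matching the columns produced by cox_fit for this grouping."""
    cols = {}
    for lv in sorted(map(str, series.astype(str).unique())):
        if lv == str(reference):
            continue
        cols[f"{grouping}[{lv}]"] = (series.astype(str) == lv).astype(float)
    return pd.DataFrame(cols, index=series.index)
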