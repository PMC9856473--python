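"""Relative importance of Cox model terms via partial Wald chi-square.

Each term's block Wald chi-square measures its contribution to the fitted
risk; expressing the chi-squares as percentages of their total gives the
relative-importance decomposition displayed alongside multivariable fits.
By default the raw chi-square is used; ``adjust_df=True`` switches to
chi-square minus degrees of freedom (both conventions are in circulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._cox import CoxFit, wald_test


@dataclass(frozen=True)
class ImportanceBreakdown:
    table: pd.DataFrame  # index: term; columns: chi2, df, relative_pct
    total_chi2: float

    def __post_init__(self):
        pct = self.table["relative_pct"]
        if abs(pct.sum() - 100.0) > 0.1:
            raise ValueError("relative importances must sum to 100")
        if (pct < -1e-9).any():
            raise ValueError("relative importances must be >= 0")


def chi2_importance(fit: CoxFit, adjust_df: bool = False) -> ImportanceBreakdown:
    """Per-term partial Wald chi-square and relative importance (%)."""
    if not fit.terms:
        raise ValueError("fit has no terms")
    rows = {}
    for term in fit.terms:
        chi2, df, _p = wald_test(fit, term)
        stat = max(chi2 - df, 0.0) if adjust_df else chi2
        rows[term] = (stat, df)
    table = pd.DataFrame(rows, index=["chi2", "df"]).T
    total = float(table["chi2"].sum())
    if total <= 0:
        raise ValueError(
            "all partial chi-square statistics are zero; relative importance "
            "is undefined"
        )
    table["relative_pct"] = 100.0 * table["chi2"] / total
    table["df"] = table["df"].astype(int)
    return ImportanceBreakdown(table=table, total_chi2=total)
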