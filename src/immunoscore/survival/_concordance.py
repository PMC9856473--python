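"""Harrell's concordance index for censored survival data."""

from __future__ import annotations

import numpy as np
from scipy import stats


def c_index(risk_score, times, events, conf_level: float = 0.95):
    """Harrell's C with a normal-approximation confidence interval.

    A pair (i, j) is usable when the smaller observed time is an event and
    the times differ; concordance means the earlier failure has the higher
    risk score, with score ties counting 1/2.  Returns
    ``(c, lower, upper, n_pairs)``.

    The standard error is a U-statistic (delta-method) approximation: each
    subject's average pair score acts as its influence contribution.
    """
    s = np.asarray(risk_score, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = t.size
    if not (s.size == n == e.size):
        raise ValueError("risk_score, times and events must have equal length")

    # usable[i, j]: t_i < t_j and e_i  (i the earlier failure)
    earlier = t[:, None] < t[None, :]
    usable = earlier & e[:, None]
    np.fill_diagonal(usable, False)
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise ValueError("no usable (comparable) pairs")

    score = np.where(s[:, None] > s[None, :], 1.0,
                     np.where(s[:, None] == s[None, :], 0.5, 0.0))
    total = float((score * usable).sum())
    c = total / n_pairs

    # per-subject influence: mean pair score over pairs involving the subject
    pair_any = usable | usable.T
    counts = pair_any.sum(axis=1)
    sym_score = score * usable + score.T * usable.T  # score of each pair, both slots
    with np.errstate(invalid="ignore"):
        subj_mean = np.where(counts > 0, sym_score.sum(axis=1) / np.maximum(counts, 1), np.nan)
    used = counts > 0
    m = int(used.sum())
    if m > 1:
        var_h1 = np.nanvar(subj_mean[used], ddof=1)
        se = float(np.sqrt(4.0 * var_h1 / m))  # degree-2 U-statistic approximation
    else:
        se = 0.0
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    lo, hi = max(0.0, c - z * se), min(1.0, c + z * se)
    return float(c), float(lo), float(hi), n_pairs
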