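"""The k-sample log-rank test, computed over pooled risk sets."""

from __future__ import annotations

import numpy as np
from scipy import stats


def logrank(*groups):
    """Log-rank test for equality of survival across >= 2 groups.

    Each group is a (times, events) pair.  Returns (chi2, df, p) where
    df = number of groups - 1.  At each distinct pooled event time the
    observed events per group are compared with their hypergeometric
    expectation given the pooled risk set; the statistic is the quadratic
    form of the summed observed-minus-expected vector against the summed
    hypergeometric covariance (last group dropped).
    """
    if len(groups) < 2:
        raise ValueError("log-rank requires at least two groups")
    times_list, events_list = [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {g} has zero observations")
        times_list.append(t)
        events_list.append(e)

    k = len(groups)
    times = np.concatenate(times_list)
    events = np.concatenate(events_list)
    labels = np.concatenate([np.full(t.size, g) for g, t in enumerate(times_list)])

    order = np.argsort(times, kind="stable")
    times, events, labels = times[order], events[order], labels[order]
    uniq, start = np.unique(times, return_index=True)

    n_total = times.size
    # per-group at-risk counts just before each distinct time:
    # n_g(t) = (# in g) - (# in g with time < t), via cumulative counts
    onehot = np.zeros((n_total, k))
    onehot[np.arange(n_total), labels] = 1.0
    cum_before = np.vstack([np.zeros(k), np.cumsum(onehot, axis=0)])[start]
    n_g = onehot.sum(axis=0)[None, :] - cum_before  # (n_times, k)
    d_g = np.add.reduceat(onehot * events[:, None], start, axis=0)  # events per group per time

    n_t = n_g.sum(axis=1)
    d_t = d_g.sum(axis=1)
    use = d_t > 0
    n_g, d_g, n_t, d_t = n_g[use], d_g[use], n_t[use], d_t[use]

    expected = d_t[:, None] * n_g / n_t[:, None]
    ome = (d_g - expected).sum(axis=0)

    # hypergeometric covariance, summed over event times (k-1 x k-1 block)
    cov = np.zeros((k - 1, k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    p_g = n_g / n_t[:, None]
    for i in range(k - 1):
        for j in range(k - 1):
            if i == j:
                cov[i, j] = np.sum(factor * p_g[:, i] * (1.0 - p_g[:, i]))
            else:
                cov[i, j] = -np.sum(factor * p_g[:, i] * p_g[:, j])

    v = ome[: k - 1]
    if np.allclose(cov, 0.0):
        chi2 = 0.0
    else:
        chi2 = float(v @ np.linalg.pinv(cov) @ v)
        chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
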