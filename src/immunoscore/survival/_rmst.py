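"""Restricted mean survival time: area under the KM curve up to tau.

The study convention selects tau automatically as the shortest maximum
observed time across the compared groups, so the restricted mean is defined
on a window every group supports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._km import km_curve


@dataclass(frozen=True)
class RMSTResult:
    rmst: float
    se: float
    ci_lower: float
    ci_upper: float
    tau: float


def auto_tau(*groups) -> float:
    """Tau rule: minimum over groups of each group's maximum observed time."""
    maxima = []
    for times, _events in groups:
        t = np.asarray(times, dtype=float)
        if t.size == 0:
            raise ValueError("empty group")
        maxima.append(float(t.max()))
    return min(maxima)


def rmst(times, events, tau: float, conf_level: float = 0.95) -> RMSTResult:
    """RMST = integral of the KM curve on [0, tau], with nonparametric variance.

    Variance uses the standard Greenwood-type formula: for each event time
    t_j <= tau, the squared remaining area from t_j to tau weighted by
    d_j / (n_j (n_j - d_j)).
    """
    t = np.asarray(times, dtype=float)
    if tau > t.max():
        raise ValueError(
            f"tau={tau} exceeds the largest observed time {t.max():.6g}; use "
            "auto_tau to pick a supported cutoff"
        )
    if tau <= 0:
        raise ValueError("tau must be > 0")
    km = km_curve(times, events)

    # integrate the right-continuous step function on [0, tau]
    et = km.event_times
    sv = km.survival
    within = et < tau
    knots = np.concatenate([[0.0], et[within], [tau]])
    heights = np.concatenate([[1.0], sv[within]])
    widths = np.diff(knots)
    area = float(np.sum(heights * widths))

    # variance: events strictly before tau contribute; remaining area after t_j
    idx = np.flatnonzero(within & (km.n_at_risk > km.n_events))
    var = 0.0
    for j in idx:
        # area under the curve from et[j] to tau
        kj = et[j]
        seg_mask = within & (et > kj)
        seg_knots = np.concatenate([[kj], et[seg_mask], [tau]])
        seg_heights = np.concatenate([[sv[j]], sv[seg_mask]])
        a_j = float(np.sum(seg_heights * np.diff(seg_knots)))
        nj, dj = km.n_at_risk[j], km.n_events[j]
        var += a_j * a_j * dj / (nj * (nj - dj))
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    return RMSTResult(rmst=area, se=se, ci_lower=area - z * se,
                      ci_upper=area + z * se, tau=float(tau))


def rmst_difference(group_a, group_b, tau: float | None = None,
                    conf_level: float = 0.95):
    """RMST(A) - RMST(B) with summed variances and a two-sided z test.

    Each group is a (times, events) pair; ``tau=None`` applies the auto rule.
    Returns (difference, se, ci_lower, ci_upper, p, tau).
    """
    if tau is None:
        tau = auto_tau(group_a, group_b)
    ra = rmst(*group_a, tau=tau, conf_level=conf_level)
    rb = rmst(*group_b, tau=tau, conf_level=conf_level)
    diff = ra.rmst - rb.rmst
    se = float(np.sqrt(ra.se ** 2 + rb.se ** 2))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(diff) / se))
    else:
        p = 1.0
    return diff, se, diff - z * se, diff + z * se, p, float(tau)
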