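"""Kaplan-Meier product-limit estimator with Greenwood variance.

Confidence intervals are computed on the log(-log) (complementary log-log)
scale, which keeps them inside [0, 1] and matches standard survival software
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class KaplanMeier:
    """Fitted product-limit estimator.

    Attributes
    ----------
    event_times : distinct times with >= 1 event, ascending
    survival : S(t) just after each event time (right-continuous steps)
    n_at_risk, n_events : risk-set size and event count at each event time
    cumvar_loghaz : running Greenwood sum  sum d/(n(n-d))  (variance of log S)
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    cumvar_loghaz: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): value of the right-continuous step function at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def greenwood_var_at(self, t: float) -> float:
        """Greenwood variance of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 0.0
        s = self.survival[idx]
        return float(s * s * self.cumvar_loghaz[idx])

    def rate_at(self, t: float, conf_level: float = 0.95):
        """Event-free rate S(t) with a log(-log)-scale confidence interval.

        Returns (estimate, lower, upper), all on the probability scale.
        """
        s = self.survival_at(t)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0 or s in (0.0, 1.0):
            return s, s, s
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        # var of log(-log S) by the delta method
        v = self.cumvar_loghaz[idx] / (np.log(s) ** 2)
        theta = np.log(-np.log(s))
        lo = np.exp(-np.exp(theta + z * np.sqrt(v)))
        hi = np.exp(-np.exp(theta - z * np.sqrt(v)))
        return float(s), float(lo), float(hi)

    def as_table(self):
        """(time, survival, lower, upper, n_at_risk) rows, one per event time."""
        rows = []
        for t in self.event_times:
            s, lo, hi = self.rate_at(t)
            n = self.n_at_risk[np.searchsorted(self.event_times, t)]
            rows.append((float(t), s, lo, hi, int(n)))
        return rows


def km_curve(times, events) -> KaplanMeier:
    """Fit the Kaplan-Meier estimator.

    Parameters
    ----------
    times : array of follow-up times (>= 0)
    events : boolean array, True when the event was observed
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty sample")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and >= 0")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    uniq, start = np.unique(times, return_index=True)
    n_total = times.size
    # risk set just before each distinct time
    at_risk_all = n_total - start
    d_all = np.add.reduceat(events.astype(int), start)

    has_event = d_all > 0
    t_ev = uniq[has_event]
    n_ev = at_risk_all[has_event]
    d_ev = d_all[has_event]

    if t_ev.size == 0:
        return KaplanMeier(
            event_times=np.empty(0), survival=np.empty(0), n_at_risk=np.empty(0, int),
            n_events=np.empty(0, int), cumvar_loghaz=np.empty(0), n=n_total,
        )
    surv = np.cumprod(1.0 - d_ev / n_ev)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_ev > d_ev, d_ev / (n_ev * (n_ev - d_ev)), np.inf)
    cumvar = np.cumsum(inc)
    return KaplanMeier(
        event_times=t_ev, survival=surv, n_at_risk=n_ev.astype(int),
        n_events=d_ev.astype(int), cumvar_loghaz=cumvar, n=n_total,
    )
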