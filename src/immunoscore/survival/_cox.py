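"""Cox proportional-hazards regression, optionally stratified by center.

The partial likelihood is maximized by Newton iterations with step-halving,
handling tied event times with the Efron approximation (default) or Breslow.
Stratification enters in the usual way: each stratum contributes its own
risk sets and the log partial likelihoods add.

Implemented from first principles (suffix-sum risk-set accumulation, no
survival library behind it); established libraries are used only as
cross-check oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


class ConvergenceWarning(UserWarning):
    pass


def _unpack_y(y):
    """Accept (times, events) tuples, (n,2) arrays, or structured arrays."""
    if isinstance(y, tuple) and len(y) == 2:
        t, e = y
    elif hasattr(y, "dtype") and y.dtype.names:
        names = y.dtype.names
        tname = next(n for n in names if "time" in n.lower() or "duration" in n.lower())
        ename = next(n for n in names if n != tname)
        t, e = y[tname], y[ename]
    else:
        arr = np.asarray(y)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("y must be (times, events), a structured array, or (n, 2)")
        t, e = arr[:, 0], arr[:, 1]
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=bool)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("event/censoring times must be finite and >= 0")
    return t, e


def _stratum_derivatives(t, e, X, beta, ties):
    """(log-PL, gradient, information) contribution of one stratum at beta."""
    n, p = X.shape
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    if n == 0 or not np.any(e):
        return ll, grad, info

    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    eta = X @ beta
    eta = eta - eta.max()  # shifts cancel exactly in the partial likelihood
    r = np.exp(eta)

    # suffix (risk-set) sums: S*[i] = sum over subjects with time >= t[i]
    S0s = np.cumsum(r[::-1])[::-1]
    S1s = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    XX = X[:, :, None] * X[:, None, :]
    S2s = np.cumsum((r[:, None, None] * XX)[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(e)
    t_ev = t[ev_idx]
    uniq_ev, grp_start = np.unique(t_ev, return_index=True)
    d = np.diff(np.append(grp_start, t_ev.size))
    pos = np.searchsorted(t, uniq_ev, side="left")

    S0j, S1j, S2j = S0s[pos], S1s[pos], S2s[pos]
    ll += float(eta[ev_idx].sum())
    grad += X[ev_idx].sum(axis=0)

    untied = d == 1
    if np.any(untied):
        phi = S0j[untied]
        ll -= float(np.log(phi).sum())
        Z = S1j[untied] / phi[:, None]
        grad -= Z.sum(axis=0)
        info += (S2j[untied] / phi[:, None, None]).sum(axis=0)
        info -= np.einsum("jp,jq->pq", Z, Z)

    for j in np.flatnonzero(~untied):
        dj = int(d[j])
        sel = ev_idx[grp_start[j]: grp_start[j] + dj]
        rD = r[sel]
        xD = X[sel]
        s0d = rD.sum()
        s1d = (rD[:, None] * xD).sum(axis=0)
        s2d = (rD[:, None, None] * (xD[:, :, None] * xD[:, None, :])).sum(axis=0)
        fracs = np.zeros(dj) if ties == "breslow" else np.arange(dj) / dj
        for f in fracs:
            phi = S0j[j] - f * s0d
            z = (S1j[j] - f * s1d) / phi
            ll -= float(np.log(phi))
            grad -= z
            info += (S2j[j] - f * s2d) / phi - np.outer(z, z)
    return ll, grad, info


class StratifiedCoxPH(BaseEstimator):
    """Cox proportional-hazards model with optional stratification.

    Scikit-learn style estimator: ``fit(X, y, strata=...)`` where ``y`` is a
    ``(times, events)`` pair (or equivalent structured/(n,2) array) and
    ``strata`` is an optional per-sample label array (e.g. participating
    center).  Hazard ratios are ``exp(coef_)``.

    Parameters
    ----------
    ties : {"efron", "breslow"}, default "efron"
        Tie handling in the partial likelihood.
    tol : float, default 1e-9
        Convergence: maximum absolute Newton step below this value.
    max_iter : int, default 50
    alpha : float, default 0.05
        1 - confidence level for summaries.

    Attributes
    ----------
    coef_ : ndarray of shape (p,) — log hazard ratios
    cov_ : ndarray (p, p) — inverse observed information at the optimum
    se_ : ndarray (p,)
    log_likelihood_, null_log_likelihood_ : log partial likelihoods
    n_, n_events_ : sample and event counts
    converged_ : bool — False flags a monotone likelihood / non-convergence
    feature_names_in_ : list of str
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9,
                 max_iter: int = 50, alpha: float = 0.05):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha

    def _loglik(self, blocks, beta):
        p = len(beta)
        ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
        for t, e, X in blocks:
            l, g, i = _stratum_derivatives(t, e, X, beta, self.ties)
            ll += l
            grad += g
            info += i
        return ll, grad, info

    def fit(self, X, y, strata=None):
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be 'efron' or 'breslow', got {self.ties!r}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"x{i}" for i in range(Xa.shape[1])]
        t, e = _unpack_y(y)
        n, p = Xa.shape
        if t.size != n:
            raise ValueError("X and y have different lengths")

        if strata is None:
            strata_arr = np.zeros(n, dtype=int)
        else:
            strata_arr = np.asarray(strata)
        blocks = []
        for s in pd.unique(strata_arr):
            m = strata_arr == s
            blocks.append((t[m], e[m], Xa[m]))

        # terms constant within every contributing stratum have no information
        for j in range(p):
            if all(np.ptp(Xb[:, j]) == 0 for _, _, Xb in blocks if Xb.shape[0]):
                raise ValueError(
                    f"covariate {self.feature_names_in_[j]!r} is constant within all "
                    "strata and cannot be estimated; drop it before fitting"
                )

        beta = np.zeros(p)
        ll, grad, info = self._loglik(blocks, beta)
        self.null_log_likelihood_ = ll
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.pinv(info) @ grad
            # step-halving to guarantee ascent
            factor = 1.0
            for _ in range(25):
                cand = beta + factor * step
                ll_new, grad_new, info_new = self._loglik(blocks, cand)
                if ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            beta, ll, grad, info = cand, ll_new, grad_new, info_new
            if np.max(np.abs(factor * step)) < self.tol:
                converged = True
                break
            if np.max(np.abs(beta)) > 50:
                break  # monotone likelihood / complete separation

        self.converged_ = converged
        if not converged:
            warnings.warn(
                "Cox partial likelihood did not converge (possible monotone "
                "likelihood / complete separation); estimates are unreliable",
                ConvergenceWarning,
            )
        self.coef_ = beta
        try:
            self.cov_ = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            self.cov_ = np.linalg.pinv(info)
        self.se_ = np.sqrt(np.clip(np.diag(self.cov_), 0.0, None))
        self.log_likelihood_ = ll
        self.n_ = n
        self.n_events_ = int(e.sum())
        self.n_iter_ = n_iter
        return self

    @property
    def hazard_ratios_(self):
        return np.exp(self.coef_)

    def predict(self, X):
        """Linear predictor (log relative hazard)."""
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return Xa @ self.coef_

    def summary(self) -> pd.DataFrame:
        z = stats.norm.ppf(1 - self.alpha / 2)
        coef = self.coef_
        se = self.se_
        zstat = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
        return pd.DataFrame(
            {
                "coef": coef,
                "hr": np.exp(coef),
                "se": se,
                "z": zstat,
                "p": 2 * stats.norm.sf(np.abs(zstat)),
                "hr_lower": np.exp(coef - z * se),
                "hr_upper": np.exp(coef + z * se),
            },
            index=self.feature_names_in_,
        )


@dataclass
class CoxFit:
    """A fitted Cox model plus the term structure needed for block tests."""

    terms: dict  # term name -> list of design-column names
    coef: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    null_log_likelihood: float
    strata: Optional[str]
    n: int
    n_events: int
    converged: bool
    ties: str
    estimator: StratifiedCoxPH = field(repr=False, default=None)

    def __post_init__(self):
        if self.n_events > self.n:
            raise ValueError("n_events cannot exceed n")

    def summary(self) -> pd.DataFrame:
        return self.estimator.summary()


def build_design(
    data: pd.DataFrame,
    terms: Sequence[str],
    reference_levels: Optional[dict] = None,
) -> tuple[pd.DataFrame, dict, list]:
    """Design matrix for Cox terms: numeric columns as-is, categoricals dummy-coded.

    Returns (X, term_columns, dropped) where ``term_columns`` maps each term
    to its design columns and ``dropped`` lists constant terms removed (for
    example N-stage in a node-negative cohort).
    """
    reference_levels = reference_levels or {}
    cols = {}
    term_columns: dict[str, list] = {}
    dropped = []
    for term in terms:
        if term not in data.columns:
            raise KeyError(f"term {term!r} not in data")
        col = data[term]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            if col.nunique(dropna=False) <= 1:
                dropped.append(term)
                continue
            cols[term] = col.astype(float)
            term_columns[term] = [term]
        else:
            levels = sorted(map(str, col.astype(str).unique()))
            ref = str(reference_levels.get(term, levels[0]))
            others = [lv for lv in levels if lv != ref]
            if not others:
                dropped.append(term)
                continue
            names = []
            for lv in others:
                name = f"{term}[{lv}]"
                cols[name] = (col.astype(str) == lv).astype(float)
                names.append(name)
            term_columns[term] = names
    X = pd.DataFrame(cols, index=data.index)
    return X, term_columns, dropped


def cox_fit(
    data: pd.DataFrame,
    terms: Sequence[str],
    duration_col: str,
    event_col: str,
    strata: Optional[str] = None,
    ties: str = "efron",
    reference_levels: Optional[dict] = None,
) -> CoxFit:
    """Fit a (stratified) Cox model on a cohort table.

    ``terms`` are column names; categorical columns are expanded to dummies
    against a reference level (default: first level in sorted order).
    Constant terms are silently dropped from the design (they carry zero
    degrees of freedom) and do not appear in ``CoxFit.terms``.
    """
    X, term_columns, _dropped = build_design(data, terms, reference_levels)
    if X.shape[1] == 0:
        raise ValueError("no non-constant terms to fit")
    est = StratifiedCoxPH(ties=ties)
    strata_values = data[strata].to_numpy() if strata is not None else None
    est.fit(X, (data[duration_col].to_numpy(), data[event_col].to_numpy()),
            strata=strata_values)
    coef = pd.Series(est.coef_, index=X.columns)
    cov = pd.DataFrame(est.cov_, index=X.columns, columns=X.columns)
    return CoxFit(
        terms=term_columns, coef=coef, cov=cov,
        log_likelihood=est.log_likelihood_,
        null_log_likelihood=est.null_log_likelihood_,
        strata=strata, n=est.n_, n_events=est.n_events_,
        converged=est.converged_, ties=ties, estimator=est,
    )


def wald_test(fit: CoxFit, term: str):
    """Block Wald test of a term's coefficients against zero: (chi2, df, p)."""
    if term not in fit.terms:
        raise KeyError(f"term {term!r} not in fit (terms: {list(fit.terms)})")
    names = fit.terms[term]
    b = fit.coef[names].to_numpy()
    V = fit.cov.loc[names, names].to_numpy()
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(f"singular covariance block for term {term!r}")
    df = len(names)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def lr_test(full: CoxFit, reduced: CoxFit):
    """Likelihood-ratio comparison of nested Cox models: (chi2, df, p).

    Requires the reduced model's design columns to be a subset of the full
    model's, fitted on the same data, endpoint and strata.
    """
    full_cols = set(full.coef.index)
    red_cols = set(reduced.coef.index)
    if not red_cols.issubset(full_cols):
        raise ValueError("models are not nested (reduced design is not a subset)")
    if full.n != reduced.n or full.n_events != reduced.n_events:
        raise ValueError("models were fitted on different data")
    if full.strata != reduced.strata:
        raise ValueError("models use different strata")
    df = len(full_cols) - len(red_cols)
    chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    chi2 = max(float(chi2), 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
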