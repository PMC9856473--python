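"""Synthetic cohort generation calibrated to the study conditions.

Generates patient-level tables with the statistical structure the analysis
assumes: a true three-level Immunoscore category per patient (sampled at the
published category proportions), a mean percentile uniform within the
category band, four marker/region percentiles averaging exactly to that
mean, densities obtained by inverse-percentile lookup against a reference
distribution, proportional-hazards event times per category (exponential by
default; Weibull shape exposed), an independent death-without-recurrence
process, uniform administrative censoring tuned to a target median
follow-up among censored patients, and marginal covariates at the cohort's
published prevalences.

Everything is deterministic given the config seed; named substreams keep
the category, percentile, survival, censoring and covariate draws
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .reference import ReferenceDistribution, default_reference
from .scoring import DENSITY_COLUMNS, classify

CATEGORIES = ("Lo", "Int", "Hi")
#: IS-3 band edges (closed right): Lo [0,25], Int (25,70], Hi (70,100].
CATEGORY_BANDS = {"Lo": (0.0, 25.0), "Int": (25.0, 70.0), "Hi": (70.0, 100.0)}
_CAT_ORDER = {c: i for i, c in enumerate(CATEGORIES)}

#: Months in five years; the time unit is months throughout.
FIVE_YEARS_MONTHS = 60.0

#: Marginal covariate prevalences of the study population: 52.6% male,
#: median age 68 (IQR 60-77), mean 19 lymph nodes examined, 451/1885 Stage I,
#: 1130/1434 Stage II patients untreated.
DEFAULT_COVARIATE_PREVALENCES = {
    "male_fraction": 0.526,
    "age_median": 68.0,
    "age_sd": 12.6,
    "stage1_fraction": 451.0 / 1885.0,
    "t_stage_stage1": {"T1": 0.4, "T2": 0.6},
    "t_stage_stage2": {"T3": 0.85, "T4": 0.15},
    "msi": {"MSS": 0.455, "MSI": 0.12, "unknown": 0.425},
    "velipi": {"positive": 0.20, "negative": 0.75, "unknown": 0.05},
    "differentiation": {"well/moderate": 0.82, "poor": 0.15, "unknown": 0.03},
    "sidedness_right_fraction": 0.5,
    "chemotherapy_stage1": 0.02,
    "chemotherapy_stage2": 1.0 - 1130.0 / 1434.0,
    "perforation_fraction": 0.03,
    "ln_examined_mean": 19.0,
    "preoperative_treatment_fraction": 0.0,
}

#: Per-category TTR calibration: published 5-year recurrence-free rates.
DEFAULT_SURVIVAL_SPEC = {
    "Lo": {"rate_5yr": 0.784},
    "Int": {"rate_5yr": 0.881},
    "Hi": {"rate_5yr": 0.934},
}

DEFAULT_CENSORING_SPEC = {
    "family": "uniform_median",
    "target_median": 69.5,  # months, among censored observations
    "lower_frac": 0.5,      # L = lower_frac * U
}


def calibrate_rate_from_5yr(survival_at_5yr: float) -> float:
    """Exponential hazard (per month) matching a 5-year event-free rate.

    Solves exp(-60 * lam) = rate; a rate of 1.0 gives hazard 0 (no events).
    """
    if not 0.0 < survival_at_5yr <= 1.0:
        raise ValueError(f"5-year rate must be in (0, 1], got {survival_at_5yr}")
    return -np.log(survival_at_5yr) / FIVE_YEARS_MONTHS


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (defaults = study conditions)."""

    n_patients: int
    seed: int
    n_centers: int = 14
    cohort_split: float = 262.0 / 1885.0  # fraction in cohort 1
    category_proportions: tuple = (0.238, 0.472, 0.290)
    survival_spec: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_SURVIVAL_SPEC.items()})
    censoring_spec: dict = field(default_factory=lambda: dict(DEFAULT_CENSORING_SPEC))
    covariate_prevalences: dict = field(default_factory=lambda: {
        k: (dict(v) if isinstance(v, dict) else v)
        for k, v in DEFAULT_COVARIATE_PREVALENCES.items()})
    death_without_recurrence_rate: float = 0.005  # per month
    post_recurrence_death_rate: float = 0.029     # per month, after relapse
    weibull_shape: float = 1.0                    # 1.0 = exponential
    percentile_sd: float = 10.0                   # spread of the four percentiles
    exact_counts: bool = False                    # deterministic category counts
    with_densities: bool = True                   # construct percentiles/densities
    qc_fail_rate: float = 0.0
    preop_rate: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.category_proportions, dtype=float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("category_proportions must be 3 non-negative values summing to 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_centers > self.n_patients:
            raise ValueError("n_centers cannot exceed n_patients")
        if self.death_without_recurrence_rate < 0 or self.post_recurrence_death_rate < 0:
            raise ValueError("death hazards must be >= 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if "Lo" not in self.survival_spec or "rate_5yr" not in self.survival_spec["Lo"]:
            raise ValueError("survival_spec must give the Lo category a rate_5yr")

    def to_dict(self) -> dict:
        return asdict(self)


# -- survival-time machinery -------------------------------------------------

def _hazard_multipliers(spec: dict) -> tuple[float, dict]:
    """(baseline Lo cumulative-hazard scale at 60 months, per-category multiplier)."""
    rate_lo = spec["Lo"]["rate_5yr"]
    lam_lo_cum60 = -np.log(rate_lo)  # Lo cumulative hazard at 60 months
    mult = {}
    for cat in CATEGORIES:
        s = spec.get(cat, {})
        if "hr_vs_lo" in s:
            mult[cat] = float(s["hr_vs_lo"])
        elif "rate_5yr" in s:
            r = s["rate_5yr"]
            if not 0.0 < r <= 1.0:
                raise ValueError(f"rate_5yr for {cat} must be in (0, 1]")
            if lam_lo_cum60 == 0.0:
                if r < 1.0:
                    raise ValueError("cannot express a rate relative to an event-free Lo")
                mult[cat] = 1.0
            else:
                mult[cat] = -np.log(r) / lam_lo_cum60
        else:
            raise ValueError(f"survival_spec for {cat} needs rate_5yr or hr_vs_lo")
        if mult[cat] < 0:
            raise ValueError(f"hazard multiplier for {cat} must be >= 0")
    return lam_lo_cum60, mult


def _draw_event_times(rng, categories, spec, shape):
    """Proportional-hazards event times; Weibull(shape) baseline, exponential when 1."""
    lam60, mult = _hazard_multipliers(spec)
    h = np.array([mult[c] for c in categories])
    e = rng.exponential(1.0, size=h.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        # cumulative hazard: h * lam60 * (t/60)^shape = e
        t = FIVE_YEARS_MONTHS * np.power(
            np.where(h * lam60 > 0, e / np.where(h * lam60 > 0, h * lam60, 1.0), np.inf),
            1.0 / shape,
        )
    t[h * lam60 <= 0] = np.inf
    return t


def _mixture_survival(spec, proportions, shape, extra_hazard=0.0):
    """S(t) of min(category event time, background death) under the mixture."""
    lam60, mult = _hazard_multipliers(spec)
    w = np.asarray(proportions, dtype=float)
    h = np.array([mult[c] for c in CATEGORIES])

    def S(t):
        t = np.asarray(t, dtype=float)
        cum = np.outer(h * lam60, np.power(t / FIVE_YEARS_MONTHS, shape))
        return (w[:, None] * np.exp(-cum - extra_hazard * t[None, :])).sum(axis=0)

    return S


def solve_uniform_censoring(
    target_median: float, survival_fn, lower_frac: float = 0.5
) -> tuple[float, float]:
    """Solve the support [L, U] of uniform administrative censoring.

    Finds U (with L = lower_frac * U) such that the median follow-up among
    censored observations — patients whose event time exceeds their
    censoring draw — equals ``target_median`` months.
    """
    if not 0.0 <= lower_frac < 1.0:
        raise ValueError("lower_frac must be in [0, 1)")
    if target_median <= 0:
        raise ValueError("target_median must be > 0")

    def censored_median(upper):
        low = lower_frac * upper
        grid = np.linspace(low, upper, 2001)
        dens = survival_fn(grid)  # unnormalized density of C | censored
        cum = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0
                                               * np.diff(grid))])
        total = cum[-1]
        if total <= 0:
            return low
        return float(np.interp(0.5 * total, cum, grid))

    lo_u = target_median * 1.0001
    hi_u = max(2.0, 1.5 / max(lower_frac, 1e-6)) * target_median
    f = lambda u: censored_median(u) - target_median
    if f(lo_u) > 0 or f(hi_u) < 0:
        raise ValueError("censoring target median is not attainable with this window")
    upper = brentq(f, lo_u, hi_u, xtol=1e-6)
    return lower_frac * upper, float(upper)


def _draw_censoring(rng, n, spec, survival_fn):
    fam = spec.get("family", "uniform_median")
    if fam == "fixed":
        return np.full(n, float(spec["time"]))
    if fam == "uniform":
        low, high = float(spec["low"]), float(spec["high"])
        if not 0 <= low < high:
            raise ValueError("uniform censoring needs 0 <= low < high")
        return rng.uniform(low, high, size=n)
    if fam == "uniform_median":
        low, high = solve_uniform_censoring(
            float(spec["target_median"]), survival_fn,
            float(spec.get("lower_frac", 0.5)),
        )
        return rng.uniform(low, high, size=n)
    raise ValueError(f"unknown censoring family {fam!r}")


# -- percentile construction -------------------------------------------------

def _construct_percentiles(rng, mean_targets, categories, ref, sd):
    """Four reference-grid percentiles per patient averaging into the sampled band.

    Draws centered perturbations around each target mean, clips and
    re-centers so the mean is exact, snaps each percentile to the grid its
    reference sequence can represent, then repairs any patient whose snapped
    mean crossed a band edge by stepping single percentiles one grid unit.
    """
    n = mean_targets.size
    sizes = np.array([ref.size(m, r) for (m, r) in DENSITY_COLUMNS], dtype=float)

    eps = rng.normal(0.0, sd, size=(n, 4))
    eps -= eps.mean(axis=1, keepdims=True)
    p = mean_targets[:, None] + eps
    for _ in range(100):
        p = np.clip(p, 0.0, 100.0)
        resid = mean_targets - p.mean(axis=1)
        if np.all(np.abs(resid) < 1e-12):
            break
        p += resid[:, None]
    p = np.clip(p, 0.0, 100.0)

    k = np.rint(p * sizes[None, :] / 100.0)
    snapped = 100.0 * k / sizes[None, :]
    means = snapped.sum(axis=1) / 4.0
    got = np.asarray(classify(means, "IS3"))
    bad = np.flatnonzero(got != categories)
    for i in bad:
        want = _CAT_ORDER[categories[i]]
        for _ in range(10000):
            have = _CAT_ORDER[classify(snapped[i].sum() / 4.0, "IS3")]
            if have == want:
                break
            if have > want:  # mean too high: pull the largest percentile down
                j = int(np.argmax(np.where(k[i] > 0, snapped[i], -np.inf)))
                k[i, j] -= 1
            else:            # mean too low: push the smallest percentile up
                j = int(np.argmin(np.where(k[i] < sizes, snapped[i], np.inf)))
                k[i, j] += 1
            snapped[i] = 100.0 * k[i] / sizes
        else:
            raise RuntimeError("percentile band repair did not terminate")
    return snapped, k.astype(int)


def _densities_from_grid(k, ref):
    """Inverse-percentile density lookup for grid indices (0 -> below minimum)."""
    out = np.empty(k.shape, dtype=float)
    for j, (m, r) in enumerate(DENSITY_COLUMNS):
        seq = ref[(m, r)]
        kj = k[:, j]
        vals = seq[np.maximum(kj - 1, 0)]
        out[:, j] = np.where(kj > 0, vals, 0.5 * seq[0])
    return out


# -- cohort assembly ---------------------------------------------------------

def _sample_categories(rng, n, proportions, exact):
    if exact:
        counts = np.floor(np.asarray(proportions) * n).astype(int)
        counts[0] += n - counts.sum()  # remainder to the reference category
        cats = np.repeat(np.array(CATEGORIES, dtype=object), counts)
        rng.shuffle(cats)
        return cats
    idx = rng.choice(3, size=n, p=np.asarray(proportions, dtype=float))
    return np.array(CATEGORIES, dtype=object)[idx]


def generate_cohort(
    config: GeneratorConfig, ref: ReferenceDistribution | None = None
) -> pd.DataFrame:
    """Generate a patient-level cohort table per the configured conditions.

    Deterministic given ``config.seed``.  When ``config.with_densities`` the
    table carries four densities whose rescoring through the scoring module
    reproduces ``true_category`` exactly.
    """
    if ref is None and config.with_densities:
        ref = default_reference()
    n = config.n_patients
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_cat, rng_pct, rng_surv, rng_cens, rng_cov, rng_center = (
        np.random.default_rng(s) for s in streams
    )

    cats = _sample_categories(rng_cat, n, config.category_proportions,
                              config.exact_counts)

    # percentiles and densities
    if config.with_densities:
        bands = np.array([CATEGORY_BANDS[c] for c in cats])
        mean_targets = rng_pct.uniform(bands[:, 0], bands[:, 1])
        snapped, kgrid = _construct_percentiles(
            rng_pct, mean_targets, cats, ref, config.percentile_sd
        )
        dens = _densities_from_grid(kgrid, ref)
        true_mean = snapped.sum(axis=1) / 4.0
    else:
        dens = np.full((n, 4), np.nan)
        true_mean = np.full(n, np.nan)

    # event and death processes
    rec_true = _draw_event_times(rng_surv, cats, config.survival_spec,
                                 config.weibull_shape)
    lam_bg = config.death_without_recurrence_rate
    bg_death = (rng_surv.exponential(1.0 / lam_bg, size=n) if lam_bg > 0
                else np.full(n, np.inf))
    lam_post = config.post_recurrence_death_rate
    post = (rng_surv.exponential(1.0 / lam_post, size=n) if lam_post > 0
            else np.full(n, np.inf))
    death_true = np.minimum(bg_death, rec_true + post)

    surv_fn = _mixture_survival(config.survival_spec, config.category_proportions,
                                config.weibull_shape, extra_hazard=lam_bg)
    censor = _draw_censoring(rng_cens, n, config.censoring_spec, surv_fn)

    death_obs = death_true <= censor
    rec_obs = (rec_true <= censor) & (rec_true <= death_true)
    followup_end = np.minimum(np.where(death_obs, death_true, np.inf), censor)
    rec_time = np.where(rec_obs, rec_true, followup_end)
    death_time = np.where(death_obs, death_true, censor)

    # covariates (marginal, independent)
    cov = config.covariate_prevalences
    male = rng_cov.random(n) < cov["male_fraction"]
    age = np.clip(rng_cov.normal(cov["age_median"], cov["age_sd"], size=n), 18, 99)
    stage1 = rng_cov.random(n) < cov["stage1_fraction"]
    stage = np.where(stage1, "I", "II")

    def _draw_cat(dist: dict, size):
        keys = sorted(dist)
        probs = np.array([dist[k] for k in keys], dtype=float)
        probs = probs / probs.sum()
        return np.array(keys, dtype=object)[rng_cov.choice(len(keys), size=size, p=probs)]

    t_stage = np.empty(n, dtype=object)
    t_stage[stage1] = _draw_cat(cov["t_stage_stage1"], int(stage1.sum()))
    t_stage[~stage1] = _draw_cat(cov["t_stage_stage2"], int((~stage1).sum()))
    msi = _draw_cat(cov["msi"], n)
    velipi = _draw_cat(cov["velipi"], n)
    differentiation = _draw_cat(cov["differentiation"], n)
    sided = np.where(rng_cov.random(n) < cov["sidedness_right_fraction"],
                     "right", "left")
    chemo_p = np.where(stage1, cov["chemotherapy_stage1"], cov["chemotherapy_stage2"])
    chemo = rng_cov.random(n) < chemo_p
    perforation = rng_cov.random(n) < cov["perforation_fraction"]
    ln_examined = rng_cov.poisson(cov["ln_examined_mean"], size=n)
    preop = rng_cov.random(n) < max(cov.get("preoperative_treatment_fraction", 0.0),
                                    config.preop_rate)

    center = rng_center.integers(1, config.n_centers + 1, size=n)
    cohort_id = np.where(rng_center.random(n) < config.cohort_split, 1, 2)

    table = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "cohort": cohort_id,
        "center": center,
        "gender": np.where(male, "male", "female"),
        "age": np.round(age, 1),
        "stage": stage,
        "t_stage": t_stage,
        "n_stage": np.zeros(n, dtype=int),
        "sidedness": sided,
        "msi": msi,
        "velipi": velipi,
        "differentiation": differentiation,
        "perforation": perforation,
        "ln_examined": ln_examined,
        "chemotherapy": chemo,
        "preoperative_treatment": preop,
        "recurrence_time": rec_time,
        "recurrence_observed": rec_obs,
        "death_time": death_time,
        "death_observed": death_obs,
        "censor_time": censor,
        "true_category": cats,
        "true_mean_percentile": true_mean,
        "cd3_ct": dens[:, 0],
        "cd3_im": dens[:, 1],
        "cd8_ct": dens[:, 2],
        "cd8_im": dens[:, 3],
    })
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 CSV with '.' decimals and stable float format."""
    table.to_csv(path, index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
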