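"""Endpoint construction and subgroup definitions.

Endpoints (months from surgery):

* TTR — time to recurrence: event at first recurrence; deaths without prior
  recurrence censor TTR at the death time.
* DFS — disease-free survival: event at the first of recurrence or death
  from any cause.
* OS  — overall survival: event at death from any cause.

Stage II risk partition: high risk = VELIPI+ (venous emboli, lymphatic or
perineural invasion) or T4, or perforation, or poor differentiation, or
fewer than 12 lymph nodes examined; low risk = T1-T3 with none of these.
A very-high-risk category combines T4 with VELIPI+ (conjunction by default;
the disjunctive reading is available via ``very_high_risk_how="any"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ENDPOINTS = ("TTR", "DFS", "OS")

SUBGROUP_NAMES = (
    "stage1", "stage2", "stage1_mss", "stage2_mss", "stage2_untreated",
    "high_risk_stage2", "low_risk_stage2", "very_high_risk_stage2",
    "t4n0", "t4n0_untreated",
)

EXCL_PREOP = "PREOP"


@dataclass(frozen=True)
class Endpoint:
    kind: str
    time: float
    event: bool

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("endpoint time must be >= 0")


def derive_endpoint(p, kind: str) -> Endpoint:
    """Endpoint for a single patient record (mapping-like with outcome fields)."""
    kind = kind.upper()
    rec_t, rec_e = float(p["recurrence_time"]), bool(p["recurrence_observed"])
    dth_t, dth_e = float(p["death_time"]), bool(p["death_observed"])
    cen_t = float(p["censor_time"])
    if rec_e and dth_e and rec_t > dth_t:
        raise ValueError("observed recurrence after observed death")
    if kind == "TTR":
        if rec_e:
            return Endpoint("TTR", rec_t, True)
        cutoff = min(dth_t if dth_e else np.inf, cen_t)
        return Endpoint("TTR", cutoff, False)
    if kind == "DFS":
        if rec_e or dth_e:
            first = min(rec_t if rec_e else np.inf, dth_t if dth_e else np.inf)
            return Endpoint("DFS", first, True)
        return Endpoint("DFS", cen_t, False)
    if kind == "OS":
        if dth_e:
            return Endpoint("OS", dth_t, True)
        return Endpoint("OS", cen_t, False)
    raise ValueError(f"unknown endpoint kind {kind!r}")


def derive_endpoints(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized endpoint derivation: appends ``{ttr,dfs,os}_{time,event}``."""
    out = cohort.copy()
    rec_t = out["recurrence_time"].to_numpy(dtype=float)
    rec_e = out["recurrence_observed"].to_numpy(dtype=bool)
    dth_t = out["death_time"].to_numpy(dtype=float)
    dth_e = out["death_observed"].to_numpy(dtype=bool)
    cen_t = out["censor_time"].to_numpy(dtype=float)
    bad = rec_e & dth_e & (rec_t > dth_t)
    if bad.any():
        raise ValueError(f"{bad.sum()} records with observed recurrence after death")

    death_or_admin = np.minimum(np.where(dth_e, dth_t, np.inf), cen_t)
    out["ttr_time"] = np.where(rec_e, rec_t, death_or_admin)
    out["ttr_event"] = rec_e

    any_event = rec_e | dth_e
    first = np.minimum(np.where(rec_e, rec_t, np.inf), np.where(dth_e, dth_t, np.inf))
    out["dfs_time"] = np.where(any_event, first, cen_t)
    out["dfs_event"] = any_event

    out["os_time"] = np.where(dth_e, dth_t, cen_t)
    out["os_event"] = dth_e
    return out


def apply_exclusions(cohort: pd.DataFrame, quantifications=None):
    """Remove preoperative-treated patients and QC failures.

    ``quantifications``: optional mapping patient_id -> SlideQuantification
    (with QC populated) or DataFrame with ``patient_id``/``qc_pass``/
    ``qc_reasons``.  Returns ``(retained_cohort, exclusion_log)`` where the
    log is a (reason, count) table, consort style.
    """
    reasons = {}
    keep = np.ones(len(cohort), dtype=bool)

    preop = cohort.get("preoperative_treatment")
    if preop is not None:
        m = preop.to_numpy(dtype=bool)
        reasons[EXCL_PREOP] = int(m.sum())
        keep &= ~m

    if quantifications is not None:
        if isinstance(quantifications, pd.DataFrame):
            qmap = {
                row["patient_id"]: (bool(row["qc_pass"]),
                                    row.get("qc_reasons", "") or "")
                for _, row in quantifications.iterrows()
            }
        else:
            qmap = {q.patient_id: (q.qc_pass, ";".join(q.qc_reasons))
                    for q in (quantifications.values()
                              if isinstance(quantifications, dict)
                              else quantifications)}
        for i, pid in enumerate(cohort["patient_id"]):
            if pid not in qmap:
                raise KeyError(f"no quantification for patient {pid!r}")
            qc_ok, why = qmap[pid]
            if not qc_ok and keep[i]:
                keep[i] = False
                for code in filter(None, why.split(";")):
                    reasons[code] = reasons.get(code, 0) + 1

    log = pd.DataFrame(
        sorted(reasons.items()), columns=["reason", "count"]
    )
    return cohort[keep].reset_index(drop=True), log


# -- risk features -----------------------------------------------------------

def _high_risk_features(df: pd.DataFrame) -> pd.Series:
    """Boolean: any stage II high-risk feature present (NaN-unsafe callers
    should mask unknown VELIPI/differentiation first)."""
    return (
        (df["velipi"] == "positive")
        | (df["t_stage"] == "T4")
        | df["perforation"].astype(bool)
        | (df["differentiation"] == "poor")
        | (df["ln_examined"] < 12)
    )


def _risk_fields_complete(df: pd.DataFrame) -> pd.Series:
    return (df["velipi"] != "unknown") & (df["differentiation"] != "unknown")


def subgroup(
    cohort: pd.DataFrame, name: str, very_high_risk_how: str = "all"
) -> pd.DataFrame:
    """Filter a cohort to one of the named analysis subgroups.

    Patients with unknown VELIPI or differentiation are excluded from the
    risk-partition subgroups only; MSI-unknown patients are dropped from MSS
    subgroups.  ``untreated`` means no (adjuvant) chemotherapy.
    """
    df = cohort
    stage2 = df["stage"] == "II"
    if name == "stage1":
        m = df["stage"] == "I"
    elif name == "stage2":
        m = stage2
    elif name == "stage1_mss":
        m = (df["stage"] == "I") & (df["msi"] == "MSS")
    elif name == "stage2_mss":
        m = stage2 & (df["msi"] == "MSS")
    elif name == "stage2_untreated":
        m = stage2 & ~df["chemotherapy"].astype(bool)
    elif name == "high_risk_stage2":
        m = stage2 & _risk_fields_complete(df) & _high_risk_features(df)
    elif name == "low_risk_stage2":
        m = (stage2 & _risk_fields_complete(df)
             & df["t_stage"].isin(["T1", "T2", "T3"]) & ~_high_risk_features(df))
    elif name == "very_high_risk_stage2":
        t4 = df["t_stage"] == "T4"
        vel = df["velipi"] == "positive"
        if very_high_risk_how == "all":
            m = stage2 & _risk_fields_complete(df) & t4 & vel
        elif very_high_risk_how == "any":
            m = stage2 & _risk_fields_complete(df) & (t4 | vel)
        else:
            raise ValueError("very_high_risk_how must be 'all' or 'any'")
    elif name == "t4n0":
        m = stage2 & (df["t_stage"] == "T4") & (df["n_stage"] == 0)
    elif name == "t4n0_untreated":
        m = (stage2 & (df["t_stage"] == "T4") & (df["n_stage"] == 0)
             & ~df["chemotherapy"].astype(bool))
    else:
        raise KeyError(f"unknown subgroup {name!r}; expected one of {SUBGROUP_NAMES}")
    return df[m].reset_index(drop=True)
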