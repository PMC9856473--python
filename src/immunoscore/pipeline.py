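"""End-to-end orchestration: generate/load -> score -> endpoints -> analyses.

A run produces, for each requested (subgroup x endpoint x grouping), the
univariate comparison table, a center-stratified multivariable Cox summary
with the chi-square relative-importance breakdown, and Kaplan-Meier curve
exports, plus a JSON manifest recording the config hash, seed, exclusion
funnel and subgroup sizes.  Outputs are deterministic given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohorts import ENDPOINTS, SUBGROUP_NAMES, apply_exclusions, derive_endpoints, subgroup
from .scoring import score_cohort
from .simulate import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from .survival import chi2_importance, compare_groups, cox_fit, km_curve

log = logging.getLogger("immunoscore")

#: Adjustment set of the multivariable models (strata: participating center).
MULTIVARIABLE_TERMS = ["is3", "gender", "t_stage", "n_stage", "msi"]

DEFAULT_ANALYSIS = {
    "subgroups": list(SUBGROUP_NAMES),
    "endpoints": list(ENDPOINTS),
    "groupings": ["is2", "is3"],
}


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _km_export(cohort: pd.DataFrame, endpoint: str, grouping: str) -> pd.DataFrame:
    rows = []
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for level, sub in cohort.groupby(grouping, sort=False):
        km = km_curve(sub[tcol].to_numpy(), sub[ecol].to_numpy(dtype=bool))
        for t, s, lo, hi, n_risk in km.as_table():
            rows.append((level, t, s, lo, hi, n_risk))
    return pd.DataFrame(
        rows, columns=["level", "time", "survival", "lower", "upper", "n_at_risk"]
    )


def run(config: dict, outdir, force: bool = False, seed: int | None = None) -> Path:
    """Execute a full analysis run into ``outdir`` (never overwritten unless force)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is non-empty; pass force to reuse")
    outdir.mkdir(parents=True, exist_ok=True)

    config = dict(config)
    if seed is not None:
        config.setdefault("generator", {})
        config["generator"]["seed"] = int(seed)

    # 1. obtain cohort
    if "cohort_file" in config:
        cohort = read_cohort(config["cohort_file"])
        log.info("loaded cohort of %d patients from %s", len(cohort),
                 config["cohort_file"])
    else:
        gen_cfg = GeneratorConfig(**config.get("generator", {}))
        cohort = generate_cohort(gen_cfg)
        log.info("generated synthetic cohort of %d patients (seed %d)",
                 len(cohort), gen_cfg.seed)
        write_cohort(cohort, outdir / "cohort.csv")

    # 2. exclusions (preoperative treatment; QC happens upstream of densities)
    n0 = len(cohort)
    cohort, excl_log = apply_exclusions(cohort)
    excl_log.to_csv(outdir / "exclusions.csv", index=False)
    log.info("exclusion funnel: %d -> %d patients", n0, len(cohort))
    for _, r in excl_log.iterrows():
        log.info("  excluded %d for %s", r["count"], r["reason"])

    # 3. score + endpoints
    scored = derive_endpoints(score_cohort(cohort))
    write_cohort(scored, outdir / "scored_cohort.csv")

    analysis = {**DEFAULT_ANALYSIS, **config.get("analysis", {})}
    manifest = {
        "config_hash": config_hash(config),
        "input_paths": ([config["cohort_file"]] if "cohort_file" in config else []),
        "seed": config.get("generator", {}).get("seed"),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_input": n0,
        "n_analyzed": len(cohort),
        "exclusions": {r["reason"]: int(r["count"]) for _, r in excl_log.iterrows()},
        "subgroup_sizes": {},
        "failures": [],
    }

    for sg in analysis["subgroups"]:
        sub = subgroup(scored, sg)
        manifest["subgroup_sizes"][sg] = len(sub)
        if len(sub) == 0:
            manifest["failures"].append(f"{sg}: empty subgroup")
            continue
        sgdir = outdir / sg
        sgdir.mkdir(exist_ok=True)
        for ep in analysis["endpoints"]:
            ep = ep.lower()
            for grouping in analysis["groupings"]:
                tag = f"{ep}_{grouping}"
                try:
                    comp = compare_groups(sub, ep, grouping, strata="center")
                    table = comp.table.copy()
                    table["logrank_p"] = comp.logrank_p
                    table["c_index"] = comp.c_index
                    table["c_index_lower"] = comp.c_index_ci[0]
                    table["c_index_upper"] = comp.c_index_ci[1]
                    table["tau"] = comp.tau
                    table.to_csv(sgdir / f"comparison_{tag}.csv",
                                 float_format="%.10g")
                    _km_export(sub, ep, grouping).to_csv(
                        sgdir / f"km_{tag}.csv", index=False, float_format="%.10g")
                except Exception as exc:  # isolate per-block failures
                    manifest["failures"].append(f"{sg}/{tag}: {exc}")
                    log.warning("block %s/%s failed: %s", sg, tag, exc)
            # multivariable model per endpoint (three-level score + adjusters)
            try:
                fit = cox_fit(sub, MULTIVARIABLE_TERMS, duration_col=f"{ep}_time",
                              event_col=f"{ep}_event", strata="center",
                              reference_levels={"is3": "Lo"})
                fit.summary().to_csv(sgdir / f"multivariable_{ep}.csv",
                                     float_format="%.10g")
                imp = chi2_importance(fit)
                imp.table.to_csv(sgdir / f"importance_{ep}.csv",
                                 float_format="%.10g")
            except Exception as exc:
                manifest["failures"].append(f"{sg}/multivariable_{ep}: {exc}")
                log.warning("multivariable %s/%s failed: %s", sg, ep, exc)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if manifest["failures"]:
        log.warning("%d analysis blocks failed", len(manifest["failures"]))
    return outdir
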