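"""Cox regression: oracles, recovery, stratification, Wald/LR, importance."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from immunoscore.survival import (
    ConvergenceWarning,
    StratifiedCoxPH,
    chi2_importance,
    cox_fit,
    lr_test,
    wald_test,
)

from conftest import random_survival_data


def simulate_ph(rng, n, coefs, censor=(5.0, 60.0), strata_k=None, binary=True):
    p = len(coefs)
    if binary:
        X = (rng.random((n, p)) < 0.5).astype(float)
    else:
        X = rng.normal(size=(n, p))
    lam0 = 0.02
    t = rng.exponential(1.0 / (lam0 * np.exp(X @ np.asarray(coefs))))
    c = rng.uniform(*censor, size=n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["time"] = np.minimum(t, c)
    df["event"] = t <= c
    if strata_k:
        df["center"] = rng.integers(0, strata_k, size=n)
    return df


class TestCoxFit:
    def test_identical_groups_null_coefficient(self):
        rng = np.random.default_rng(1)
        t, e = random_survival_data(rng, 600)
        df = pd.DataFrame({"g": np.repeat([0.0, 1.0], 300), "time": t, "event": e})
        fit = cox_fit(df, ["g"], "time", "event")
        assert abs(fit.coef["g"]) < 0.25  # |HR-1| within sampling noise
        chi2, df_, p = wald_test(fit, "g")
        assert p > 0.01

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(2)
        df = simulate_ph(rng, 400, [0.7, -0.4])
        df["center"] = 1
        plain = cox_fit(df, ["x0", "x1"], "time", "event")
        strat = cox_fit(df, ["x0", "x1"], "time", "event", strata="center")
        np.testing.assert_allclose(plain.coef, strat.coef, atol=1e-12)
        assert plain.log_likelihood == pytest.approx(strat.log_likelihood)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("tied_times", [False, True])
    def test_matches_lifelines(self, ties, tied_times):
        rng = np.random.default_rng(3)
        for _ in range(5):
            df = simulate_ph(rng, 300, [0.8, -0.5, 0.0], binary=False)
            if tied_times:
                df["time"] = np.ceil(df["time"])
            fit = cox_fit(df, ["x0", "x1", "x2"], "time", "event", ties=ties)
            cph = CoxPHFitter().fit(df[["x0", "x1", "x2", "time", "event"]],
                                    "time", "event",
                                    fit_options={"precision": 1e-12})
            if ties == "efron":  # lifelines implements Efron only
                np.testing.assert_allclose(fit.coef.to_numpy(),
                                           cph.params_.to_numpy(), atol=1e-6)
                np.testing.assert_allclose(
                    fit.summary()["se"].to_numpy(),
                    cph.standard_errors_.to_numpy(), atol=1e-6)
                assert fit.log_likelihood == pytest.approx(
                    cph.log_likelihood_, abs=1e-6)

    def test_breslow_matches_r_survival_style_on_ties(self):
        # Breslow vs Efron differ on tied data; both near truth on untied data
        rng = np.random.default_rng(4)
        df = simulate_ph(rng, 500, [0.6])
        fe = cox_fit(df, ["x0"], "time", "event", ties="efron")
        fb = cox_fit(df, ["x0"], "time", "event", ties="breslow")
        np.testing.assert_allclose(fe.coef, fb.coef, atol=1e-10)  # no ties
        df["time"] = np.ceil(df["time"])
        fe = cox_fit(df, ["x0"], "time", "event", ties="efron")
        fb = cox_fit(df, ["x0"], "time", "event", ties="breslow")
        assert abs(fe.coef["x0"] - fb.coef["x0"]) > 1e-6

    def test_stratified_matches_lifelines(self):
        rng = np.random.default_rng(5)
        df = simulate_ph(rng, 500, [0.5, -0.3], strata_k=5)
        fit = cox_fit(df, ["x0", "x1"], "time", "event", strata="center")
        cph = CoxPHFitter().fit(df, "time", "event", strata=["center"])
        np.testing.assert_allclose(fit.coef.to_numpy(), cph.params_.to_numpy(),
                                   atol=1e-6)

    def test_true_hazard_ratio_recovery(self):
        rng = np.random.default_rng(6)
        df = simulate_ph(rng, 5000, [np.log(0.5)])
        fit = cox_fit(df, ["x0"], "time", "event")
        assert 0.45 < np.exp(fit.coef["x0"]) < 0.55

    def test_parameter_recovery_unbiased(self):
        # mean coefficient bias over replicates small relative to the true log-HR
        rng = np.random.default_rng(7)
        true = np.log(0.5)
        est = []
        for _ in range(200):
            df = simulate_ph(rng, 2000, [true])
            est.append(cox_fit(df, ["x0"], "time", "event").coef["x0"])
        assert abs(np.mean(est) - true) < 0.02 * abs(true)

    def test_categorical_dummy_coding(self):
        rng = np.random.default_rng(8)
        n = 400
        g = rng.choice(["Lo", "Int", "Hi"], size=n)
        t, e = random_survival_data(rng, n)
        df = pd.DataFrame({"grp": g, "time": t, "event": e})
        fit = cox_fit(df, ["grp"], "time", "event",
                      reference_levels={"grp": "Lo"})
        assert set(fit.coef.index) == {"grp[Int]", "grp[Hi]"}
        assert fit.terms["grp"] == ["grp[Hi]", "grp[Int]"] or \
            set(fit.terms["grp"]) == {"grp[Int]", "grp[Hi]"}

    def test_constant_term_dropped(self):
        rng = np.random.default_rng(9)
        df = simulate_ph(rng, 200, [0.5])
        df["n_stage"] = 0
        fit = cox_fit(df, ["x0", "n_stage"], "time", "event")
        assert "n_stage" not in fit.terms

    def test_constant_within_strata_rejected(self):
        rng = np.random.default_rng(10)
        df = simulate_ph(rng, 200, [0.5], strata_k=2)
        df["x0"] = df["center"].astype(float)  # constant within each stratum
        with pytest.raises(ValueError, match="constant within"):
            cox_fit(df, ["x0"], "time", "event", strata="center")

    def test_separation_flagged(self):
        # perfect separation: all events in one group -> monotone likelihood
        df = pd.DataFrame({
            "x": np.repeat([0.0, 1.0], 20),
            "time": np.concatenate([np.arange(1, 21), np.arange(100, 120)]),
            "event": np.concatenate([np.ones(20), np.zeros(20)]).astype(bool),
        })
        with pytest.warns(ConvergenceWarning):
            fit = cox_fit(df, ["x"], "time", "event")
        assert not fit.converged

    def test_sklearn_protocol(self):
        est = StratifiedCoxPH(ties="breslow")
        assert est.get_params()["ties"] == "breslow"
        rng = np.random.default_rng(11)
        df = simulate_ph(rng, 200, [0.5])
        est.fit(df[["x0"]], (df["time"].to_numpy(), df["event"].to_numpy()))
        assert hasattr(est, "coef_") and est.converged_
        lp = est.predict(df[["x0"]])
        assert lp.shape == (200,)
        np.testing.assert_allclose(est.hazard_ratios_, np.exp(est.coef_))


class TestWald:
    def test_one_df_is_squared_z(self):
        rng = np.random.default_rng(12)
        df = simulate_ph(rng, 300, [0.6])
        fit = cox_fit(df, ["x0"], "time", "event")
        chi2, dof, p = wald_test(fit, "x0")
        z = fit.coef["x0"] / fit.summary().loc["x0", "se"]
        assert chi2 == pytest.approx(z * z, rel=1e-12)
        assert dof == 1
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)

    def test_matches_lifelines_p(self):
        rng = np.random.default_rng(13)
        df = simulate_ph(rng, 400, [0.7, -0.2], binary=False)
        fit = cox_fit(df, ["x0", "x1"], "time", "event")
        cph = CoxPHFitter().fit(df[["x0", "x1", "time", "event"]], "time", "event")
        for term in ("x0", "x1"):
            _, _, p = wald_test(fit, term)
            assert p == pytest.approx(cph.summary.loc[term, "p"], abs=1e-6)

    def test_unknown_term_rejected(self):
        rng = np.random.default_rng(14)
        df = simulate_ph(rng, 100, [0.5])
        fit = cox_fit(df, ["x0"], "time", "event")
        with pytest.raises(KeyError):
            wald_test(fit, "nope")


class TestLikelihoodRatio:
    def test_same_model_gives_null(self):
        rng = np.random.default_rng(15)
        df = simulate_ph(rng, 200, [0.5])
        fit = cox_fit(df, ["x0"], "time", "event")
        chi2, dof, p = lr_test(fit, fit)
        assert (chi2, dof, p) == (0.0, 0, 1.0)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(16)
        df = simulate_ph(rng, 200, [0.5, 0.3])
        f1 = cox_fit(df, ["x0"], "time", "event")
        f2 = cox_fit(df, ["x1"], "time", "event")
        with pytest.raises(ValueError, match="nested"):
            lr_test(f1, f2)

    def test_noise_covariate_null_uniform(self):
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            df = simulate_ph(rng, 120, [0.5])
            df["noise"] = rng.normal(size=120)
            full = cox_fit(df, ["x0", "noise"], "time", "event")
            red = cox_fit(df, ["x0"], "time", "event")
            pvals.append(lr_test(full, red)[2])
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_power_for_true_effect(self):
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(100):
            df = simulate_ph(rng, 400, [np.log(0.3)])
            full = cox_fit(df, ["x0"], "time", "event")
            # null model: fit an intercept-free empty reduction via a constant
            chi2 = 2 * (full.log_likelihood - full.null_log_likelihood)
            p = stats.chi2.sf(chi2, 1)
            hits += p < 0.001
        assert hits >= 99


class TestImportance:
    def test_single_term_is_everything(self):
        rng = np.random.default_rng(19)
        df = simulate_ph(rng, 300, [0.8])
        imp = chi2_importance(cox_fit(df, ["x0"], "time", "event"))
        assert imp.table.loc["x0", "relative_pct"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(20)
        df = simulate_ph(rng, 400, [0.8, -0.5, 0.2])
        imp = chi2_importance(cox_fit(df, ["x0", "x1", "x2"], "time", "event"))
        assert imp.table["relative_pct"].sum() == pytest.approx(100.0)
        assert (imp.table["relative_pct"] >= 0).all()

    def test_symmetric_effects_split_evenly(self):
        rng = np.random.default_rng(21)
        shares = []
        for _ in range(30):
            df = simulate_ph(rng, 2500, [0.7, 0.7])
            imp = chi2_importance(cox_fit(df, ["x0", "x1"], "time", "event"))
            shares.append(imp.table.loc["x0", "relative_pct"])
        assert abs(np.mean(shares) - 50.0) < 5.0

    def test_adjust_df_switch(self):
        rng = np.random.default_rng(22)
        df = simulate_ph(rng, 400, [0.9, 0.1])
        fit = cox_fit(df, ["x0", "x1"], "time", "event")
        raw = chi2_importance(fit, adjust_df=False)
        adj = chi2_importance(fit, adjust_df=True)
        assert raw.total_chi2 >= adj.total_chi2
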