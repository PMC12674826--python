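import numpy as np
import pandas as pd
import pytest

from appwt import synthetic as syn
from appwt.fitting import PopulationFit
from appwt.survival import (CollinearityError, cox_fit, cox_lasso_path,
                            km_logrank, lasso_select, parameter_forest,
                            survival_frame, threshold_scan)
from conftest import make_individual

# six subjects, all events, no ties; the covariate is interleaved so the
# partial likelihood has a finite interior maximum (a blockwise covariate
# with all one group's events first has a monotone likelihood)
TOY = pd.DataFrame({
    "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    "event": [1, 1, 1, 1, 1, 1],
    "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
})


def _brute_force_cox_beta(df, step=1e-4, lo=-4.0, hi=4.0):
    """Grid maximization of the (untied) Cox partial likelihood."""
    time = df["time"].to_numpy()
    x = df["x"].to_numpy()
    order = np.argsort(time)
    x = x[order]
    betas = np.arange(lo, hi + step, step)
    best_b, best_pl = None, -np.inf
    for b in betas:
        risk = np.exp(b * x)
        denom = np.cumsum(risk[::-1])[::-1]  # risk set sums at each event
        pl = np.sum(b * x - np.log(denom))
        if pl > best_pl:
            best_pl, best_b = pl, b
    return best_b


class TestCoxFit:
    def test_symmetric_event_pattern_gives_null(self):
        df = pd.DataFrame({"time": [1, 1, 2, 2, 3, 3],
                           "event": [1] * 6,
                           "x": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]})
        res = cox_fit(df, ["x"])
        assert res.table.loc["x", "coef"] == pytest.approx(0.0, abs=1e-8)
        assert res.hr("x") == pytest.approx(1.0, abs=1e-8)

    def test_toy_matches_partial_likelihood_grid(self):
        res = cox_fit(TOY, ["x"])
        oracle = _brute_force_cox_beta(TOY)
        assert res.table.loc["x", "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_label_swap_reciprocity(self):
        res = cox_fit(TOY, ["x"])
        flipped = TOY.assign(x=1.0 - TOY["x"])
        res2 = cox_fit(flipped, ["x"])
        assert res2.hr("x") == pytest.approx(1.0 / res.hr("x"), rel=1e-10)

    def test_consistency_large_sample(self):
        rng = np.random.default_rng(2)
        n = 1000
        x = rng.standard_normal(n)
        u = rng.random(n)
        t = -np.log(u) / (0.01 * np.exp(0.5 * x))
        cens = np.full(n, 400.0)
        df = pd.DataFrame({"time": np.minimum(t, cens),
                           "event": (t <= cens).astype(int), "x": x})
        res = cox_fit(df, ["x"])
        se = (np.log(res.table.loc["x", "ci_high"])
              - np.log(res.table.loc["x", "ci_low"])) / (2 * 1.96)
        assert abs(res.table.loc["x", "coef"] - 0.5) < 3 * se

    def test_no_events_rejected(self):
        df = TOY.assign(event=0)
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_separation_flagged(self):
        # the binary covariate perfectly orders the event times
        df = pd.DataFrame({"time": [1, 2, 3, 10, 11, 12],
                           "event": [1] * 6,
                           "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0] })
        res = cox_fit(df, ["x"])
        assert res.flagged or res.table.loc["x", "coef"] < 10


class TestLasso:
    def test_no_candidates_returns_empty(self):
        sel = lasso_select(TOY, [])
        assert sel.selected == []

    def test_strong_single_covariate_selected(self):
        rng = np.random.default_rng(4)
        n = 500
        x = rng.standard_normal(n)
        t = -np.log(rng.random(n)) / (0.01 * np.exp(1.0 * x))
        df = pd.DataFrame({"time": np.minimum(t, 300.0),
                           "event": (t <= 300.0).astype(int), "x": x})
        sel = lasso_select(df, ["x"], seed=0)
        assert sel.selected == ["x"]

    def test_noise_covariates_rarely_selected(self):
        sizes = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            n = 500
            X = rng.standard_normal((n, 10))
            t = -np.log(rng.random(n)) / 0.01
            df = pd.DataFrame(X, columns=[f"z{i}" for i in range(10)])
            df["time"] = np.minimum(t, 300.0)
            df["event"] = (t <= 300.0).astype(int)
            sel = lasso_select(df, [f"z{i}" for i in range(10)], seed=rep)
            sizes.append(len(sel.selected))
        assert np.mean(sizes) < 1.0

    def test_vanishing_penalty_matches_cox(self):
        rng = np.random.default_rng(5)
        n = 300
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        t = -np.log(rng.random(n)) / (0.01 * np.exp(0.6 * x1 - 0.4 * x2))
        df = pd.DataFrame({"time": np.minimum(t, 300.0),
                           "event": (t <= 300.0).astype(int),
                           "x1": x1, "x2": x2})
        est, alphas, mu, sd, data = cox_lasso_path(df, ["x1", "x2"],
                                                   alphas=[1e-7])
        # unpenalized Cox on the same standardized design
        std = data.copy()
        std[["x1", "x2"]] = (std[["x1", "x2"]] - mu) / sd
        ref = cox_fit(std, ["x1", "x2"])
        for j, name in enumerate(["x1", "x2"]):
            assert est.coef_[j, 0] == pytest.approx(
                ref.table.loc[name, "coef"], abs=5e-3)

    def test_too_few_events_for_folds(self):
        df = TOY.copy()
        df.loc[2:, "event"] = 0
        with pytest.raises(ValueError):
            lasso_select(df, ["x"], folds=5)


class TestKMLogrank:
    def test_identical_groups_no_difference(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 0, 1, 1])
        res = km_logrank(np.r_[t, t], np.r_[e, e],
                         ["a"] * 4 + ["b"] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_toy_matches_hypergeometric_accumulation(self):
        """Hand O-E computation for the 6-subject toy."""
        t = TOY["time"].to_numpy()
        e = TOY["event"].to_numpy()
        g = TOY["x"].to_numpy()
        # logrank chi-square via direct O-E and hypergeometric variance
        o_minus_e, var = 0.0, 0.0
        for ti in np.unique(t[e == 1]):
            at_risk = t >= ti
            n_tot = at_risk.sum()
            n_1 = (at_risk & (g == 1)).sum()
            d = ((t == ti) & (e == 1)).sum()
            d_1 = ((t == ti) & (e == 1) & (g == 1)).sum()
            o_minus_e += d_1 - d * n_1 / n_tot
            if n_tot > 1:
                var += d * (n_1 / n_tot) * (1 - n_1 / n_tot) * (n_tot - d) / (n_tot - 1)
        chi2 = o_minus_e ** 2 / var
        res = km_logrank(t, e, g)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 40).round(2)
        res = km_logrank(np.r_[t, t + 0.001], np.ones(80),
                        ["a"] * 40 + ["b"] * 40)
        curve = res.curves["a"]
        for _, row in curve.iloc[1:].iterrows():
            emp = np.mean(t > row["time"])
            assert row["survival"] == pytest.approx(emp, abs=1e-10)

    def test_power_under_hazard_ratio_two(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(300 + rep)
            t1 = rng.exponential(10.0, 200)
            t2 = rng.exponential(5.0, 200)
            t = np.r_[t1, t2]
            res = km_logrank(np.minimum(t, 30.0), (t <= 30.0).astype(int),
                             ["a"] * 200 + ["b"] * 200)
            if res.pvalue < 0.05:
                hits += 1
        assert hits >= 95

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [1, 1, 1], ["a", "a", "a"])


def _random_truth_fit(n, seed, pop=None):
    pop = pop or syn.chemotherapy_population()
    rng = np.random.default_rng(seed)
    inds, covs = {}, {}
    for i in range(n):
        sid = f"s{i}"
        cov = syn.sample_covariates("chemotherapy", rng)
        inds[sid] = syn.sample_individual(pop, cov, rng)
        covs[sid] = cov
    fit = PopulationFit.from_truth(pop, inds, covariates=covs)
    return fit, rng


class TestParameterForest:
    def test_null_hazard_coverage(self):
        """Independent survival: each HR interval covers 1 most of the time."""
        cover = {name: 0 for name in ("L0", "PMAX", "SLP", "WT0", "Imax")}
        n_rep = 100
        for rep in range(n_rep):
            fit, rng = _random_truth_fit(120, 500 + rep)
            t = rng.exponential(300.0, 120)
            surv = pd.DataFrame({"time": np.minimum(t, 900.0),
                                 "event": (t <= 900.0).astype(int)},
                                index=list(fit.ebes))
            res = parameter_forest(fit, surv)
            for name in cover:
                lo = res.table.loc[name, "ci_low"]
                hi = res.table.loc[name, "ci_high"]
                if lo <= 1.0 <= hi:
                    cover[name] += 1
        for name, c in cover.items():
            assert c / n_rep >= 0.9, name

    def test_duplicate_parameter_column_flagged(self):
        fit, rng = _random_truth_fit(60, 3)
        t = rng.exponential(300.0, 60)
        surv = pd.DataFrame({"time": t, "event": np.ones(60, dtype=int)},
                            index=list(fit.ebes))
        with pytest.raises(CollinearityError):
            parameter_forest(fit, surv,
                             params=("L0", "PMAX", "SLP", "WT0", "Imax", "L0"))


class TestThresholdScan:
    def test_single_cutoff_equals_plain_cox(self):
        fit, rng = _random_truth_fit(200, 11)
        losses = {}
        from appwt.simulation import predicted_change_at
        for sid in fit.ebes:
            losses[sid] = predicted_change_at(fit, sid, 90.0)[0]
        t = rng.exponential(400.0, 200)
        surv = pd.DataFrame({"time": np.minimum(t, 1100.0) + 100.0,
                             "event": np.ones(200, dtype=int)},
                            index=list(fit.ebes))
        scan = threshold_scan(fit, surv, landmark=90.0, grid=np.array([5.0]))
        assert len(scan.table) == 1
        row = scan.table.iloc[0]
        direct = surv.copy()
        direct["group"] = [float(losses[s] >= 5.0) for s in surv.index]
        ref = cox_fit(direct, ["group"])
        assert row["hr"] == pytest.approx(ref.hr("group"), rel=1e-8)
        assert row["p"] == pytest.approx(ref.p("group"), rel=1e-8)

    def test_invariance_to_order_and_time_shift(self):
        fit, rng = _random_truth_fit(250, 21)
        loss_dependent = []
        from appwt.simulation import predicted_change_at
        for sid in fit.ebes:
            loss_dependent.append(predicted_change_at(fit, sid, 90.0)[0])
        lp = 0.08 * np.asarray(loss_dependent)
        t = 100.0 + rng.exponential(400.0 / np.exp(lp))
        surv = pd.DataFrame({"time": t, "event": np.ones(250, dtype=int)},
                            index=list(fit.ebes))
        base = threshold_scan(fit, surv, landmark=90.0)
        shuffled = surv.sample(frac=1.0, random_state=1)
        scan_shuffled = threshold_scan(fit, shuffled, landmark=90.0)
        shifted = surv.assign(time=surv["time"] + 500.0)
        scan_shifted = threshold_scan(fit, shifted, landmark=90.0)
        assert scan_shuffled.selected_cutoff == base.selected_cutoff
        assert scan_shifted.selected_cutoff == base.selected_cutoff

    def test_landmark_eligibility(self):
        fit, rng = _random_truth_fit(100, 31)
        t = rng.exponential(200.0, 100)
        surv = pd.DataFrame({"time": t, "event": np.ones(100, dtype=int)},
                            index=list(fit.ebes))
        scan = threshold_scan(fit, surv, landmark=90.0, grid=np.array([2.0]))
        eligible = (surv["time"] > 90.0).sum()
        row = scan.table.iloc[0]
        assert row["n_above"] + row["n_below"] == eligible


def test_survival_frame_columns(chemo_cohort_small):
    surv = survival_frame(chemo_cohort_small)
    assert {"time", "event", "female", "ecog", "smoking_current",
            "smoking_former", "age"} <= set(surv.columns)
    assert (surv["time"] > 0).all()
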