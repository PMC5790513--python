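
import numpy as np
import pandas as pd
import pytest

from sigforge import (CoxModel, censor_at, combine_signatures, cox_fit,
                      km_estimate, logrank_test)
from sigforge.exceptions import EstimationError, ValidationError


def records(times, events, **cov) -> pd.DataFrame:
    df = pd.DataFrame({"time_years": times, "event": events, **cov})
    df.index = [f"p{i}" for i in range(len(df))]
    return df


def brute_force_logrank(df: pd.DataFrame, groups: pd.Series) -> float:
    """Two-group log-rank chi-square tabulated by hand over event times."""
    o_minus_e, var = 0.0, 0.0
    g0 = groups.unique()[0]
    for t in sorted(df.loc[df["event"] == 1, "time_years"].unique()):
        at_risk = df["time_years"] >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d = ((df["time_years"] == t) & (df["event"] == 1)).sum()
        d0 = ((df["time_years"] == t) & (df["event"] == 1)
              & (groups == g0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_partial_loglik(beta: float, df: pd.DataFrame, x: np.ndarray) -> float:
    """Breslow partial log-likelihood for one binary covariate, no ties."""
    ll = 0.0
    for i in df.index[df["event"] == 1]:
        t = df.loc[i, "time_years"]
        risk = df["time_years"] >= t
        ll += beta * x[df.index.get_loc(i)] \
            - np.log(np.sum(np.exp(beta * x[risk.to_numpy()])))
    return ll


class TestCensorAt:
    @pytest.mark.parametrize("t,e,expect_t,expect_e", [
        (7.2, 1, 5.0, 0),
        (3.0, 1, 3.0, 1),
        (5.0, 1, 5.0, 1),   # event exactly at the horizon is kept
        (6.0, 0, 5.0, 0),
    ])
    def test_truncation(self, t, e, expect_t, expect_e):
        out = censor_at(records([t], [e]), horizon=5.0)
        assert out["time_years"].iloc[0] == expect_t
        assert out["event"].iloc[0] == expect_e

    def test_bad_horizon(self):
        with pytest.raises(ValidationError):
            censor_at(records([1.0], [1]), horizon=0.0)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # censored at 1, events at 2 and 3: S(2) = 1/2, S(3) = 0
        km = km_estimate(records([1.0, 2.0, 3.0], [0, 1, 1]))
        assert km.survival_at(2.0) == pytest.approx(0.5)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        km = km_estimate(records([1.0, 2.0, 3.0], [0, 0, 0]))
        assert km.survival_at(10.0) == 1.0

    def test_all_events_equals_empirical(self):
        km = km_estimate(records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]))
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert km.survival_at(t) == pytest.approx(s)

    def test_no_censoring_matches_ecdf_property(self, rng):
        times = rng.exponential(3.0, size=40).round(3)
        km = km_estimate(records(times, np.ones(40, dtype=int)))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert km.survival_at(t) == pytest.approx((times > t).mean())


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        df = records(t + t, e + e)
        chi2, dof, p = logrank_test(df, pd.Series(["a"] * 4 + ["b"] * 4,
                                                  index=df.index))
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)
        assert dof == 1

    def test_matches_bruteforce_tabulation(self):
        df = records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        groups = pd.Series(["a", "a", "b", "b"], index=df.index)
        chi2, _, _ = logrank_test(df, groups)
        assert chi2 == pytest.approx(brute_force_logrank(df, groups),
                                     rel=1e-10)

    def test_matches_bruteforce_with_censoring(self, rng):
        t = rng.exponential(2, size=30).round(2)
        e = (rng.random(30) < 0.7).astype(int)
        df = records(t, e)
        groups = pd.Series(rng.choice(["a", "b"], 30), index=df.index)
        chi2, _, _ = logrank_test(df, groups)
        assert chi2 == pytest.approx(brute_force_logrank(df, groups),
                                     rel=1e-8)

    def test_equals_squared_cox_score_no_ties(self, rng):
        # score test for the group indicator at beta = 0
        t = np.sort(rng.exponential(2, size=24))  # distinct times
        df = records(t, np.ones(24, dtype=int))
        x = rng.choice([0.0, 1.0], 24)
        groups = pd.Series(np.where(x > 0, "b", "a"), index=df.index)
        chi2, _, _ = logrank_test(df, groups)
        # closed-form score and information of the partial likelihood at 0:
        # U = sum_events (x_i - xbar_risk), I = sum_events var_risk(x)
        score, info = 0.0, 0.0
        t_arr = df["time_years"].to_numpy()
        for i in range(len(df)):
            risk = t_arr >= t_arr[i]
            xbar = x[risk].mean()
            score += x[i] - xbar
            info += (x[risk] ** 2).mean() - xbar**2
        assert chi2 == pytest.approx(score**2 / info, abs=1e-6)

    def test_single_group_rejected(self):
        df = records([1.0, 2.0], [1, 1])
        with pytest.raises(ValidationError):
            logrank_test(df, pd.Series(["a", "a"], index=df.index))


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        t = rng.exponential(2, size=200)
        e = (rng.random(200) < 0.8).astype(int)
        df = records(t, e, arm=rng.choice(["x", "y"], 200))
        res = CoxModel(df, ["arm"], reference_levels={"arm": "x"}).fit()
        row = res.frame.iloc[0]
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_matches_bruteforce_partial_likelihood(self):
        df = records([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        df["grp"] = np.where(x > 0, "high", "low")
        res = CoxModel(df, ["grp"], reference_levels={"grp": "low"}).fit()
        grid = np.linspace(-4, 4, 20001)
        lls = [cox_partial_loglik(b, df, x) for b in grid]
        beta_bf = grid[int(np.argmax(lls))]
        assert res.frame["beta"].iloc[0] == pytest.approx(beta_bf, abs=1e-3)
        # refine by golden-section-free quadratic step around the optimum
        from scipy.optimize import minimize_scalar
        opt = minimize_scalar(lambda b: -cox_partial_loglik(b, df, x),
                              bracket=(beta_bf - 0.1, beta_bf + 0.1))
        assert res.frame["beta"].iloc[0] == pytest.approx(opt.x, abs=1e-6)

    def test_recovers_planted_hazard_ratio(self):
        hrs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = (rng.random(250) < 0.25).astype(float)
            t = rng.exponential(1.0 / (0.1 * 2.5**x))
            cens = rng.uniform(2, 12, 250)
            time = np.minimum(t, cens)
            df = records(time, (t <= cens).astype(int),
                         grp=np.where(x > 0, "high", "low"))
            res = CoxModel(df, ["grp"], reference_levels={"grp": "low"}).fit()
            hrs.append(res.frame["hr"].iloc[0])
        assert 2.0 < np.mean(hrs) < 3.1

    def test_time_rescaling_invariance(self, rng):
        t = rng.exponential(2, size=100)
        e = (rng.random(100) < 0.7).astype(int)
        z = rng.normal(size=100)
        a = CoxModel(records(t, e, z=z), ["z"]).fit()
        b = CoxModel(records(t * 365.25, e, z=z), ["z"]).fit()
        assert a.frame["beta"].iloc[0] == pytest.approx(
            b.frame["beta"].iloc[0], abs=1e-8)

    def test_separation_flagged_non_estimable(self):
        # perfect separation: all events in one arm before any in the other
        df = records([1, 2, 3, 4, 10, 11, 12, 13],
                     [1, 1, 1, 1, 1, 1, 1, 1],
                     grp=["a"] * 4 + ["b"] * 4)
        res = CoxModel(df, ["grp"], reference_levels={"grp": "b"}).fit()
        assert not res.frame["estimable"].iloc[0] or \
            abs(res.frame["beta"].iloc[0]) > 2.0

    def test_collinear_covariates_rejected(self, rng):
        t = rng.exponential(2, size=50)
        z = rng.normal(size=50)
        df = records(t, np.ones(50, dtype=int), z=z, z2=2 * z)
        with pytest.raises(EstimationError, match="collinear"):
            CoxModel(df, ["z", "z2"]).fit()

    def test_missing_covariates_complete_case(self, rng):
        t = rng.exponential(2, size=60)
        z = rng.normal(size=60)
        z[:10] = np.nan
        res = CoxModel(records(t, np.ones(60, dtype=int), z=z), ["z"]).fit()
        assert res.n_excluded == 10
        assert res.n == 50

    def test_breslow_option_runs(self, rng):
        t = np.repeat(rng.exponential(2, size=20), 2)  # heavy ties
        e = np.ones(40, dtype=int)
        z = rng.normal(size=40)
        efron = cox_fit(records(t, e, z=z), ["z"], ties="efron")
        breslow = cox_fit(records(t, e, z=z), ["z"], ties="breslow")
        assert efron.frame["beta"].iloc[0] != breslow.frame["beta"].iloc[0]

    def test_categorical_reference_has_no_row(self, rng):
        t = rng.exponential(2, size=90)
        site = rng.choice(["limb", "trunk", "head"], 90)
        res = CoxModel(records(t, np.ones(90, dtype=int), site=site),
                       ["site"], reference_levels={"site": "limb"}).fit()
        assert len(res.frame) == 2
        assert all("vs limb" in name for name in res.frame.index)


class TestCombineSignatures:
    def _base(self, rng, n=200, hr_h=1.0, hr_s=1.0, independent=True):
        hyp = rng.random(n) < 0.4
        if independent:
            sec = rng.random(n) < 0.5
        else:
            sec = hyp
        lam = 0.15 * hr_h**hyp.astype(float) * hr_s**sec.astype(float)
        t = rng.exponential(1 / lam)
        cens = rng.uniform(3, 15, n)
        df = records(np.minimum(t, cens), (t <= cens).astype(int))
        h = pd.Series(np.where(hyp, "high", "low"), index=df.index)
        s = pd.Series(np.where(sec, "high", "low"), index=df.index)
        return df, h, s

    def test_identical_labels_leave_mixed_strata_empty(self, rng):
        df, h, _ = self._base(rng, independent=False)
        comb = combine_signatures(df, h, h)
        assert set(comb.strata.unique()) == {"LL", "HH"}
        assert not comb.cox.frame.loc["stratum[LH vs LL]", "estimable"]
        assert not comb.cox.frame.loc["stratum[HL vs LL]", "estimable"]
        assert comb.cox.frame.loc["stratum[HH vs LL]", "estimable"]

    def test_null_labels_hr_near_one(self, rng):
        df, h, s = self._base(rng, n=400)
        comb = combine_signatures(df, h, s)
        est = comb.cox.frame[comb.cox.frame["estimable"]]
        assert ((est["ci_low"] < 1.0) & (1.0 < est["ci_high"])).all()

    def test_multiplicative_hazards_compose(self):
        hrs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            df, h, s = self._base(rng, n=1500, hr_h=2.0, hr_s=2.0)
            comb = combine_signatures(df, h, s)
            hrs.append(comb.cox.frame.loc["stratum[HH vs LL]", "hr"])
        assert np.mean(hrs) == pytest.approx(4.0, rel=0.2)

    def test_missing_labels_rejected(self, rng):
        df, h, s = self._base(rng, n=50)
        h.iloc[0] = np.nan
        with pytest.raises(ValidationError):
            combine_signatures(df, h, s)


def test_plot_km_draws_one_curve_per_group(rng, tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from sigforge.survival import plot_km

    t = rng.exponential(2, size=60)
    e = (rng.random(60) < 0.7).astype(int)
    df = records(t, e)
    groups = pd.Series(rng.choice(["high", "low"], 60), index=df.index)
    ax = plot_km(df, groups, title="toy")
    assert len(ax.lines) >= 2
    ax.figure.savefig(tmp_path / "km.png")
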