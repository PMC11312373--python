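"""Cox fitting, trend tests, splines, subgroup and sensitivity runners."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inflascore import (
    ConfigError,
    DataError,
    FitError,
    ModelSpec,
    cox_fit,
    quartile_fit,
    rcs_basis,
    rcs_curve,
    sensitivity_run,
    subgroup_run,
    trend_test,
)
from inflascore.survival import prune_inestimable, rcs_knots

from conftest import simulate_exponential_survival


def partial_loglik(beta, time, event, x):
    """Breslow-free partial log-likelihood for untied times (oracle)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_two_group_exponential_rate_ratio(self, rng):
        """Closed-form oracle: exponential rates 2:1 give HR 2."""
        df = simulate_exponential_survival(rng, 10_000, [0.0, np.log(2.0)])
        df["g2"] = (df["group"] == "Q2").astype(int)
        fit = cox_fit(df, "time", "event", ["g2"])
        row = fit.iloc[0]
        assert abs(row["coef"] - np.log(2.0)) < 3 * row["log_hr_se"]

    def test_permuted_labels_cover_null(self, rng):
        df = simulate_exponential_survival(rng, 4000, [0.0, np.log(2.0)])
        df["g2"] = rng.permutation((df["group"] == "Q2").astype(int).to_numpy())
        row = cox_fit(df, "time", "event", ["g2"]).iloc[0]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_matches_grid_search_oracle_on_toy_data(self):
        """Eight untied observations: PL maximum by brute-force refinement."""
        time = np.arange(1.0, 9.0)
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([0.5, -1.2, 0.3, 1.0, -0.7, 0.2, 1.5, -0.3])
        b = np.linspace(-3, 3, 6001)
        best = b[np.argmax([partial_loglik(bi, time, event, x) for bi in b])]
        for _ in range(3):
            b = np.linspace(best - 0.01, best + 0.01, 2001)
            best = b[np.argmax([partial_loglik(bi, time, event, x) for bi in b])]
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = cox_fit(df, "time", "event", ["x"])
        assert fit.loc[0, "coef"] == pytest.approx(best, abs=1e-4)

    def test_zero_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(FitError):
            cox_fit(df, "time", "event", ["x"])

    def test_constant_covariate_rejected(self, rng):
        df = simulate_exponential_survival(rng, 200, [0.0, 0.5])
        df["c"] = 1.0
        with pytest.raises(FitError):
            cox_fit(df, "time", "event", ["c"])

    def test_affine_rescaling_leaves_other_hrs_unchanged(self, rng):
        n = 3000
        x1 = rng.normal(size=n)
        x2 = rng.normal(10, 3, size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.4 * x1 + 0.1 * x2)))
        df = pd.DataFrame(
            {
                "time": np.minimum(t, 15),
                "event": (t <= 15).astype(int),
                "x1": x1,
                "x2": x2,
            }
        )
        hr_a = cox_fit(df, "time", "event", ["x1", "x2"]).loc[0, "hr"]
        df["x2"] = df["x2"] * 7.3 - 4.0
        hr_b = cox_fit(df, "time", "event", ["x1", "x2"]).loc[0, "hr"]
        assert hr_a == pytest.approx(hr_b, abs=1e-8)

    def test_breslow_ties_available(self, rng):
        df = simulate_exponential_survival(rng, 500, [0.0, 0.7])
        df["time"] = np.ceil(df["time"])  # induce heavy ties
        df["g2"] = (df["group"] == "Q2").astype(int)
        efron = cox_fit(df, "time", "event", ["g2"], ties="efron")
        breslow = cox_fit(df, "time", "event", ["g2"], ties="breslow")
        # both estimate the same quantity, differing only via tie handling
        assert efron.loc[0, "coef"] == pytest.approx(breslow.loc[0, "coef"], abs=0.1)
        assert efron.loc[0, "coef"] != breslow.loc[0, "coef"]


class TestTrendTest:
    def test_monotone_hazards_detected(self, rng):
        df = simulate_exponential_survival(
            rng, 6000, [0.0, 0.2, 0.4, 0.6], base_rate=0.03
        )
        coef, p = trend_test(df, "time", "event", "group")
        assert coef > 0 and p < 1e-4

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(120):
            df = simulate_exponential_survival(rng, 300, [0.0, 0.0, 0.0, 0.0],
                                               base_rate=0.05)
            ps.append(trend_test(df, "time", "event", "group")[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_rejected(self, rng):
        df = simulate_exponential_survival(rng, 200, [0.0])
        with pytest.raises(FitError):
            trend_test(df, "time", "event", "group")


class TestQuartileFit:
    def test_reference_row_and_labels(self, rng):
        df = simulate_exponential_survival(rng, 5000, [0.0, 0.1, 0.3, 0.5])
        spec = ModelSpec(exposure="group", adjust=())
        est = quartile_fit(df.assign(time=df.time, event=df.event), spec)
        assert est["term"].tolist() == ["Q1", "Q2", "Q3", "Q4"]
        assert est.loc[0, "hr"] == 1.0
        assert "p_trend" in est.columns

    def test_recovers_generating_hrs(self, rng):
        truth = [0.0, np.log(1.3), np.log(1.7), np.log(2.2)]
        df = simulate_exponential_survival(rng, 20_000, truth, base_rate=0.03)
        spec = ModelSpec(exposure="group", adjust=())
        est = quartile_fit(df, spec).set_index("term")
        for q, b in zip(["Q2", "Q3", "Q4"], truth[1:]):
            z = abs(np.log(est.loc[q, "hr"]) - b) / est.loc[q, "log_hr_se"]
            assert z < 3


class TestRcs:
    def test_basis_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.linspace(4, 8, 50)
        b = rcs_basis(x, knots)
        # second differences of every column vanish outside the knot span
        for j in range(b.shape[1]):
            assert np.allclose(np.diff(b[:, j], 2), 0.0, atol=1e-9)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(DataError):
            rcs_knots(np.ones(100))

    def test_curve_is_one_at_reference(self, small_cohort):
        from inflascore import derive_outcomes

        out = derive_outcomes(small_cohort)
        df = pd.concat([small_cohort, out], axis=1)
        spec = ModelSpec(adjust=("age_baseline", "sex_male"))
        curve, p = rcs_curve(df, "infla_score", spec)
        ref = curve.attrs["ref_value"]
        # evaluate exactly at the reference point
        curve2, _ = rcs_curve(df, "infla_score", spec, grid=np.array([ref]))
        assert curve2["hr"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_linear_truth_keeps_nonlinear_terms_small(self):
        rng = np.random.default_rng(42)
        n = 6000
        x = rng.normal(0, 3, n)
        t = rng.exponential(1 / (0.03 * np.exp(0.15 * x)))
        df = pd.DataFrame(
            {"time": np.minimum(t, 15), "event": (t <= 15).astype(int), "score": x}
        )
        spec = ModelSpec(adjust=())
        spec2 = ModelSpec(outcome="premature_death", adjust=())
        curve, p = rcs_curve(df, "score", spec2)
        assert p > 0.001  # no spurious strong nonlinearity

    def test_j_shape_detected(self):
        rng = np.random.default_rng(21)
        n = 8000
        x = rng.normal(0, 3, n)
        lp = 0.06 * (x + 1.0) ** 2
        t = rng.exponential(1 / (0.02 * np.exp(lp)))
        df = pd.DataFrame(
            {"time": np.minimum(t, 15), "event": (t <= 15).astype(int), "score": x}
        )
        curve, p = rcs_curve(df, "score", ModelSpec(adjust=()))
        assert p < 0.001


class TestSubgroupAndSensitivity:
    def make_analysis(self, rng, n=6000):
        df = simulate_exponential_survival(rng, n, [0.0, 0.1, 0.25, 0.5],
                                           base_rate=0.03)
        df["age55"] = (rng.random(n) < 0.5).astype(int)
        for f in ("cvd", "cancer", "diabetes", "respiratory"):
            df[f] = (rng.random(n) < 0.2).astype(int)
        df["infla_score"] = df["group"].cat.codes * 4 + rng.normal(0, 1, n)
        return df

    def spec(self):
        return ModelSpec(exposure="group", adjust=())

    def test_single_stratum_reproduces_unstratified_fit(self, rng):
        df = self.make_analysis(rng)
        df["whole"] = 1
        sub = subgroup_run(df, self.spec(), "whole")
        est = quartile_fit(df, self.spec())
        np.testing.assert_allclose(
            sub.loc[sub["term"] == "Q4", "hr"], est.loc[est["term"] == "Q4", "hr"]
        )

    def test_partition_bookkeeping(self, rng):
        df = self.make_analysis(rng)
        sub = subgroup_run(df, self.spec(), "age55")
        totals = sub.groupby("stratum")["n_total"].first()
        assert totals.sum() == len(df)
        assert len(totals) == 2

    def test_empty_ish_stratum_marked_inestimable(self, rng):
        df = self.make_analysis(rng, n=800)
        # one stratum with almost no rows and no events
        df.loc[df.index[:-5], "rare"] = 0
        df.loc[df.index[-5:], "rare"] = 1
        df.loc[df.index[-5:], "event"] = 0
        sub = subgroup_run(df, self.spec(), "rare")
        bad = sub[sub["stratum"] == "rare=1.0"]
        assert (bad["term"] == "(inestimable)").any() or bad["hr"].isna().all()

    def test_sensitivity_short_followup_filter_counts(self, rng):
        df = self.make_analysis(rng)
        short = (df["time"] < 2.0).sum()
        est = sensitivity_run(df, 3, self.spec())
        assert est.attrs["n_total"] == len(df) - short

    def test_sensitivity_noop_when_no_short_followup(self, rng):
        df = self.make_analysis(rng)
        df["time"] = df["time"] + 2.0
        est = sensitivity_run(df, 3, self.spec())
        base = quartile_fit(df, self.spec())
        np.testing.assert_allclose(est["hr"], base["hr"])
        assert est.attrs["n_total"] == len(df)

    def test_sensitivity_prevalent_disease_noop_when_all_false(self, rng):
        df = self.make_analysis(rng)
        for f in ("cvd", "cancer", "diabetes", "respiratory"):
            df[f] = 0
        est = sensitivity_run(df, 1, self.spec())
        base = quartile_fit(df, self.spec())
        np.testing.assert_allclose(est["hr"], base["hr"])

    def test_sensitivity_quintile_rebinning(self, rng):
        df = self.make_analysis(rng)
        est = sensitivity_run(df, 2, self.spec())
        assert est["term"].tolist() == ["Q1", "Q2", "Q3", "Q4", "Q5"]

    def test_unknown_sensitivity_rejected(self, rng):
        with pytest.raises(ConfigError):
            sensitivity_run(self.make_analysis(rng, 500), 4, self.spec())


class TestPruning:
    def test_separated_flag_dropped(self, rng):
        df = simulate_exponential_survival(rng, 1000, [0.0, 0.5])
        df["flag"] = 0
        df.loc[df.index[:20], "flag"] = 1
        df.loc[df["flag"] == 1, "event"] = 0  # no events among flag=1
        kept = prune_inestimable(df, "event", ("flag",))
        assert kept == ()

    def test_healthy_flag_kept(self, rng):
        df = simulate_exponential_survival(rng, 1000, [0.0, 0.5])
        df["flag"] = (rng.random(1000) < 0.5).astype(int)
        assert prune_inestimable(df, "event", ("flag",)) == ("flag",)
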