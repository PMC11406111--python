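import numpy as np
import pandas as pd
import pytest

from silicarisk import survival as sv
from silicarisk.risk_quant import PredictionFormula
from conftest import make_records


class TestExposurePath:
    def test_constant_path_cumulative(self):
        p = sv.ExposurePath.constant(0.4)
        assert p.cumulative(10.0) == pytest.approx(4.0)

    def test_piecewise_cumulative(self):
        p = sv.ExposurePath((0.0, 10.0), (1.0, 0.5))
        assert p.cumulative(5.0) == pytest.approx(5.0)
        assert p.cumulative(20.0) == pytest.approx(10.0 + 5.0)
        assert p.rate_at(12.0) == 0.5

    def test_invalid_paths(self):
        with pytest.raises(ValueError):
            sv.ExposurePath((1.0,), (0.5,))
        with pytest.raises(ValueError):
            sv.ExposurePath((0.0, 5.0), (0.5, -0.1))


class TestKaplanMeier:
    def test_no_events_is_constant_one(self):
        with pytest.warns(UserWarning):
            km = sv.kaplan_meier(make_records([(3, 0, 1), (5, 0, 0)]))
        assert km.survival_at(4.0) == 1.0

    def test_hand_product_limit(self):
        # times {2, 2, 3+, 1+}: risk set 3 at t=2, two events -> S = 1/3
        km = sv.kaplan_meier(
            make_records([(2, 1, 1), (2, 1, 0), (3, 0, 1), (1, 0, 0)])
        )
        assert km.survival_at(2.0) == pytest.approx(1 / 3)

    def test_single_subject_event(self):
        km = sv.kaplan_meier(make_records([(5, 1, 1)]))
        assert km.survival_at(4.99) == 1.0
        assert km.survival_at(5.0) == 0.0

    def test_equals_empirical_survivor_without_censoring(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10.0, 80).round(1) + 0.1
        records = make_records([(t, 1, 1) for t in times])
        km = sv.kaplan_meier(records)
        grid = np.linspace(0.0, times.max() + 1, 200)
        empirical = [(times > t).mean() for t in grid]
        assert np.allclose(km.survival_at(grid), empirical)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        rows = [(1, 1, 1), (2, 0, 1), (3, 1, 1)]
        records = make_records(rows + rows)
        res = sv.logrank_test(records, ["A"] * 3 + ["B"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_hypergeometric_sum(self, toy_two_group):
        # O_A = 2, E_A = 3/6 + 2/5 + 2/4 = 1.4, V = 0.25 + 0.24 + 0.25
        records, groups = toy_two_group
        res = sv.logrank_test(records, groups)
        assert res.statistic == pytest.approx(0.36 / 0.74)
        assert res.df == 1
        assert 0 <= res.p_value <= 1

    def test_matches_lifelines(self, toy_two_group):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        records, groups = toy_two_group
        t = [r.exit_time for r in records]
        e = [r.event for r in records]
        ref = lifelines_stats.multivariate_logrank_test(t, groups, e)
        res = sv.logrank_test(records, groups)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_three_groups_df(self):
        records = make_records(
            [(1, 1, 1), (2, 1, 1), (3, 1, 0), (4, 0, 1), (5, 1, 0), (6, 0, 1)]
        )
        res = sv.logrank_test(records, ["A", "A", "B", "B", "C", "C"])
        assert res.df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sv.logrank_test(make_records([(1, 1, 1), (2, 1, 0)]), ["A", "A"])

    def test_invariance_under_relabeling_and_early_censoring(self, toy_two_group):
        records, groups = toy_two_group
        base = sv.logrank_test(records, groups).statistic
        relabeled = sv.logrank_test(records, ["g2" if g == "A" else "g1" for g in groups])
        assert relabeled.statistic == pytest.approx(base)
        extra = records + make_records([(0.5, 0, 1)])  # censored before 1st event
        res = sv.logrank_test(extra, groups + ["A"])
        assert res.statistic == pytest.approx(base)


def breslow_partial_loglik(beta, times, events, x):
    """Independent scalar-covariate Breslow partial log-likelihood."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))[:, None]
    ll = np.zeros(beta.shape[0])
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = risk & (times == t) & (events == 1)
        ll += x[dead].sum() * beta[:, 0] - dead.sum() * np.log(
            np.exp(beta * x[risk][None, :]).sum(axis=1)
        )
    return ll


FIVE_SUBJECTS = [(1, 1, 1), (2, 1, 0), (3, 0, 1), (4, 1, 1), (5, 0, 0)]


class TestCoxFit:
    def test_matches_grid_search_oracle(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = sv.cox_fit(make_records(FIVE_SUBJECTS))  # D constant 0 -> dropped
        assert fit.names == ("gender",)
        times = np.array([r[0] for r in FIVE_SUBJECTS], dtype=float)
        events = np.array([r[1] for r in FIVE_SUBJECTS])
        x = np.array([r[2] for r in FIVE_SUBJECTS], dtype=float)
        grid = np.arange(-3.0, 3.0, 1e-4)
        ll = breslow_partial_loglik(grid, times, events, x)
        assert fit.beta[0] == pytest.approx(grid[np.argmax(ll)], abs=1.5e-4)

    def test_score_vanishes_at_optimum(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = sv.cox_fit(make_records(FIVE_SUBJECTS))
        times = np.array([r[0] for r in FIVE_SUBJECTS], dtype=float)
        events = np.array([r[1] for r in FIVE_SUBJECTS])
        x = np.array([r[2] for r in FIVE_SUBJECTS], dtype=float)
        h = 1e-6
        score = (
            breslow_partial_loglik(fit.beta[0] + h, times, events, x)
            - breslow_partial_loglik(fit.beta[0] - h, times, events, x)
        ) / (2 * h)
        assert abs(score[0]) < 1e-6

    def test_matches_lifelines_time_fixed(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        n = 150
        gender = (rng.random(n) < 0.6).astype(int)
        rate = rng.lognormal(-1.0, 0.5, n)
        # untied times: with no ties the Breslow and Efron partial
        # likelihoods coincide, so lifelines (Efron) is an exact oracle
        t = rng.exponential(8.0 / (1 + gender + rate), n) + 0.01
        e = (rng.random(n) < 0.7).astype(int)
        records = [
            sv.SubjectRecord(f"s{i}", int(gender[i]), float(t[i]), int(e[i]),
                             sv.ExposurePath.constant(float(rate[i])))
            for i in range(n)
        ]
        fit = sv.cox_fit(records, time_varying=False)
        df = pd.DataFrame(
            {"t": t, "e": e, "gender": gender, "D": rate * t}
        )
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        ref = cph.params_[["gender", "D"]].to_numpy()
        assert np.allclose(fit.beta, ref, atol=1e-5)
        ref_se = cph.standard_errors_[["gender", "D"]].to_numpy()
        assert np.allclose(fit.se, ref_se, atol=1e-5)

    def test_requires_two_events(self):
        with pytest.raises(ValueError):
            sv.cox_fit(make_records([(1, 1, 1), (2, 0, 0)]))

    def test_perfect_separation_raises(self):
        # all male subjects fail early, all female survive: monotone likelihood
        rows = [(1, 1, 1), (2, 1, 1), (3, 1, 1), (10, 0, 0), (11, 0, 0), (12, 0, 0)]
        with pytest.raises(sv.ConvergenceError), pytest.warns(UserWarning):
            sv.cox_fit(make_records(rows))

    def test_censored_subject_outside_risk_sets_is_irrelevant(self):
        with pytest.warns(UserWarning, match="constant"):
            base = sv.cox_fit(make_records(FIVE_SUBJECTS))
        extra = make_records(FIVE_SUBJECTS + [(0.5, 0, 1)])
        with pytest.warns(UserWarning, match="constant"):
            fit = sv.cox_fit(extra)
        assert fit.beta[0] == pytest.approx(base.beta[0], abs=1e-10)


def oracle_breslow_baseline(beta, xbar, times, events, x):
    """Independent centered Breslow cumulative-hazard oracle (1 covariate)."""
    out = []
    total = 0.0
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = risk & (times == t) & (events == 1)
        total += dead.sum() / np.exp(beta * (x[risk] - xbar)).sum()
        out.append((t, total))
    return out


class TestBreslowBaseline:
    def test_null_model_reduces_to_nelson_aalen(self):
        records = make_records([(1, 1, 1), (2, 0, 0), (3, 0, 1), (4, 0, 0)])
        fit = sv.SurvFit(
            names=("gender",), beta=np.zeros(1), se=np.ones(1),
            cov=np.eye(1), loglik=0.0, loglik_null=0.0, n=4, n_events=1,
            covariate_means={"gender": 0.5, "D": 0.0}, converged=True,
            n_iter=0, time_varying=False,
        )
        h0 = sv.breslow_baseline(fit, records)
        assert h0(0.5) == 0.0
        assert h0(1.0) == pytest.approx(1 / 4)

    def test_matches_hand_breslow_sum(self):
        records = make_records(FIVE_SUBJECTS)
        with pytest.warns(UserWarning, match="constant"):
            fit = sv.cox_fit(records)
        h0 = sv.breslow_baseline(fit, records)
        times = np.array([r[0] for r in FIVE_SUBJECTS], dtype=float)
        events = np.array([r[1] for r in FIVE_SUBJECTS])
        x = np.array([r[2] for r in FIVE_SUBJECTS], dtype=float)
        oracle = oracle_breslow_baseline(
            fit.beta[0], fit.covariate_means["gender"], times, events, x
        )
        for t, val in oracle:
            assert h0(t) == pytest.approx(val, rel=1e-10)

    def test_zero_before_first_event_and_nondecreasing(self):
        records = make_records(FIVE_SUBJECTS)
        with pytest.warns(UserWarning, match="constant"):
            fit = sv.cox_fit(records)
        h0 = sv.breslow_baseline(fit, records)
        assert h0(0.0) == 0.0
        vals = h0(np.linspace(0, 6, 50))
        assert np.all(np.diff(vals) >= 0)


class TestPredictionFormulaConstruction:
    def test_from_fit_survival_matches_exp_neg_hazard(self):
        rng = np.random.default_rng(5)
        n = 300
        gender = (rng.random(n) < 0.5).astype(int)
        rate = rng.lognormal(-1.0, 0.4, n)
        t = rng.uniform(1.0, 40.0, n)
        e = (rng.random(n) < 0.5).astype(int)
        records = [
            sv.SubjectRecord(f"s{i}", int(gender[i]), float(t[i]), int(e[i]),
                             sv.ExposurePath.constant(float(rate[i])))
            for i in range(n)
        ]
        fit = sv.cox_fit(records)
        f = sv.build_prediction_formula(fit, records)
        for tau in (10, 20, 30):
            assert f.baseline_S[tau] == pytest.approx(np.exp(-f.baseline_H[tau]))
        assert isinstance(f, PredictionFormula)
        assert f.mean_gender == pytest.approx(gender.mean())

    def test_horizon_beyond_last_event_raises(self):
        records = make_records([(3, 1, 1), (4, 1, 0), (5, 0, 1), (6, 0, 0)])
        with pytest.warns(UserWarning, match="constant"):
            fit = sv.cox_fit(records)
        with pytest.raises(sv.ExtrapolationError):
            sv.build_prediction_formula(fit, records, horizons=[10])


class TestLifeTable:
    def test_published_table_consistent_with_247_cases(self, exposure_life_table):
        report = sv.life_table_check(exposure_life_table)
        assert report["consistent"]
        assert report["total_cases"] == 247

    def test_single_clean_row(self):
        df = pd.DataFrame({"L": [10], "W": [0], "D": [0]})
        assert sv.life_table_check(df)["consistent"]

    def test_increasing_participants_flagged(self):
        df = pd.DataFrame({"L": [10, 12], "W": [1, 1], "D": [1, 1]})
        report = sv.life_table_check(df)
        assert not report["consistent"]
        assert any("increases" in s for s in report["issues"])

    def test_overfull_bin_flagged(self):
        df = pd.DataFrame({"L": [10, 5], "W": [4, 1], "D": [7, 1]})
        assert not sv.life_table_check(df)["consistent"]
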