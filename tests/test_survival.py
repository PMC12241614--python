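"""Pathway scores, penalized and unpenalized Cox fits, KM/log-rank."""

import numpy as np
import pandas as pd
import pytest

from netage.survival_signature import (
    AgingSignatureModel,
    aging_signature,
    cox_fit,
    fit_lasso_cox,
    km_logrank,
    lasso_cox_solve,
    lasso_lambda_max,
    median_split,
    pathway_score,
    pathway_score_matrix,
    split_train_test,
)
from netage.synthetic_data import generate_pathway_survival_cohort


def survival_data(n=120, beta=1.0, seed=0, p=1):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    hazard = 0.01 * np.exp(x[:, 0] * beta)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / hazard.mean())
    time = np.minimum(t_event, t_cens) + rng.uniform(0, 1e-6, n)  # no ties
    event = (t_event <= t_cens).astype(float)
    return x, time, event


class TestPathwayScore:
    def test_single_gene_degenerates_to_centered_indegree(self, rng):
        scores = pd.DataFrame(
            rng.random((3, 6)), index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(6)],
        )
        vec, orient = pathway_score(scores, ["b"])
        assert np.allclose(vec, scores.loc["b"] - scores.loc["b"].mean())
        assert orient == 1

    def test_perfectly_correlated_pair_explains_all_variance(self, rng):
        base = rng.random(8)
        scores = pd.DataFrame(
            [base, 2.0 * base + 1.0], index=["a", "b"],
            columns=[f"s{i}" for i in range(8)],
        )
        vec, _ = pathway_score(scores, ["a", "b"])
        centered = base - base.mean()
        # PC1 carries the common pattern: |corr| == 1
        assert abs(np.corrcoef(vec, centered)[0, 1]) == pytest.approx(1.0)

    def test_matches_eigen_decomposition_oracle(self, rng):
        scores = pd.DataFrame(
            rng.random((4, 10)), index=list("abcd"),
            columns=[f"s{i}" for i in range(10)],
        )
        vec, _ = pathway_score(scores, list("abcd"))
        sub = scores.to_numpy().T
        sub = sub - sub.mean(axis=0)
        cov = np.cov(sub.T, bias=True)
        w, v = np.linalg.eigh(cov)
        proj = sub @ v[:, -1]
        assert abs(np.corrcoef(vec, proj)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_positive_against_mean_indegree(self, rng):
        scores = pd.DataFrame(
            rng.random((5, 12)) + np.linspace(0, 2, 12)[None, :],
            index=list("abcde"), columns=[f"s{i}" for i in range(12)],
        )
        vec, _ = pathway_score(scores, list("abcde"))
        mean_deg = scores.mean(axis=0)
        assert np.corrcoef(vec, mean_deg)[0, 1] > 0

    def test_matrix_rows_are_centered(self, rng):
        scores = pd.DataFrame(
            rng.random((6, 9)), index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(9)],
        )
        m = pathway_score_matrix(scores, {"P1": ["g0", "g1", "g2"], "P2": ["g3", "g4"]})
        assert m.shape == (2, 9)
        assert np.allclose(m.mean(axis=1), 0.0, atol=1e-10)


class TestLassoCox:
    def test_all_zero_at_and_above_lambda_max(self):
        x, time, event = survival_data(n=80, p=3, seed=1)
        xs = (x - x.mean(0)) / x.std(0)
        lam_max = lasso_lambda_max(xs, time, event)
        assert np.all(lasso_cox_solve(xs, time, event, lam_max) == 0.0)
        assert np.all(lasso_cox_solve(xs, time, event, lam_max * 1.5) == 0.0)
        # strictly below lambda_max something must enter
        assert np.any(lasso_cox_solve(xs, time, event, lam_max * 0.8) != 0.0)

    def test_unpenalized_single_predictor_matches_newton_oracle(self):
        x, time, event = survival_data(n=100, beta=0.8, seed=2)
        b_cd = lasso_cox_solve(x, time, event, 0.0)
        b_nr = cox_fit(x, time, event).coef
        assert b_cd[0] == pytest.approx(b_nr[0], abs=1e-6)

    def test_unpenalized_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        x, time, event = survival_data(n=90, beta=0.5, seed=3, p=2)
        df = pd.DataFrame({"x0": x[:, 0], "x1": x[:, 1], "t": time, "e": event})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        mine = cox_fit(x, time, event)
        assert mine.coef == pytest.approx(ll.params_.to_numpy(), abs=1e-5)
        assert mine.se == pytest.approx(ll.standard_errors_.to_numpy(), abs=1e-5)

    def test_cv_model_selects_planted_pathways(self):
        scores, cov, truth = generate_pathway_survival_cohort(
            n_samples=300, n_pathways=12, n_active=3, beta=0.9, seed=5
        )
        model = fit_lasso_cox(
            scores, cov["survival_time"].to_numpy(), cov["event"].to_numpy(),
            n_folds=5, seed=5,
        )
        assert set(truth["active_pathways"]) <= set(model.selected)
        assert model.chosen_lambda >= model.lambda_min
        assert model.chosen_lambda in model.lambda_path

    def test_signature_is_dot_product_and_ignores_extra_rows(self):
        model = AgingSignatureModel(
            candidates=["P1", "P2", "P3"],
            selected=["P1", "P2"],
            coefficients=pd.Series({"P1": 0.5, "P2": -1.0, "P3": 0.0}),
            lambda_path=np.array([1.0]),
            cv_mean=np.array([0.0]),
            cv_se=np.array([0.0]),
            chosen_lambda=1.0,
            lambda_min=1.0,
            n_folds=2,
            fold_seed=0,
            n_train=10,
            n_events=5,
        )
        x = pd.DataFrame(
            {"s1": [2.0, 1.0, 9.9], "s2": [0.0, 3.0, 9.9]},
            index=["P1", "P2", "P3"],
        )
        sig = aging_signature(model, x)
        assert sig["s1"] == pytest.approx(0.5 * 2.0 - 1.0 * 1.0)
        assert sig["s2"] == pytest.approx(-3.0)
        # removing the non-selected pathway changes nothing
        sig2 = aging_signature(model, x.drop(index="P3"))
        assert np.allclose(sig, sig2)
        with pytest.raises(KeyError, match="P1"):
            aging_signature(model, x.drop(index="P1"))

    def test_empty_model_gives_constant_signature(self):
        model = AgingSignatureModel(
            candidates=["P1"], selected=[],
            coefficients=pd.Series({"P1": 0.0}),
            lambda_path=np.array([1.0]), cv_mean=np.array([0.0]),
            cv_se=np.array([0.0]), chosen_lambda=1.0, lambda_min=1.0,
            n_folds=2, fold_seed=0, n_train=5, n_events=2,
        )
        x = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["P1"])
        assert (aging_signature(model, x) == 0.0).all()


class TestCoxFit:
    def test_null_covariate_within_three_se(self):
        rng = np.random.default_rng(7)
        n = 150
        x = rng.standard_normal((n, 1))
        time = rng.exponential(100.0, n)
        event = (rng.random(n) < 0.7).astype(float)
        res = cox_fit(x, time, event)
        assert abs(res.coef[0]) < 3 * res.se[0]

    def test_agrees_with_lasso_path_at_zero_penalty(self):
        x, time, event = survival_data(n=70, beta=0.6, seed=9, p=2)
        nr = cox_fit(x, time, event)
        cd = lasso_cox_solve(x, time, event, 0.0)
        assert np.allclose(nr.coef, cd, atol=1e-6)

    def test_scale_equivariance(self):
        x, time, event = survival_data(n=80, beta=0.7, seed=4)
        a = cox_fit(x, time, event)
        b = cox_fit(2.0 * x, time, event)
        assert b.coef[0] == pytest.approx(a.coef[0] / 2.0, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit(np.ones((5, 1)), np.arange(1.0, 6.0), np.zeros(5))


class TestKMLogrank:
    def test_no_events_gives_flat_curves_and_p_one(self):
        time = np.array([5.0, 6.0, 7.0, 8.0])
        event = np.zeros(4, int)
        curves, chi2, p = km_logrank(time, event, np.array([0, 0, 1, 1], bool))
        assert p == 1.0
        for c in curves.values():
            assert np.allclose(c.survival, 1.0)

    def test_hand_worked_product_limit_table(self):
        # group "low": times 2,4,6 all events; KM steps 2/3, 1/3, 0
        # group "high": times 3+, 5 (event), 7+
        time = np.array([2.0, 4.0, 6.0, 3.0, 5.0, 7.0])
        event = np.array([1, 1, 1, 0, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1], bool)
        curves, chi2, p = km_logrank(time, event, group)
        low = curves["low"]
        surv = dict(zip(low.times, low.survival))
        assert surv[2.0] == pytest.approx(2.0 / 3.0)
        assert surv[4.0] == pytest.approx(1.0 / 3.0)
        assert surv[6.0] == pytest.approx(0.0)
        high = curves["high"]
        sh = dict(zip(high.times, high.survival))
        assert sh[5.0] == pytest.approx(0.5)
        # hand-worked log-rank (observed vs expected, 1 df) over event
        # times 2, 4, 5, 6 with at-risk (low, high): (3,3), (2,2), (1,2), (1,1)
        # E_low = 1/2 + 1/2 + 1/3 + 1/2 = 11/6;  O_low = 3
        # V = 1/4 + 1/4 + 2/9 + 1/4 = 35/36
        # chi2 = (3 - 11/6)^2 / (35/36) = 1.4
        assert chi2 == pytest.approx((3 - 11.0 / 6.0) ** 2 / (35.0 / 36.0), rel=1e-6)

    def test_group_label_exchange_keeps_statistic(self):
        x, time, event = survival_data(n=60, beta=1.0, seed=6)
        group = x[:, 0] > 0
        _, chi2a, pa = km_logrank(time, event, group)
        _, chi2b, pb = km_logrank(time, event, ~group)
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_median_split_ties_go_low(self):
        v = np.array([1.0, 2.0, 2.0, 3.0])
        grp = median_split(v)  # median 2.0; ties -> low
        assert list(grp) == [False, False, False, True]


class TestSplit:
    def test_deterministic_and_disjoint(self):
        samples = [f"s{i}" for i in range(20)]
        a = split_train_test(samples, 0.5, seed=3)
        b = split_train_test(samples, 0.5, seed=3)
        assert a == b
        train, test = a
        assert len(train) == 10 and len(test) == 10
        assert not set(train) & set(test)
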