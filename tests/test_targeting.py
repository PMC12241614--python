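"""Targeting scores, differential-targeting models, moderation, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from netage.network_inference import SampleNetworkSet
from netage.targeting import (
    DifferentialTargetingModel,
    aging_trajectory,
    fit_linear_models,
    indegree,
    moderate_tstats,
    rank_sum_compare,
    select_age_genes,
)


def make_set(weights, samples=None):
    n, t, g = weights.shape
    return SampleNetworkSet(
        tfs=[f"T{i}" for i in range(t)],
        genes=[f"g{j}" for j in range(g)],
        samples=samples or [f"s{k}" for k in range(n)],
        weights=weights,
    )


class TestIndegree:
    def test_all_ones_gives_tf_count(self):
        nets = make_set(np.ones((2, 3, 4)))
        assert (indegree(nets).to_numpy() == 3).all()

    def test_matches_hand_summation(self):
        w = np.arange(12, dtype=float).reshape(2, 2, 3)
        deg = indegree(make_set(w))
        # sample 0: columns sums of [[0,1,2],[3,4,5]]
        assert list(deg.iloc[:, 0]) == [3.0, 5.0, 7.0]
        assert list(deg.iloc[:, 1]) == [15.0, 17.0, 19.0]

    def test_zero_tf_row_is_neutral(self, rng):
        w = rng.random((2, 3, 4))
        w2 = np.concatenate([w, np.zeros((2, 1, 4))], axis=1)
        nets2 = SampleNetworkSet(
            tfs=["T0", "T1", "T2", "Tz"],
            genes=[f"g{j}" for j in range(4)],
            samples=["s0", "s1"],
            weights=w2,
        )
        assert np.allclose(indegree(make_set(w)), indegree(nets2))

    def test_linearity_in_weights(self, rng):
        w1, w2 = rng.random((2, 3, 4)), rng.random((2, 3, 4))
        combo = indegree(make_set(2.0 * w1 + 3.0 * w2))
        assert np.allclose(
            combo, 2.0 * indegree(make_set(w1)) + 3.0 * indegree(make_set(w2))
        )


def toy_covariates(n, seed=0):
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": r.uniform(30, 70, n).round(1),
            "sex": r.choice(["female", "male"], n),
            "smoking": r.choice(["ever", "never"], n),
        },
        index=[f"s{k}" for k in range(n)],
    )


class TestFitLinearModels:
    def test_exact_linear_response(self):
        cov = toy_covariates(10)
        scores = pd.DataFrame(
            [2.0 * cov["age"].to_numpy()], index=["g0"], columns=cov.index
        )
        res = fit_linear_models(scores, cov, terms=["age"])
        assert res.slope[0] == pytest.approx(2.0)
        assert res.residual_variance[0] == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self, rng):
        cov = toy_covariates(8, seed=3)
        y = rng.random((5, 8))
        scores = pd.DataFrame(y, index=[f"g{i}" for i in range(5)], columns=cov.index)
        res = fit_linear_models(scores, cov, terms=["age", "smoking"])
        # independent (X'X)^-1 X'y oracle
        x = np.column_stack(
            [
                np.ones(8),
                cov["age"].to_numpy(),
                (cov["smoking"] == "never").to_numpy(float),
            ]
        )
        j = 1
        xtx_inv = np.linalg.inv(x.T @ x)
        for gi in range(5):
            beta = xtx_inv @ x.T @ y[gi]
            resid = y[gi] - x @ beta
            s2 = resid @ resid / (8 - 3)
            t = beta[j] / np.sqrt(s2 * xtx_inv[j, j])
            assert res.slope[gi] == pytest.approx(beta[j], rel=1e-10)
            assert res.t[gi] == pytest.approx(t, rel=1e-10)

    def test_sample_permutation_invariance(self, rng):
        cov = toy_covariates(12, seed=5)
        scores = pd.DataFrame(
            rng.random((4, 12)), index=list("abcd"), columns=cov.index
        )
        res1 = fit_linear_models(scores, cov, terms=["age", "sex"])
        perm = rng.permutation(12)
        scores_p = scores.iloc[:, perm]
        res2 = fit_linear_models(scores_p, cov.iloc[perm], terms=["age", "sex"])
        assert np.allclose(res1.t, res2.t)

    def test_missing_responses_use_complete_cases(self):
        cov = toy_covariates(10, seed=7)
        y = 1.5 * cov["age"].to_numpy()
        ym = y.copy()
        ym[:3] = np.nan
        scores = pd.DataFrame([y, ym], index=["full", "gap"], columns=cov.index)
        res = fit_linear_models(scores, cov, terms=["age"])
        assert res.slope[1] == pytest.approx(1.5)
        assert res.df_residual[1] == 10 - 3 - 2

    def test_rank_deficient_design_names_columns(self):
        cov = toy_covariates(8)
        cov["age2"] = cov["age"]
        scores = pd.DataFrame(
            np.random.rand(2, 8), index=["a", "b"], columns=cov.index
        )
        with pytest.raises(ValueError, match="aliased"):
            fit_linear_models(scores, cov, terms=["age", "age2"])

    def test_interaction_coefficient(self):
        cov = toy_covariates(40, seed=9)
        smoke = (cov["smoking"] == "ever").to_numpy(float)  # never = reference
        y = 2.0 + 0.3 * cov["age"].to_numpy() + 0.5 * cov["age"].to_numpy() * smoke
        scores = pd.DataFrame([y], index=["g"], columns=cov.index)
        res = fit_linear_models(
            scores,
            cov,
            terms=["age", "smoking"],
            interaction=("age", "smoking"),
            coefficient="age:smoking[ever]",
        )
        assert res.slope[0] == pytest.approx(0.5, rel=1e-6)


class TestDiseaseModel:
    def test_tumor_coefficient_with_covariate_adjustment(self):
        # disease-status contrast (tumor vs healthy reference) with age kept
        rng = np.random.default_rng(13)
        n = 60
        cov = pd.DataFrame(
            {
                "age": rng.uniform(40, 80, n).round(1),
                "disease": rng.choice(["healthy", "tumor"], n),
            },
            index=[f"s{k}" for k in range(n)],
        )
        tumor = (cov["disease"] == "tumor").to_numpy(float)
        y = 1.0 + 0.02 * cov["age"].to_numpy() + 3.0 * tumor
        scores = pd.DataFrame([y], index=["g"], columns=cov.index)
        res = fit_linear_models(
            scores, cov, terms=["age", "disease"],
            coefficient="disease[tumor]",
        )
        assert res.slope[0] == pytest.approx(3.0, rel=1e-8)


class TestModeration:
    def _result(self, s2, df=10.0, n=None):
        n = n or len(s2)
        from netage.targeting import DiffTargetingResult

        return DiffTargetingResult(
            genes=[f"g{i}" for i in range(n)],
            coefficient="age",
            slope=np.ones(n),
            t=1.0 / np.sqrt(np.asarray(s2)),
            p=np.full(n, 0.5),
            df_residual=np.full(n, df),
            residual_variance=np.asarray(s2, dtype=float),
            stdunscaled=np.ones(n),
        )

    def test_equal_variances_leave_t_unchanged(self):
        res = moderate_tstats(self._result([2.0] * 30))
        assert np.allclose(res.moderated_t, res.t, rtol=1e-6)

    def test_squeeze_formula_with_estimated_prior(self, rng):
        s2 = rng.chisquare(10, 20) / 10.0
        res = moderate_tstats(self._result(s2))
        d0, s0 = res.df_prior, res.var_prior
        if np.isfinite(d0):
            expected = (d0 * s0 + 10.0 * s2) / (d0 + 10.0)
        else:
            expected = np.full(20, s0)
        assert np.allclose(res.moderated_t, res.slope / np.sqrt(expected))

    def test_prior_estimate_recovers_scaled_f_moments(self, rng):
        # variances drawn from the hierarchical model itself: d0=8, s0^2=1.5
        d0_true, s0_true, d = 8.0, 1.5, 10.0
        g = 5000
        s2_true = s0_true * d0_true / rng.chisquare(d0_true, g)
        s2 = s2_true * rng.chisquare(d, g) / d
        res = moderate_tstats(self._result(s2, df=d, n=g))
        assert res.df_prior == pytest.approx(d0_true, rel=0.25)
        assert res.var_prior == pytest.approx(s0_true, rel=0.15)

    def test_requires_enough_genes(self):
        with pytest.raises(ValueError, match="10 genes"):
            moderate_tstats(self._result([1.0] * 5))


class TestSelectAgeGenes:
    def test_all_p_one_gives_empty_lists(self):
        from netage.targeting import DiffTargetingResult

        res = DiffTargetingResult(
            genes=["a", "b"],
            coefficient="age",
            slope=np.array([1.0, -1.0]),
            t=np.zeros(2),
            p=np.ones(2),
            df_residual=np.full(2, 5.0),
            residual_variance=np.ones(2),
            stdunscaled=np.ones(2),
        )
        assert select_age_genes(res) == ([], [])

    def test_partition_matches_manual_filter_and_strict_threshold(self):
        from netage.targeting import DiffTargetingResult

        res = DiffTargetingResult(
            genes=["a", "b", "c", "d"],
            coefficient="age",
            slope=np.array([2.0, -1.0, 0.5, -0.1]),
            t=np.zeros(4),
            p=np.array([0.01, 0.04, 0.05, 0.2]),  # 0.05 itself must NOT pass
            df_residual=np.full(4, 5.0),
            residual_variance=np.ones(4),
            stdunscaled=np.ones(4),
        )
        up, down = select_age_genes(res, 0.05)
        assert up == ["a"] and down == ["b"]


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        stat, p = rank_sum_compare([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_exact_enumeration_small_groups(self):
        # all three of a below all of b: one-sided p = 1/C(6,3)
        stat, p = rank_sum_compare([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1.0 / 20.0)

    def test_group_swap_symmetry(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 3.0, 8.0]
        _, p_less = rank_sum_compare(a, b, alternative="less")
        _, p_greater = rank_sum_compare(b, a, alternative="greater")
        assert p_less == pytest.approx(p_greater)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 60)
        _, p = rank_sum_compare(a, b, alternative="less")
        assert 0 < p < 0.01


class TestAgingTrajectory:
    def test_constant_scores_give_zero_slopes(self):
        cov = toy_covariates(40, seed=1)
        scores = pd.DataFrame(
            np.full((3, 40), 5.0), index=["a", "b", "c"], columns=cov.index
        )
        traj = aging_trajectory(scores, ["a", "b"], cov)
        assert (traj.bins["median"] == 5.0).all()
        assert np.allclose(traj.fits["slope"], 0.0)

    def test_bins_match_sorting_oracle(self):
        cov = toy_covariates(40, seed=2)
        cov["smoking"] = "ever"  # single subgroup
        vals = np.linspace(0, 1, 40)[None, :]
        scores = pd.DataFrame(vals, index=["g"], columns=cov.index)
        traj = aging_trajectory(scores, ["g"], cov)
        assert len(traj.bins) == 20
        assert (traj.bins["n"] == 2).all()
        order = np.argsort(cov["age"].to_numpy(), kind="stable")
        per_sample = scores.loc["g"].to_numpy()
        for b in range(20):
            members = order[2 * b : 2 * b + 2]
            row = traj.bins[traj.bins["bin"] == b].iloc[0]
            assert row["median"] == pytest.approx(np.median(per_sample[members]))

    def test_smoking_acceleration_steepens_ever_slope(self):
        # construct targeting scores with a planted steeper ever-smoker trend
        cov = toy_covariates(200, seed=3)
        age = cov["age"].to_numpy()
        ever = (cov["smoking"] == "ever").to_numpy()
        y = 0.1 * age + 0.15 * age * ever
        scores = pd.DataFrame([y, y], index=["a", "b"], columns=cov.index)
        traj = aging_trajectory(scores, ["a", "b"], cov)
        assert traj.subgroup_slope("ever") > traj.subgroup_slope("never")

    def test_gene_set_must_intersect(self):
        cov = toy_covariates(40)
        scores = pd.DataFrame(
            np.random.rand(2, 40), index=["a", "b"], columns=cov.index
        )
        with pytest.raises(ValueError, match="intersect"):
            aging_trajectory(scores, ["zzz"], cov)


class TestModelInterface:
    def test_fit_returns_moderated_results(self, rng):
        cov = toy_covariates(30, seed=4)
        scores = pd.DataFrame(
            rng.random((15, 30)),
            index=[f"g{i}" for i in range(15)],
            columns=cov.index,
        )
        res = DifferentialTargetingModel(scores, cov, terms=["age", "sex"]).fit()
        assert res.moderated_t is not None
        assert res.to_frame().shape[0] == 15
        res_plain = DifferentialTargetingModel(scores, cov, terms=["age", "sex"]).fit(
            moderated=False
        )
        assert res_plain.moderated_t is None
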