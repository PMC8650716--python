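"""Robust Huber regression, sandwich Wald and permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neuroqol import robust
from neuroqol.networks import DifferentialActivity


def simple_design(rng, n=28, slope=0.5):
    x = rng.standard_normal(n)
    nuis = rng.standard_normal((n, 2))
    y = slope * x + nuis @ [0.2, -0.1] + 1.0 + rng.standard_normal(n)
    return robust.RegressionDesign(response=y, predictor=x, nuisance=nuis)


class TestRobustFit:
    def test_exact_linear_data_interpolated(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0
        fit = robust.robust_fit(robust.RegressionDesign(response=y, predictor=x))
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients[-1] == pytest.approx(1.0, abs=1e-8)

    def test_large_threshold_limit_equals_ols(self):
        rng = np.random.default_rng(0)
        design = simple_design(rng)
        y, x, Z = design.matrices()
        fit = robust.robust_fit(design, c=1e9)
        ols = sm.OLS(y, np.column_stack([x, Z])).fit()
        assert np.abs(fit.coefficients - ols.params).max() < 1e-8

    def test_matches_statsmodels_rlm(self):
        rng = np.random.default_rng(1)
        design = simple_design(rng)
        y, x, Z = design.matrices()
        fit = robust.robust_fit(design)
        rlm = sm.RLM(y, np.column_stack([x, Z]), M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad", conv="coefs", tol=1e-10, maxiter=300
        )
        assert np.abs(fit.coefficients - rlm.params).max() < 1e-5

    def test_outlier_resistance_beats_ols(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 21)
        y = x.copy()
        y[-1] += 25.0  # one gross outlier
        fit = robust.robust_fit(robust.RegressionDesign(response=y, predictor=x))
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(fit.coefficients[0] - 1.0) < abs(ols.params[1] - 1.0)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(robust.DesignError):
            robust.RegressionDesign(
                response=np.ones(10), predictor=x, nuisance=np.column_stack([x, x])
            ).matrices()

    def test_constant_predictor_rejected(self):
        with pytest.raises(robust.DegenerateDesignError):
            robust.RegressionDesign(
                response=np.arange(10.0), predictor=np.ones(10)
            ).matrices()


class TestWaldStatistic:
    def test_scale_invariance_in_response_units(self):
        rng = np.random.default_rng(3)
        design = simple_design(rng)
        w1 = robust.wald_statistic(design)
        scaled = robust.RegressionDesign(
            response=np.asarray(design.response) * 2.0,
            predictor=design.predictor,
            nuisance=design.nuisance,
        )
        assert robust.wald_statistic(scaled) == pytest.approx(w1, rel=1e-8)

    def test_matches_hand_computed_sandwich_in_ols_limit(self):
        rng = np.random.default_rng(4)
        n = 15
        x = rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        design = robust.RegressionDesign(response=y, predictor=x)
        w = robust.wald_statistic(design, c=1e9)
        # independent closed-form HC0 oracle
        X = np.column_stack([x, np.ones(n)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ (X * (r**2)[:, None])
        V = bread @ meat @ bread
        assert w == pytest.approx(beta[0] ** 2 / V[0, 0], rel=1e-8)

    def test_zero_slope_gives_zero_wald(self):
        # symmetric response orthogonal to the predictor
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, -2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, 0.0, -1.0, 0.0, 1.0, 1.0, 0.0, -1.0, 0.0, 1.0])
        w = robust.wald_statistic(
            robust.RegressionDesign(response=y, predictor=x), c=1e9
        )
        assert w == pytest.approx(0.0, abs=1e-16)


class TestPermutationPvalue:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        n = 5
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        Z = np.ones((n, 1))
        p, w_obs, _ = robust.permutation_wald_pvalue(y, x, Z, exhaustive=True)
        # brute-force oracle: refit every arrangement one at a time
        walds = []
        for perm in itertools.permutations(range(n)):
            _, w_arr, _, _ = robust._fit_and_wald(x[np.array(perm)][None], Z, y)
            walds.append(w_arr[0])
        oracle = np.mean(np.asarray(walds) >= w_obs)
        assert p == pytest.approx(oracle, abs=0)
        assert p >= 1 / 120

    def test_add_one_lower_bound_and_determinism(self):
        rng = np.random.default_rng(6)
        design = simple_design(rng, slope=3.0)
        res1 = robust.permutation_pvalue(design, n_perm=99, seed=11)
        res2 = robust.permutation_pvalue(design, n_perm=99, seed=11)
        assert res1.p_permutation == res2.p_permutation
        assert res1.p_permutation >= 1 / 100

    def test_t_equivalent_sign_follows_slope(self):
        rng = np.random.default_rng(7)
        design = simple_design(rng, slope=-2.0)
        res = robust.permutation_pvalue(design, n_perm=99, seed=0)
        assert res.t_equivalent < 0
        assert res.t_equivalent**2 == pytest.approx(res.wald_statistic)

    def test_size_calibrated_under_null(self):
        # exchangeable null: predictor independent of response
        rng = np.random.default_rng(8)
        n, n_sim, alpha = 28, 300, 0.05
        rejections = 0
        for _ in range(n_sim):
            x = rng.standard_normal(n)
            nuis = rng.standard_normal(n)
            y = 0.3 * nuis + rng.standard_normal(n)
            p, _, _ = robust.permutation_wald_pvalue(
                y, x, np.column_stack([nuis, np.ones(n)]), n_perm=199, seed=rng
            )
            rejections += p < alpha
        rate = rejections / n_sim
        half = 2.576 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert alpha - half <= rate <= alpha + half


class TestBonferroni:
    def test_reported_thresholds(self):
        assert robust.bonferroni_threshold_display(0.05, 28) == 0.0018
        assert robust.bonferroni_threshold_display(0.1, 28) == 0.0036

    def test_single_test_identity(self):
        assert robust.bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            robust.bonferroni_threshold(1.5, 28)
        with pytest.raises(ValueError):
            robust.bonferroni_threshold(0.05, 0)

    def test_fwe_adjust_caps_at_one(self):
        assert robust.fwe_adjust(0.2, 28) == 1.0
        assert robust.fwe_adjust(0.001, 28) == pytest.approx(0.028)


def _marker_table(rng, n=28, ms_effect=0.0):
    ms = np.array(["RRMS"] * n, dtype=object)
    ms[rng.choice(n, 5, replace=False)] = "SPMS"
    tab = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(27, 61, n),
            "education": rng.integers(0, 2, n),
            "edss": rng.uniform(1, 6, n),
            "relapse_rate": rng.exponential(0.4, n),
            "t2_lesion_load": rng.lognormal(1.5, 0.8, n),
            "ms_type": ms,
            "disease_duration": rng.uniform(271, 12250, n),
            "gm_fraction": rng.normal(0.45, 0.03, n),
            "total_T0": rng.normal(2.5, 0.5, n),
            "followup_days": rng.integers(363, 1170, n).astype(float),
        }
    )
    tab["delta_total"] = (
        ms_effect * (tab["ms_type"] == "SPMS").astype(float)
        + 0.05 * rng.standard_normal(n)
    )
    return tab


class TestScreenMarkers:
    def test_planted_ms_type_effect_is_flagged(self):
        hits, others = 0, 0
        n_rep = 10
        for s in range(n_rep):
            tab = _marker_table(np.random.default_rng(100 + s), ms_effect=1.0)
            res = robust.screen_markers(tab, n_perm=199, seed=s)
            row = res.set_index("marker")
            hits += bool(row.loc["ms_type", "significant"])
            others += int(
                row.drop(index="ms_type")["significant"].sum()
            )
        assert hits >= 9  # high-SNR effect recovered essentially always
        assert others <= n_rep * 8 * 0.25  # spurious flags stay near alpha

    def test_constant_marker_column_is_degenerate(self):
        tab = _marker_table(np.random.default_rng(0))
        tab["edss"] = 3.0
        with pytest.raises(robust.DegenerateDesignError):
            robust.screen_markers(tab, n_perm=49, seed=0)

    def test_missing_marker_column_is_schema_error(self):
        tab = _marker_table(np.random.default_rng(0)).drop(columns=["gm_fraction"])
        with pytest.raises(robust.DesignError):
            robust.screen_markers(tab, n_perm=49, seed=0)


class TestPredictHrqlFromNetworks:
    def _toy_inputs(self, rng, n=20, m=4, effect=0.0):
        ids = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
        cols = [f"network_{k + 1}" for k in range(m)]
        exposure = pd.DataFrame(rng.standard_normal((n, m)), index=ids, columns=cols)
        cessation = pd.DataFrame(rng.standard_normal((n, m)), index=ids, columns=cols)
        outcomes = pd.DataFrame(
            {
                "total_T0": rng.normal(2.5, 0.4, n),
                "followup_days": rng.integers(363, 1170, n).astype(float),
                "task_load": rng.standard_normal(n),
                "ms_type": rng.choice(["RRMS", "SPMS"], n),
            },
            index=ids,
        )
        outcomes["delta_total"] = (
            effect * cessation["network_2"] + 0.05 * rng.standard_normal(n)
        )
        return DifferentialActivity(exposure=exposure, cessation=cessation), outcomes

    def test_planted_cessation_network_flagged(self):
        rng = np.random.default_rng(9)
        diffs, outcomes = self._toy_inputs(rng, effect=1.0)
        res = robust.predict_hrql_from_networks(
            diffs, outcomes, scales=("total",), n_perm=999, seed=3
        )
        hit = res[(res.process == "cessation") & (res.network == "network_2")]
        assert bool(hit["significant"].iloc[0])

    def test_family_results_match_single_design_path(self):
        rng = np.random.default_rng(10)
        diffs, outcomes = self._toy_inputs(rng, effect=0.3)
        res = robust.predict_hrql_from_networks(
            diffs, outcomes, scales=("total",), n_perm=99, seed=5
        )
        # recompute one cell through the one-design-at-a-time public path
        ss = np.random.SeedSequence(5)
        children = ss.spawn(4)  # exposure family children, network order
        cell = res[(res.process == "exposure") & (res.network == "network_3")].iloc[0]
        design = robust.RegressionDesign(
            response=outcomes["delta_total"],
            predictor=diffs.exposure["network_3"],
            nuisance=pd.DataFrame(
                {
                    "t0_score": outcomes["total_T0"],
                    "followup_days": outcomes["followup_days"],
                    "task_load": outcomes["task_load"],
                    "ms_type": robust._encode(outcomes["ms_type"]),
                }
            ),
        )
        single = robust.permutation_pvalue(
            design, n_perm=99, seed=np.random.default_rng(children[2])
        )
        assert cell["p_perm"] == pytest.approx(single.p_permutation, abs=0)
        assert cell["estimate"] == pytest.approx(single.estimate, rel=1e-10)

    def test_zero_variance_network_reported_untestable(self):
        rng = np.random.default_rng(11)
        diffs, outcomes = self._toy_inputs(rng)
        diffs.exposure["network_1"] = 1.0
        res = robust.predict_hrql_from_networks(
            diffs, outcomes, scales=("total",), n_perm=49, seed=0
        )
        flat = res[(res.process == "exposure") & (res.network == "network_1")].iloc[0]
        other = res[(res.process == "exposure") & (res.network == "network_2")].iloc[0]
        assert not flat["testable"] and not flat["significant"]
        assert other["testable"] and np.isfinite(other["p_perm"])

    def test_missing_cessation_rows_dropped_listwise(self):
        rng = np.random.default_rng(12)
        diffs, outcomes = self._toy_inputs(rng)
        diffs.cessation.iloc[0, :] = np.nan
        res = robust.predict_hrql_from_networks(
            diffs, outcomes, scales=("total",), n_perm=49, seed=0
        )
        assert (res[res.process == "cessation"]["n"] == 19).all()
        assert (res[res.process == "exposure"]["n"] == 20).all()

    def test_p_fwe_is_bonferroni_adjusted(self):
        rng = np.random.default_rng(13)
        diffs, outcomes = self._toy_inputs(rng)
        res = robust.predict_hrql_from_networks(
            diffs, outcomes, scales=("total",), n_perm=99, seed=1
        )
        ok = res[res.testable]
        assert np.allclose(
            ok["p_fwe"], np.minimum(1.0, ok["p_perm"] * ok["m"]), atol=1e-12
        )


class TestFreedmanLaneScheme:
    def test_detects_strong_signal_like_default_scheme(self):
        rng = np.random.default_rng(14)
        design = simple_design(rng, slope=3.0)
        y, x, Z = design.matrices()
        p_int, _, _ = robust.permutation_wald_pvalue(y, x, Z, n_perm=199, seed=1)
        p_fl, _, _ = robust.permutation_wald_pvalue(
            y, x, Z, n_perm=199, seed=1, scheme="freedman_lane"
        )
        assert p_int <= 0.01 and p_fl <= 0.01

    def test_size_under_null(self):
        rng = np.random.default_rng(15)
        n, n_sim, alpha = 28, 200, 0.05
        rejections = 0
        for _ in range(n_sim):
            x = rng.standard_normal(n)
            nuis = rng.standard_normal(n)
            y = 0.3 * nuis + rng.standard_normal(n)
            p, _, _ = robust.permutation_wald_pvalue(
                y, x, np.column_stack([nuis, np.ones(n)]), n_perm=99, seed=rng,
                scheme="freedman_lane",
            )
            rejections += p < alpha
        rate = rejections / n_sim
        half = 2.576 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert alpha - half <= rate <= alpha + half

    def test_unknown_scheme_rejected(self):
        rng = np.random.default_rng(16)
        design = simple_design(rng)
        y, x, Z = design.matrices()
        with pytest.raises(ValueError):
            robust.permutation_wald_pvalue(y, x, Z, n_perm=9, seed=0, scheme="rotation")
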