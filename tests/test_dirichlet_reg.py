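import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microlda import synthetic
from microlda.dirichlet_reg import (
    DirichletRegSpec,
    adjust_p,
    bonferroni_threshold,
    build_design,
    dirichlet_loglik,
    fit_dirichlet_regression,
    run_association_battery,
    squeeze_composition,
)
from microlda.io_preprocess import CovariateTable

import pandas as pd


class TestDirichletLoglik:
    def test_uniform_density_is_zero(self):
        y = np.array([[0.3, 0.7], [0.6, 0.4], [0.5, 0.5]])
        a = np.ones_like(y)
        assert dirichlet_loglik(y, a) == pytest.approx(0.0)

    def test_hand_evaluated_single_observation(self):
        # y = (1/2, 1/2), a = (2, 2): lgamma(4) - 2 lgamma(2) + log(1/4)
        # = log 6 - log 4 = log(3/2)
        val = dirichlet_loglik(np.array([0.5, 0.5]), np.array([2.0, 2.0]))
        assert val == pytest.approx(np.log(1.5))

    def test_additive_over_observations(self):
        rng = np.random.default_rng(3)
        y = rng.dirichlet([2, 3, 4], size=6)
        a = rng.uniform(0.5, 3, size=(6, 3))
        total = dirichlet_loglik(y, a)
        parts = sum(dirichlet_loglik(y[i], a[i]) for i in range(6))
        assert total == pytest.approx(parts)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="squeeze"):
            dirichlet_loglik(np.array([1.0, 0.0]), np.array([2.0, 2.0]))


class TestSqueeze:
    def test_boundary_row_formula(self):
        y = np.vstack([np.array([1.0, 0.0])] + [np.full(2, 0.5)] * 8)  # n = 9
        out = squeeze_composition(y)
        np.testing.assert_allclose(out[0], [17 / 18, 1 / 18])

    @given(st.integers(2, 6), st.integers(5, 60))
    def test_rows_preserved_and_interior(self, K, n):
        rng = np.random.default_rng(K * 100 + n)
        y = rng.dirichlet(np.full(K, 0.1), size=n)
        out = squeeze_composition(y)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out > 0).all() and (out < 1).all()
        assert np.abs(out - y).max() <= 1.0 / n + 1e-12


class TestBonferroni:
    def test_identity_at_m1(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert adjust_p(0.03, 1) == 0.03

    def test_capping(self):
        assert adjust_p(0.1, 20) == 1.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            adjust_p(1.2, 10)


@pytest.fixture(scope="module")
def planted_fit_data():
    gamma = np.array([[0.5, 0.0, 0.0]])
    cov, theta, truth = synthetic.generate_covariate_linked_thetas(
        n_samples=500, K=3, gamma=gamma, precision=10.0, seed=101
    )
    return cov, theta, truth


class TestFitDirichletRegression:
    def test_intercept_only_matches_mean_composition(self):
        cov, theta, _ = synthetic.generate_covariate_linked_thetas(
            n_samples=500, K=4, gamma=np.zeros((1, 4)), precision=8.0, seed=7
        )
        # exposure present but we check the fitted mean composition
        spec = DirichletRegSpec(outcome=theta, exposure="exposure")
        fit = fit_dirichlet_regression(spec, cov)
        intercepts = fit.table[fit.table["term"] == "Intercept"]["beta"].to_numpy()
        a = np.exp(intercepts)
        fitted_mean = a / a.sum()
        np.testing.assert_allclose(fitted_mean, theta.mean(axis=0), atol=0.02)

    def test_planted_coefficient_recovered(self, planted_fit_data):
        cov, theta, truth = planted_fit_data
        spec = DirichletRegSpec(outcome=theta, exposure="exposure")
        fit = fit_dirichlet_regression(spec, cov)
        est = fit.exposure_table()
        b1 = float(est.loc[est["subgroup"] == "subgroup_1", "beta"].iloc[0])
        p1 = float(est.loc[est["subgroup"] == "subgroup_1", "p"].iloc[0])
        assert abs(b1 - 0.5) < 0.15
        assert p1 < 0.05
        assert fit.converged

    def test_zero_variance_predictor(self, planted_fit_data):
        cov, theta, _ = planted_fit_data
        df = cov.data.copy()
        df["constant"] = 1.0
        cov2 = CovariateTable(df, {**cov.kinds, "constant": {"kind": "continuous"}})
        with pytest.raises(ValueError, match="zero-variance"):
            fit_dirichlet_regression(
                DirichletRegSpec(outcome=theta, exposure="constant"), cov2
            )

    def test_per_sd_scaling_equivariance(self, planted_fit_data):
        cov, theta, _ = planted_fit_data
        df = cov.data.copy()
        df["exposure"] = df["exposure"] * 7.3
        cov_scaled = CovariateTable(df, cov.kinds)
        spec = DirichletRegSpec(outcome=theta, exposure="exposure")
        f1 = fit_dirichlet_regression(spec, cov)
        f2 = fit_dirichlet_regression(spec, cov_scaled)
        np.testing.assert_allclose(
            f1.exposure_table()["beta"], f2.exposure_table()["beta"], atol=1e-5
        )
        np.testing.assert_allclose(
            f1.exposure_table()["p"], f2.exposure_table()["p"], atol=1e-5
        )

    def test_missing_rows_dropped_and_counted(self, planted_fit_data):
        cov, theta, _ = planted_fit_data
        df = cov.data.copy()
        df.iloc[:5, df.columns.get_loc("exposure")] = np.nan
        cov_miss = CovariateTable(df, cov.kinds)
        spec = DirichletRegSpec(outcome=theta, exposure="exposure")
        fit = fit_dirichlet_regression(spec, cov_miss)
        assert fit.n_dropped == 5 and fit.n_used == 495

    def test_boundary_composition_autosqueezed(self):
        rng = np.random.default_rng(5)
        theta = rng.dirichlet([2, 2, 2], size=120)
        theta[0] = [1.0, 0.0, 0.0]
        theta = theta / theta.sum(axis=1, keepdims=True)
        df = pd.DataFrame(
            {"exposure": rng.standard_normal(120)},
            index=[f"S{i:04d}" for i in range(120)],
        )
        cov = CovariateTable(df, {"exposure": {"kind": "continuous"}})
        fit = fit_dirichlet_regression(DirichletRegSpec(outcome=theta, exposure="exposure"), cov)
        assert np.isfinite(fit.loglik)

    def test_categorical_exposure_dummy_terms(self):
        rng = np.random.default_rng(11)
        n = 300
        theta = rng.dirichlet([3, 3, 3], size=n)
        df = pd.DataFrame(
            {"status": rng.choice(["normal", "pre", "disease"], size=n)},
            index=[f"S{i:04d}" for i in range(n)],
        )
        cov = CovariateTable(
            df, {"status": {"kind": "categorical", "reference": "normal"}}
        )
        fit = fit_dirichlet_regression(DirichletRegSpec(outcome=theta, exposure="status"), cov)
        assert sorted(fit.exposure_terms) == ["status[disease]", "status[pre]"]
        assert len(fit.exposure_table()) == 2 * 3


class TestBattery:
    def test_single_exposure_equals_single_fit(self, planted_fit_data):
        cov, theta, _ = planted_fit_data
        battery = run_association_battery(theta, cov, exposures=["exposure"])
        single = fit_dirichlet_regression(
            DirichletRegSpec(outcome=theta, exposure="exposure"), cov
        ).exposure_table()
        np.testing.assert_allclose(battery["beta"], single["beta"], atol=1e-9)
        assert (battery["p_adj"] >= battery["p"].fillna(1)).all()

    def test_m_tests_counts_exposures(self):
        rng = np.random.default_rng(23)
        n = 200
        theta = rng.dirichlet([3, 3], size=n)
        df = pd.DataFrame(
            {f"x{j}": rng.standard_normal(n) for j in range(3)},
            index=[f"S{i:04d}" for i in range(n)],
        )
        cov = CovariateTable(df, {f"x{j}": {"kind": "continuous"} for j in range(3)})
        battery = run_association_battery(theta, cov, exposures=["x0", "x1", "x2"])
        # adjusted p is min(1, 3p)
        mask = battery["p"].notna() & (battery["p"] * 3 < 1)
        np.testing.assert_allclose(
            battery.loc[mask, "p_adj"], battery.loc[mask, "p"] * 3, rtol=1e-9
        )

    def test_planted_association_flagged(self, planted_fit_data):
        cov, theta, _ = planted_fit_data
        df = cov.data.copy()
        rng = np.random.default_rng(77)
        df["noise1"] = rng.standard_normal(len(df))
        df["noise2"] = rng.standard_normal(len(df))
        cov3 = CovariateTable(
            df, {**cov.kinds, "noise1": {"kind": "continuous"}, "noise2": {"kind": "continuous"}}
        )
        battery = run_association_battery(
            theta, cov3, exposures=["exposure", "noise1", "noise2"]
        )
        hits = battery[battery["significant"]]
        assert ("exposure", "subgroup_1") in set(zip(hits["exposure"], hits["subgroup"]))
        assert not any(hits["exposure"].isin(["noise1", "noise2"]))

    def test_exclusion_rule_reduces_n(self, planted_fit_data):
        cov, theta, _ = planted_fit_data
        df = cov.data.copy()
        df["not_fasted"] = False
        df.iloc[:10, df.columns.get_loc("not_fasted")] = True
        cov2 = CovariateTable(df, cov.kinds)
        battery = run_association_battery(
            theta, cov2, exposures=["exposure"], exclude_if={"exposure": "not_fasted"}
        )
        assert (battery["n"] == len(df) - 10).all()

    def test_missing_exposure_named(self, planted_fit_data):
        cov, theta, _ = planted_fit_data
        with pytest.raises(KeyError, match="absent_item"):
            run_association_battery(theta, cov, exposures=["absent_item"])


class TestBuildDesign:
    def test_continuous_scaled_by_sd(self, planted_fit_data):
        cov, _, _ = planted_fit_data
        design, term_map = build_design(cov, ["exposure"], standardize=True)
        assert design["exposure"].std(ddof=1) == pytest.approx(1.0)
        assert term_map == {"exposure": ["exposure"]}
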