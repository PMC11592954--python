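"""Model fitting, design construction, and nested F comparisons."""

import numpy as np
import pandas as pd
import pytest

import evlm
from evlm.linmod import DegenerateFitError, RankDeficientError

from conftest import random_nested_instance


class TestBuildDesign:
    def test_citrus_full_model_is_24_by_12(self, citrus, citrus_design):
        assert citrus_design.matrix.shape == (24, 12)
        # intercept + 2 tree + 3 pest + 6 interaction columns
        assert sum(":" in c for c in citrus_design.column_names) == 6
        assert citrus_design.column_names[0] == "Intercept"
        assert np.all(citrus_design.matrix[:, 0] == 1.0)

    def test_intercept_only_design(self, citrus):
        d = evlm.build_design(citrus, ["1"])
        assert d.matrix.shape == (24, 1)
        assert np.all(d.matrix == 1.0)

    def test_two_by_two_single_replicate_full_model_invertible(self):
        # brute-force oracle: the 4x4 full-interaction matrix has nonzero det
        preds = pd.DataFrame({"a": ["1", "1", "2", "2"], "b": ["1", "2", "1", "2"]})
        data = evlm.ModelData(y=np.arange(4.0), predictors=preds,
                              factors=frozenset({"a", "b"}))
        d = evlm.build_design(data, ["1", "a", "b", "a:b"])
        assert d.matrix.shape == (4, 4)
        assert abs(np.linalg.det(d.matrix)) > 1e-8

    def test_unknown_term_raises_naming_error(self, citrus):
        with pytest.raises(ValueError, match="nosuch"):
            evlm.build_design(citrus, ["1", "nosuch"])

    def test_interaction_requires_declared_main_effects(self, citrus):
        with pytest.raises(ValueError, match="main effect"):
            evlm.build_design(citrus, ["1", "tree:pest"])

    def test_aliased_columns_are_named_in_rank_error(self):
        rng = np.random.default_rng(0)
        preds = pd.DataFrame({"x": rng.standard_normal(10)})
        preds["z"] = 2.0 * preds["x"]  # exact alias
        data = evlm.ModelData(y=rng.standard_normal(10), predictors=preds)
        with pytest.raises(RankDeficientError, match="z"):
            evlm.build_design(data, ["1", "x", "z"])


class TestFit:
    def test_constant_response_intercept_only(self):
        preds = pd.DataFrame({"x": np.arange(6.0)})
        data = evlm.ModelData(y=np.full(6, 3.5), predictors=preds)
        f = evlm.fit(data, evlm.build_design(data, ["1"]))
        assert f.beta_hat == pytest.approx([3.5])
        assert f.sigma2_ml == 0.0
        assert f.loglik_max == np.inf

    def test_matches_statsmodels_ols(self):
        # independent least-squares oracle
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(10), rng.standard_normal((10, 2))])
        y = rng.standard_normal(10)
        preds = pd.DataFrame(X[:, 1:], columns=["x1", "x2"])
        data = evlm.ModelData(y=y, predictors=preds)
        f = evlm.fit(data, evlm.build_design(data, ["1", "x1", "x2"]))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(f.beta_hat, ols.params, atol=1e-10)
        np.testing.assert_allclose(f.sigma2_ml, ols.ssr / 10, atol=1e-12)
        np.testing.assert_allclose(f.loglik_max, ols.llf, atol=1e-8)

    def test_unbiased_variance_identity_and_saturated_error(self):
        rng = np.random.default_rng(1)
        preds = pd.DataFrame({"x": rng.standard_normal(8)})
        data = evlm.ModelData(y=rng.standard_normal(8), predictors=preds)
        f = evlm.fit(data, evlm.build_design(data, ["1", "x"]))
        assert f.sigma2_unbiased == pytest.approx(8 * f.sigma2_ml / 6)
        # saturated: n == r
        X = np.eye(4)
        sat = evlm.DesignMatrix(X, [f"e{i}" for i in range(4)])
        data4 = evlm.ModelData(
            y=rng.standard_normal(4), predictors=pd.DataFrame({"x": np.zeros(4)})
        )
        fsat = evlm.fit(data4, sat)
        with pytest.raises(DegenerateFitError):
            fsat.sigma2_unbiased

    def test_residuals_orthogonal_to_design(self, citrus, citrus_design):
        f = evlm.fit(citrus, citrus_design)
        dots = citrus_design.matrix.T @ f.residuals
        assert np.all(np.abs(dots) < 1e-8 * np.linalg.norm(citrus.y))
        assert abs(f.residuals.sum()) < 1e-8  # intercept present


class TestNestedComparisons:
    def test_citrus_interaction_f_and_p(self, citrus_comparison):
        assert citrus_comparison.F == pytest.approx(1.80, abs=0.005)
        assert citrus_comparison.p_central == pytest.approx(0.1817, abs=5e-5)
        assert (citrus_comparison.n, citrus_comparison.r, citrus_comparison.q) == (24, 12, 6)

    def test_drop_null_column_of_noiseless_response_gives_zero_F(self):
        rng = np.random.default_rng(3)
        preds = pd.DataFrame(rng.standard_normal((12, 2)), columns=["x1", "x2"])
        data0 = evlm.ModelData(y=np.zeros(12), predictors=preds)
        d = evlm.build_design(data0, ["1", "x1", "x2"])
        # y in the span of X1 = (intercept, x1): the x2 coefficient is 0
        y = 2.0 + 3.0 * preds["x1"].to_numpy()
        data = evlm.ModelData(y=y, predictors=preds)
        cmp_ = evlm.compare_nested_A(data, d, ["x2"])
        assert cmp_.F == pytest.approx(0.0, abs=1e-16)

    def test_formulation_B_equals_A_on_citrus(
        self, citrus, citrus_design, citrus_interaction_cols, citrus_comparison
    ):
        r = citrus_design.r
        idx = citrus_design.column_indices(citrus_interaction_cols)
        L = np.zeros((len(idx), r))
        for row, j in enumerate(idx):
            L[row, j] = 1.0
        contrast = evlm.ContrastSpec(L=L, h=np.zeros(len(idx)))
        cmp_b = evlm.compare_nested_B(citrus, citrus_design, contrast)
        assert cmp_b.F == pytest.approx(citrus_comparison.F, abs=1e-10)

    def test_constraint_at_estimate_gives_zero_F(self, citrus, citrus_design):
        f = evlm.fit(citrus, citrus_design)
        contrast = evlm.ContrastSpec(L=np.eye(citrus_design.r), h=f.beta_hat)
        cmp_ = evlm.compare_nested_B(citrus, citrus_design, contrast)
        assert cmp_.F == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficient_L_rejected(self, citrus, citrus_design):
        L = np.zeros((2, citrus_design.r))
        L[0, 1] = 1.0
        L[1, 1] = 2.0  # second row is a multiple of the first
        with pytest.raises(RankDeficientError):
            evlm.ContrastSpec(L=L, h=np.zeros(2))

    def test_three_formulas_agree_on_random_instances(self):
        """Dropped-columns F, contrast F, and the variance-reduction form
        are algebraically equivalent; checked on 100 random instances."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n, r, q, X, y = random_nested_instance(rng)
            names = [f"c{j}" for j in range(r)]
            design = evlm.DesignMatrix(X, names)
            preds = pd.DataFrame(X[:, 1:], columns=names[1:])
            data = evlm.ModelData(y=y, predictors=preds)
            dropped = names[r - q:]
            cmp_a = evlm.compare_nested_A(data, design, dropped)
            L = np.zeros((q, r))
            for row, j in enumerate(range(r - q, r)):
                L[row, j] = 1.0
            cmp_b = evlm.compare_nested_B(
                data, design, evlm.ContrastSpec(L=L, h=np.zeros(q))
            )
            # variance-reduction form from the two ML variance estimates
            f2 = evlm.fit(data, design)
            f1 = evlm.fit(data, design.drop(dropped))
            F_red = (n - r) / q * (f1.sigma2_ml - f2.sigma2_ml) / f2.sigma2_ml
            assert cmp_b.F == pytest.approx(cmp_a.F, abs=1e-10 * (1 + cmp_a.F))
            assert F_red == pytest.approx(cmp_a.F, abs=1e-10 * (1 + cmp_a.F))

    def test_G2_matches_loglik_route(self, citrus, citrus_design,
                                      citrus_interaction_cols, citrus_comparison):
        # dual route: -2(loglik1 - loglik2) vs the F transform
        f2 = evlm.fit(citrus, citrus_design)
        f1 = evlm.fit(citrus, citrus_design.drop(citrus_interaction_cols))
        g2_direct = -2.0 * (f1.loglik_max - f2.loglik_max)
        assert citrus_comparison.G2 == pytest.approx(g2_direct, abs=1e-10)

    def test_F_invariant_to_coding(self, citrus):
        d_tr = evlm.build_design(citrus, ["1", "tree", "pest", "tree:pest"], "treatment")
        d_sum = evlm.build_design(citrus, ["1", "tree", "pest", "tree:pest"], "sum")
        inter_tr = [c for c in d_tr.column_names if ":" in c]
        inter_sum = [c for c in d_sum.column_names if ":" in c]
        f_tr = evlm.compare_nested_A(citrus, d_tr, inter_tr).F
        f_sum = evlm.compare_nested_A(citrus, d_sum, inter_sum).F
        assert f_sum == pytest.approx(f_tr, abs=1e-10)


class TestAnovaTable:
    def test_citrus_reproduces_printed_table(self, citrus):
        tbl = evlm.anova_table(citrus, ["pest", "tree", "pest:tree"])
        assert tbl.loc["pest", "SS"] == pytest.approx(2227.458333, abs=5e-7)
        assert tbl.loc["pest", "df"] == 3
        assert tbl.loc["tree", "SS"] == pytest.approx(3996.083333, abs=5e-7)
        assert tbl.loc["tree", "df"] == 2
        assert tbl.loc["pest:tree", "SS"] == pytest.approx(456.916667, abs=5e-7)
        assert tbl.loc["pest:tree", "df"] == 6
        assert tbl.loc["pest:tree", "F"] == pytest.approx(1.80, abs=0.005)
        assert tbl.loc["pest:tree", "p"] == pytest.approx(0.1817, abs=5e-5)
        assert tbl.loc["Error", "df"] == 12

    def test_zero_response_gives_zero_SS(self, citrus):
        data = evlm.ModelData(
            y=np.zeros(citrus.n), predictors=citrus.predictors,
            factors=citrus.factors,
        )
        tbl = evlm.anova_table(data, ["pest", "tree"])
        assert np.all(np.abs(tbl["SS"].to_numpy()) < 1e-20)

    def test_sequential_SS_sum_to_total_corrected_SS(self):
        spec = evlm.FactorialSpec(levels=(2, 2), cell_size=3,
                                  interaction_scale=0.7, sigma=2.0, seed=5)
        data = evlm.generate_factorial(spec).data
        tbl = evlm.anova_table(data, ["f1", "f2", "f1:f2"])
        total = np.sum((data.y - data.y.mean()) ** 2)
        assert tbl["SS"].sum() == pytest.approx(total, rel=1e-12)

    def test_quantitative_term_rejected(self):
        rng = np.random.default_rng(0)
        preds = pd.DataFrame({"x": rng.standard_normal(10)})
        data = evlm.ModelData(y=rng.standard_normal(10), predictors=preds)
        with pytest.raises(ValueError, match="not a factor"):
            evlm.anova_table(data, ["x"])


def test_csv_roundtrip(tmp_path, citrus):
    path = tmp_path / "citrus.csv"
    citrus.to_csv(path, response_name="yield")
    back = evlm.read_csv(path, response="yield", factors=["tree", "pest"])
    np.testing.assert_array_equal(back.y, citrus.y)
    assert back.is_factor("tree") and back.is_factor("pest")
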