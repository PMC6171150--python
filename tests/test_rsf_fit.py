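import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ptarmigan_rsf import covariates as cov
from ptarmigan_rsf.rsf import (
    BinAssignment,
    ModelSpec,
    _Laplace,
    build_design,
    candidate_set,
    fit_mixed_logistic,
    marginal_loglik_agq,
    model_comparison_table,
    predict_rsf,
    quantile_bin,
    scale_rsf,
    select_model,
)

PARSIMONIOUS = ModelSpec(timberline="quadratic", slope="quadratic")


def _records(rng, n=400, classes=None, areas=("A1", "A2", "A3")):
    classes = classes or [
        "Exposed alpine ridges",
        "Herb-rich meadows",
        "Lichen-rich heathland",
    ]
    df = pd.DataFrame(
        {
            "response": rng.integers(0, 2, n),
            "vegetation_class": rng.choice(classes, n),
            "area_id": rng.choice(areas, n),
            "timberline_dev_m_std": rng.normal(size=n),
            "slope_deg_std": rng.normal(size=n),
            "n_aspect_std": rng.normal(size=n),
            "e_aspect_std": rng.normal(size=n),
            "aspect_category": rng.choice(
                ["flat", "north", "east", "south", "west"], n
            ),
        }
    )
    return df


class TestModelSpec:
    def test_parsimonious_parameter_count_is_21(self):
        # 1 intercept + 15 vegetation dummies + 4 continuous + variance
        assert PARSIMONIOUS.n_parameters(n_veg_levels=16) == 21

    def test_categorical_aspect_adds_four(self):
        spec = ModelSpec(timberline="quadratic", slope="quadratic",
                         aspect="categorical")
        assert spec.n_parameters(16) == 25

    def test_default_candidate_grid(self):
        specs = candidate_set()
        assert len(specs) == 24
        labels = {s.label() for s in specs}
        # the four printed confidence-set structures are all present
        for aspect in ("none", "categorical", "ns", "ns_ew"):
            assert ModelSpec("quadratic", "quadratic", aspect) in specs
        assert len(labels) == 24

    def test_empty_grid_collapses_to_vegetation_only(self):
        specs = candidate_set((), (), ())
        assert specs == [ModelSpec()]

    def test_invalid_option_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(timberline="cubic")


class TestBuildDesign:
    def test_parsimonious_has_20_fixed_effect_columns(self, rng):
        df = _records(rng, 2000, classes=list(cov.MODELLING_CLASSES))
        y, X, groups = build_design(df, PARSIMONIOUS)
        assert X.shape[1] == 20
        assert X.columns[0] == "intercept"

    def test_categorical_aspect_adds_4_dummies(self, rng):
        df = _records(rng, 2000, classes=list(cov.MODELLING_CLASSES))
        spec = ModelSpec("quadratic", "quadratic", "categorical")
        _, X, _ = build_design(df, spec)
        assert X.shape[1] == 24
        for cat in ("north", "east", "south", "west"):
            assert f"aspect[{cat}]" in X.columns

    def test_reference_row_is_intercept_only(self, rng):
        df = _records(rng, 50)
        df.loc[0, "vegetation_class"] = "Exposed alpine ridges"
        df.loc[0, ["timberline_dev_m_std", "slope_deg_std"]] = 0.0
        _, X, _ = build_design(df, PARSIMONIOUS)
        row = X.iloc[0]
        assert row["intercept"] == 1.0
        assert (row.drop("intercept") == 0.0).all()

    def test_missing_level_named_in_error(self, rng):
        df = _records(rng, 50)
        with pytest.raises(ValueError, match="Lowland forest"):
            build_design(df, PARSIMONIOUS, veg_levels=list(cov.MODELLING_CLASSES))


def _simulate_glmm(rng, beta, sigma_u, J=6, n_per_group=150):
    n = J * n_per_group
    X = np.column_stack([np.ones(n), rng.normal(size=(n, len(beta) - 1))])
    g = np.repeat(np.arange(J), n_per_group)
    u = rng.normal(0.0, sigma_u, J)
    p = 1.0 / (1.0 + np.exp(-(X @ beta + u[g])))
    y = (rng.uniform(size=n) < p).astype(float)
    return y, pd.DataFrame(X, columns=["intercept", "x1", "x2"]), g


class TestFitMixedLogistic:
    def test_analytic_gradient_matches_numeric(self, rng):
        y, X, g = _simulate_glmm(rng, np.array([0.2, -0.5, 0.8]), 0.6)
        lap = _Laplace(y, X.to_numpy(), g, g.max() + 1)
        theta = np.array([0.1, -0.3, 0.5, math.log(0.4)])
        _, grad = lap.loglik_grad(theta)
        num = np.empty_like(theta)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            num[i] = (
                _Laplace(y, X.to_numpy(), g, g.max() + 1).loglik_grad(tp)[0]
                - _Laplace(y, X.to_numpy(), g, g.max() + 1).loglik_grad(tm)[0]
            ) / 2e-6
        np.testing.assert_allclose(grad, num, atol=1e-5)

    def test_laplace_close_to_quadrature_on_two_group_toy(self, rng):
        y, X, g = _simulate_glmm(rng, np.array([0.0, 0.7, -0.4]), 0.8, J=2,
                                 n_per_group=40)
        fit = fit_mixed_logistic(y, X, g)
        agq = marginal_loglik_agq(
            fit.beta.to_numpy(), max(fit.sigma_u, 1e-4), y, X.to_numpy(), g,
            n_nodes=51,
        )
        assert fit.loglik == pytest.approx(agq, abs=0.05)

    def test_zero_variance_limit_matches_plain_logistic(self, rng):
        beta = np.array([0.3, -0.5, 0.8])
        y, X, g = _simulate_glmm(rng, beta, sigma_u=0.0, J=5, n_per_group=200)
        fit = fit_mixed_logistic(y, X, g)
        ml = sm.Logit(y, X.to_numpy()).fit(disp=0)
        assert np.max(np.abs(fit.beta.to_numpy() - ml.params)) < 1e-3
        assert fit.sigma_u < 0.01

    def test_aic_identity_and_K(self, rng):
        y, X, g = _simulate_glmm(rng, np.array([0.1, 0.4, -0.2]), 0.5)
        fit = fit_mixed_logistic(y, X, g)
        assert fit.K == X.shape[1] + 1
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.K, abs=1e-10)

    def test_single_group_rejected(self, rng):
        y, X, g = _simulate_glmm(rng, np.array([0.1, 0.4, -0.2]), 0.5, J=1)
        with pytest.raises(ValueError, match="survey areas"):
            fit_mixed_logistic(y, X, g)

    def test_serialization_round_trip(self, rng):
        from ptarmigan_rsf.rsf import RSFFit

        y, X, g = _simulate_glmm(rng, np.array([0.1, 0.4, -0.2]), 0.5)
        fit = fit_mixed_logistic(y, X, g)
        back = RSFFit.from_json(fit.to_json())
        pd.testing.assert_series_equal(back.beta, fit.beta)
        assert back.aic == fit.aic


class TestSelectModel:
    def _fit_like(self, aic, K):
        from ptarmigan_rsf.rsf import RSFFit

        return RSFFit(
            spec=ModelSpec(), veg_levels=[], beta=pd.Series(dtype=float),
            se=pd.Series(dtype=float), sigma_u=0.1, loglik=-(aic - 2 * K) / 2,
            aic=aic, K=K, n_obs=10, n_groups=2, converged=True,
        )

    def test_parsimony_within_two_aic(self):
        rich = self._fit_like(53190.30, 25)
        lean = self._fit_like(53190.65, 21)
        assert select_model([rich, lean]) is lean

    def test_clear_winner_by_aic(self):
        a = self._fit_like(100.0, 25)
        b = self._fit_like(103.0, 21)
        assert select_model([a, b]) is a

    def test_single_fit_returned(self):
        only = self._fit_like(50.0, 5)
        assert select_model([only]) is only

    def test_comparison_table_weights_sum_to_one(self):
        tab = model_comparison_table(
            [self._fit_like(100.0, 5), self._fit_like(101.0, 4)]
        )
        assert tab["AIC_wt"].sum() == pytest.approx(1.0)
        assert list(tab["dAIC"].round(6)) == [0.0, 1.0]


class TestPredictRsf:
    def _fit(self, rng):
        df = _records(rng, 600)
        df["response"] = rng.integers(0, 2, len(df))
        y, X, g = build_design(df, PARSIMONIOUS)
        levels = ["Exposed alpine ridges"] + [
            c[4:-1] for c in X.columns if c.startswith("veg[")
        ]
        return fit_mixed_logistic(y, X, g, spec=PARSIMONIOUS,
                                  veg_levels=levels), df

    def test_reference_record_gives_w_equal_one(self, rng):
        fit, df = self._fit(rng)
        rec = df.iloc[[0]].copy()
        rec["vegetation_class"] = "Exposed alpine ridges"
        rec[["timberline_dev_m_std", "slope_deg_std"]] = 0.0
        assert predict_rsf(fit, rec)[0] == pytest.approx(1.0, abs=1e-12)

    def test_log_w_is_linear_predictor_without_intercept(self, rng):
        fit, df = self._fit(rng)
        _, X, _ = build_design(df, PARSIMONIOUS)
        cols = [c for c in X.columns if c != "intercept"]
        oracle = X[cols].to_numpy() @ fit.beta[cols].to_numpy()
        np.testing.assert_allclose(np.log(predict_rsf(fit, df)), oracle,
                                   atol=1e-10)

    def test_monotone_in_positive_coefficient(self, rng):
        fit, df = self._fit(rng)
        b = fit.beta["timberline_dev"]
        rec = df.iloc[[0, 0]].copy().reset_index(drop=True)
        rec.loc[1, "timberline_dev_m_std"] = rec.loc[0, "timberline_dev_m_std"] + 1.0
        w = predict_rsf(fit, rec)
        assert (w[1] > w[0]) == (
            b + fit.beta["timberline_dev^2"]
            * (rec.loc[1, "timberline_dev_m_std"] + rec.loc[0, "timberline_dev_m_std"])
            > 0
        )


class TestScaleAndBin:
    def test_scale_examples(self):
        np.testing.assert_allclose(scale_rsf([2.0, 4.0, 8.0]), [0.25, 0.5, 1.0])
        np.testing.assert_allclose(scale_rsf([3.0, 3.0]), [1.0, 1.0])

    def test_scale_preserves_order(self, rng):
        v = rng.uniform(0.01, 5.0, 100)
        s = scale_rsf(v)
        assert np.array_equal(np.argsort(v), np.argsort(s))
        assert s.max() == 1.0

    def test_bins_1_to_100(self):
        values = np.arange(1, 101, dtype=float)
        bins = quantile_bin(values)
        idx = bins.assign(values)
        assert set(idx[:10]) == {1}
        counts = np.bincount(idx, minlength=11)[1:]
        assert np.all(np.abs(counts - 10) <= 1)

    def test_assignment_monotone(self, rng):
        v = np.sort(rng.normal(size=500))
        idx = quantile_bin(v).assign(v)
        assert np.all(np.diff(idx) >= 0)

    def test_tied_values_warn(self):
        with pytest.warns(UserWarning):
            quantile_bin(np.ones(50))
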