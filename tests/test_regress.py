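import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from histonet import regress, synth
from histonet.regress import (
    bic_of_fit,
    cross_validate,
    derangement,
    enumerate_combination_models,
    fit_linear,
    improvement_ratio,
    interaction_design,
    shuffle_control,
    transfer_predict,
)


def make_xy(m=200, n=4, seed=0, noise=0.0, coeffs=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((m, n)), columns=[f"f{i}" for i in range(n)])
    coeffs = coeffs if coeffs is not None else np.zeros(n)
    y = pd.Series(X.to_numpy() @ np.asarray(coeffs) + noise * rng.standard_normal(m))
    return X, y


class TestFitLinear:
    def test_exact_noiseless_recovery(self):
        X, _ = make_xy(m=50, n=2, seed=1)
        y = 2 * X["f0"] - X["f1"] + 3
        fit = fit_linear(X, y)
        assert fit.params["f0"] == pytest.approx(2, abs=1e-10)
        assert fit.params["f1"] == pytest.approx(-1, abs=1e-10)
        assert fit.intercept == pytest.approx(3, abs=1e-10)
        assert fit.rss == pytest.approx(0, abs=1e-16)

    def test_interaction_design_counts(self):
        X, _ = make_xy(n=5)
        assert interaction_design(X).shape[1] == 5 + math.comb(5, 2)

    def test_null_model_bh_flags_nothing(self):
        # y independent of X: adjusted p-values at 0.001 flag ~0 coefficients
        flagged = 0
        for seed in range(1, 21):
            X, y = make_xy(m=500, n=8, seed=seed, noise=1.0)
            flagged += len(fit_linear(X, y).significant(0.001))
        assert flagged <= 1

    def test_rank_deficiency_names_columns(self):
        X, y = make_xy(m=50, n=3, seed=2, noise=1.0)
        X["dup"] = X["f0"]
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(X, y)

    def test_too_few_rows_rejected(self):
        X, y = make_xy(m=5, n=6, noise=1.0)
        with pytest.raises(ValueError, match="more rows than regressors"):
            fit_linear(X, y)

    def test_adjusted_p_not_below_raw(self):
        X, y = make_xy(m=300, n=6, seed=3, noise=1.0, coeffs=[1, 0.5, 0, 0, 0, 0])
        fit = fit_linear(X, y)
        fam = fit.pvalues.drop("intercept")
        assert (fit.pvalues_adj >= fam - 1e-15).all()


class TestCrossValidate:
    def test_noiseless_model_scores_one(self):
        X, y = make_xy(m=200, n=3, seed=4, coeffs=[1, 2, -1])
        assert cross_validate(X, y, seed=0).mean_r == pytest.approx(1.0, abs=1e-9)

    def test_null_model_scores_near_zero(self):
        # chance level: per-fold r has sd ~ 1/sqrt(fold size), so single
        # seeds scatter within ~0.15 while the seed average sits near 0
        rs = []
        for seed in range(1, 11):
            X, y = make_xy(m=1000, n=5, seed=seed, noise=1.0)
            rs.append(cross_validate(X, y, seed=seed).mean_r)
        assert all(abs(r) < 0.15 for r in rs)
        assert abs(np.mean(rs)) < 0.05

    def test_mean_r_matches_population_r_squared(self):
        # y = x1 + noise(1): population R^2 = 0.5, CV r -> sqrt(0.5)
        X, y = make_xy(m=5000, n=5, seed=7, noise=1.0, coeffs=[1, 0, 0, 0, 0])
        assert cross_validate(X, y, seed=7).mean_r == pytest.approx(math.sqrt(0.5), abs=0.05)

    def test_folds_partition_rows(self):
        X, y = make_xy(m=105, n=3, seed=8, noise=1.0, coeffs=[1, 0, 0])
        cv = cross_validate(X, y, k=10, seed=8)
        counts = np.bincount(cv.fold_of_row, minlength=10)
        assert counts.sum() == 105 and counts.max() - counts.min() <= 1

    def test_column_order_invariance(self):
        X, y = make_xy(m=400, n=4, seed=9, noise=0.5, coeffs=[1, -1, 0.5, 0])
        r1 = cross_validate(X, y, seed=3).mean_r
        r2 = cross_validate(X[list(X.columns[::-1])], y, seed=3).mean_r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestShuffleControl:
    @given(st.integers(2, 30), st.integers(0, 10))
    def test_derangement_has_no_fixed_points(self, n, seed):
        perm = derangement(n, np.random.default_rng(seed))
        assert sorted(perm) == list(range(n))
        assert not np.any(perm == np.arange(n))

    def test_two_columns_swap_deterministically(self):
        perm = derangement(2, np.random.default_rng(0))
        assert list(perm) == [1, 0]

    def test_single_column_has_no_derangement(self):
        X, y = make_xy(m=100, n=1, noise=0.5, coeffs=[1])
        with pytest.raises(ValueError, match="derangement"):
            shuffle_control(X, y)

    def test_strong_model_collapses_under_shuffle(self):
        data, truth = synth.scenario("single_driver", seed=3)
        X, y = data[truth.feature_names], data["exon_expr"]
        unshuffled = cross_validate(X, y, seed=3).mean_r
        shuffled = shuffle_control(X, y, seed=3).mean_r
        assert unshuffled > 0.9
        assert abs(shuffled) < 0.2


class TestImprovementRatio:
    def test_printed_example(self):
        assert improvement_ratio(0.70, 0.68) == pytest.approx(0.0286, abs=5e-4)

    def test_identity_and_sign(self):
        assert improvement_ratio(0.5, 0.5) == 0
        assert improvement_ratio(0.5, 0.6) == pytest.approx(-0.2)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            improvement_ratio(0.0, 0.5)


class TestCombinationModels:
    def test_combination_counts(self):
        X, y = make_xy(m=100, n=3, seed=5, noise=0.5, coeffs=[1, 0, 0])
        results, _ = enumerate_combination_models(X, y, seed=5)
        sizes = [len(c) for c, _ in results]
        assert sizes.count(1) == 3 and sizes.count(2) == 3

    def test_driver_features_win(self):
        # only f0 and f1 drive y: the best 1-model uses one of them,
        # the best 2-model uses both
        for seed in range(1, 6):
            X, y = make_xy(m=400, n=5, seed=seed, noise=0.3, coeffs=[1.2, 1.0, 0, 0, 0])
            results, full_r = enumerate_combination_models(X, y, seed=seed)
            best = results[-1][0]
            best1 = max((r for r in results if len(r[0]) == 1), key=lambda t: t[1])[0]
            assert best1[0] in ("f0", "f1")
            assert set(best) == {"f0", "f1"}
            assert full_r >= results[-1][1] - 0.05


class TestTransferPredict:
    def test_training_data_reproduces_in_sample_r(self):
        X, y = make_xy(m=300, n=4, seed=6, noise=0.5, coeffs=[1, -0.5, 0, 0])
        fit = fit_linear(X, y)
        r, p = transfer_predict(fit, X, y)
        yhat = regress.predict(fit, X)
        assert r == pytest.approx(np.corrcoef(y, yhat)[0, 1], abs=1e-12)
        assert p < 1e-10

    def test_perfect_prediction(self):
        X, y = make_xy(m=100, n=2, seed=6, noise=0.5, coeffs=[1, 1])
        fit = fit_linear(X, y)
        yhat = pd.Series(regress.predict(fit, X))
        r, _ = transfer_predict(fit, X, yhat)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_missing_feature_named(self):
        X, y = make_xy(m=100, n=2, seed=6, noise=0.5, coeffs=[1, 1])
        fit = fit_linear(X, y)
        with pytest.raises(KeyError, match="f1"):
            regress.predict(fit, X[["f0"]])


class TestBIC:
    def test_matches_brute_force_gaussian_likelihood(self):
        X, y = make_xy(m=150, n=3, seed=10, noise=0.7, coeffs=[1, 0.5, 0])
        fit = fit_linear(X, y)
        yhat = regress.predict(fit, X)
        sigma2 = fit.rss / fit.m
        loglik = np.sum(
            -0.5 * math.log(2 * math.pi * sigma2) - (y - yhat) ** 2 / (2 * sigma2)
        )
        assert bic_of_fit(fit) == pytest.approx(-2 * loglik + fit.d * math.log(fit.m), rel=1e-10)

    def test_extra_useless_regressor_costs_about_log_m(self):
        X, y = make_xy(m=2000, n=2, seed=11, noise=0.5, coeffs=[1, 0.5])
        rng = np.random.default_rng(11)
        X2 = X.copy()
        X2["noise"] = rng.standard_normal(len(X))
        delta = bic_of_fit(fit_linear(X2, y)) - bic_of_fit(fit_linear(X, y))
        assert delta == pytest.approx(math.log(2000), abs=4)

    def test_monotone_in_rss_at_fixed_d(self):
        X, y = make_xy(m=300, n=2, seed=12, noise=0.5, coeffs=[1, 1])
        good = fit_linear(X, y)
        bad = fit_linear(X, y.sample(frac=1, random_state=0).reset_index(drop=True))
        assert bad.rss > good.rss and bic_of_fit(bad) > bic_of_fit(good)

    def test_interpolated_response_rejected(self):
        X, _ = make_xy(m=50, n=2, seed=13)
        fit = fit_linear(X, 2 * X["f0"])  # RSS numerically zero
        with pytest.raises(ValueError, match="RSS"):
            bic_of_fit(fit)


class TestParameterRecovery:
    def test_known_coefficients_within_three_se(self):
        """OLS on the generator's own design recovers its coefficients."""
        hits = total = 0
        for seed in range(1, 11):
            data, truth = synth.scenario("small", m=2000, seed=seed)
            X = data[[c for c in data.columns if c != "exon_expr"]]
            fit = fit_linear(X, data["exon_expr"])
            expected = {f: truth.exon_coeffs.get(f, 0.0) for f in truth.feature_names}
            expected["gene_expr"] = truth.exon_gene_coef
            for name, a_true in expected.items():
                total += 1
                hits += abs(fit.params[name] - a_true) <= 3 * fit.bse[name]
        assert hits / total >= 0.95
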