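"""Standardization, model fitting, AICc ranking and conditional averaging."""

import numpy as np
import pandas as pd
import pytest

from fragweb.errors import RankDeficiencyError, StatisticalError
from fragweb.inference import (
    ModelFit,
    aicc,
    build_design,
    candidate_set,
    conditional_average,
    enumerate_submodels,
    fit_binom,
    fit_lm,
    respects_marginality,
    standardize01,
    vif,
)


class TestStandardize01:
    def test_maps_range_to_unit_interval(self):
        np.testing.assert_allclose(standardize01([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_unit_range(self):
        x = np.array([0.0, 0.3, 0.8, 1.0])
        np.testing.assert_allclose(standardize01(x), x)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        np.testing.assert_allclose(standardize01(3.7 * x - 11.0), standardize01(x), atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatisticalError):
            standardize01([5, 5, 5])


class TestFitLm:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        fit = fit_lm(2 * x, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicated_predictor_names_aliased_column(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(RankDeficiencyError) as exc:
            fit_lm(2 * x, X)
        assert "b" in exc.value.aliased

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=n)
        fit = fit_lm(y, X)
        M = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        # gaussian ML log-likelihood oracle
        resid = y - M @ beta
        sigma2 = (resid**2).mean()
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        assert fit.loglik == pytest.approx(llf, abs=1e-8)
        assert fit.k == 3 + 1 + 1  # slopes + intercept + variance


class TestFitBinom:
    def test_intercept_only_closed_form(self):
        # 29 successes of 67 -> logit MLE = ln(29/38)
        fit = fit_binom([29], [67], pd.DataFrame(index=[0]))
        assert fit.params["Intercept"] == pytest.approx(np.log(29 / 38), abs=1e-8)

    def test_all_successes_flags_separation(self):
        s = np.array([10, 12, 9, 11, 10, 12])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        # x perfectly predicts saturation: separation along x
        s2 = np.where(x > 0, 10, 0)
        fit = fit_binom(s2, np.full(6, 10), pd.DataFrame({"x": x}))
        assert not fit.converged

    def test_two_group_saturated_logits(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        s = np.array([3.0, 4.0, 8.0, 9.0])
        t = np.array([10.0, 10.0, 12.0, 12.0])
        fit = fit_binom(s, t, pd.DataFrame({"x": x}))
        logit0 = np.log(7 / 13)   # pooled group x=0: 7 of 20
        logit1 = np.log(17 / 7)   # pooled group x=1: 17 of 24
        assert fit.params["Intercept"] == pytest.approx(logit0, abs=1e-6)
        assert fit.params["Intercept"] + fit.params["x"] == pytest.approx(logit1, abs=1e-6)

    def test_invalid_counts_rejected(self):
        with pytest.raises(StatisticalError):
            fit_binom([5], [3], pd.DataFrame(index=[0]))


class TestAicc:
    def test_formula(self):
        # AIC 20 with k=2, n=10 -> 20 + 12/7
        loglik = -(20 - 2 * 2) / 2
        assert aicc(loglik, 2, 10) == pytest.approx(20 + 12 / 7)

    def test_approaches_aic_for_large_n(self):
        loglik, k = -37.2, 4
        aic = -2 * loglik + 2 * k
        assert aicc(loglik, k, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_always_exceeds_aic(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            loglik = rng.normal(scale=30)
            k = int(rng.integers(1, 8))
            n = int(rng.integers(k + 2, 60))
            assert aicc(loglik, k, n) > -2 * loglik + 2 * k

    def test_small_n_rejected(self):
        with pytest.raises(StatisticalError):
            aicc(-10.0, 5, 6)


class TestEnumeration:
    def test_single_main_effect(self):
        assert enumerate_submodels(["L"]) == [frozenset(), frozenset({"L"})]

    def test_three_mains_three_interactions_yields_18(self):
        models = enumerate_submodels(["L", "S", "C", "L:C", "S:C", "L:S"])
        assert len(models) == 18
        # exhaustive independent oracle over all subsets
        import itertools

        terms = ["L", "S", "C", "L:C", "S:C", "L:S"]
        oracle = sum(
            1
            for r in range(len(terms) + 1)
            for combo in itertools.combinations(terms, r)
            if respects_marginality(combo)
        )
        assert oracle == 18

    def test_free_covariate_doubles_the_count(self):
        models = enumerate_submodels(["R", "L", "S", "C", "L:C", "S:C", "L:S"])
        assert len(models) == 36

    def test_null_model_included(self):
        assert frozenset() in enumerate_submodels(["L", "S", "L:S"])

    def test_interaction_without_parent_rejected(self):
        assert not respects_marginality({"S:C", "S"})
        with pytest.raises(StatisticalError):
            enumerate_submodels(["S", "S:C"])

    def test_every_enumerated_model_respects_marginality(self):
        for model in enumerate_submodels():
            assert respects_marginality(model)


def _fake_fit(terms, aicc_value, params=None, bse=None):
    terms = frozenset(terms)
    index = ["Intercept"] + sorted(terms)
    params = pd.Series(params if params is not None else 0.0, index=index, dtype=float)
    bse = pd.Series(bse if bse is not None else 1.0, index=index, dtype=float)
    return ModelFit(
        terms=terms, family="gaussian", params=params, bse=bse,
        loglik=0.0, k=len(index) + 1, n=28, aicc=aicc_value,
    )


class TestCandidateSet:
    def test_delta_two_weights(self):
        fits = [_fake_fit(["L"], 100.0), _fake_fit(["S"], 102.0)]
        kept = candidate_set(fits)
        w = {frozenset(f.terms): f.weight for f in kept}
        assert w[frozenset({"L"})] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-4)
        assert w[frozenset({"S"})] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=1e-4)

    def test_delta_seven_excluded_and_six_is_strict(self):
        fits = [_fake_fit(["L"], 100.0), _fake_fit(["S"], 107.0), _fake_fit(["C"], 106.0)]
        kept = candidate_set(fits)
        assert {tuple(sorted(f.terms)) for f in kept} == {("L",)}

    def test_equal_aicc_equal_weights(self):
        fits = [_fake_fit(["L"], 100.0), _fake_fit(["S"], 100.0)]
        kept = candidate_set(fits)
        assert all(f.weight == pytest.approx(0.5) for f in kept)

    def test_weights_sum_to_one(self):
        fits = [_fake_fit([t], 100.0 + d) for t, d in [("L", 0), ("S", 1), ("C", 5.9)]]
        assert sum(f.weight for f in candidate_set(fits)) == pytest.approx(1.0)

    def test_nonconverged_fits_dropped_with_warning(self):
        bad = _fake_fit(["L"], 90.0)
        bad.converged = False
        with pytest.warns(UserWarning):
            kept = candidate_set([bad, _fake_fit(["S"], 100.0)])
        assert [tuple(sorted(f.terms)) for f in kept] == [("S",)]


class TestConditionalAverage:
    def test_weighted_mean_of_estimates(self):
        f1 = _fake_fit(["L"], 0.0, params=[0.0, 1.0], bse=[0.0, 0.0])
        f2 = _fake_fit(["L"], 0.0, params=[0.0, 2.0], bse=[0.0, 0.0])
        f1.weight, f2.weight = 0.6, 0.4
        (avg,) = [t for t in conditional_average([f1, f2]) if t.term == "L"]
        assert avg.estimate == pytest.approx(1.4)
        assert avg.importance == 2

    def test_single_containing_model_passthrough(self):
        f1 = _fake_fit(["L"], 0.0, params=[0.5, 1.3], bse=[0.1, 0.2])
        f2 = _fake_fit([], 0.0, params=[0.5], bse=[0.1])
        f1.weight, f2.weight = 0.3, 0.7
        (avg,) = [t for t in conditional_average([f1, f2]) if t.term == "L"]
        assert avg.estimate == pytest.approx(1.3)
        assert avg.se == pytest.approx(0.2)
        assert avg.importance == 1

    def test_three_model_hand_oracle_including_se(self):
        # weights 0.5 / 0.3 / 0.2; L in first two models only
        f1 = _fake_fit(["L"], 0.0, params=[0.0, 1.0], bse=[0.1, 0.3])
        f2 = _fake_fit(["L", "S"], 0.0, params=[0.0, 2.0, 0.5], bse=[0.1, 0.4, 0.2])
        f3 = _fake_fit(["S"], 0.0, params=[0.0, 0.6], bse=[0.1, 0.2])
        f1.weight, f2.weight, f3.weight = 0.5, 0.3, 0.2
        terms = {t.term: t for t in conditional_average([f1, f2, f3])}
        w = np.array([0.5, 0.3]) / 0.8
        beta = np.array([1.0, 2.0])
        est = float(w @ beta)
        se = float(w @ np.sqrt(np.array([0.3, 0.4]) ** 2 + (beta - est) ** 2))
        assert terms["L"].estimate == pytest.approx(est, abs=1e-12)
        assert terms["L"].se == pytest.approx(se, abs=1e-12)
        from scipy.stats import norm

        assert terms["L"].ci95 == pytest.approx(norm.ppf(0.975) * se, abs=1e-12)
        assert terms["L"].importance == 2 and terms["S"].importance == 2

    def test_invariant_to_model_order(self):
        f1 = _fake_fit(["L"], 0.0, params=[0.0, 1.0], bse=[0.1, 0.3])
        f2 = _fake_fit(["L", "S"], 0.0, params=[0.0, 2.0, 0.5], bse=[0.1, 0.4, 0.2])
        f1.weight, f2.weight = 0.6, 0.4
        a = {t.term: t.estimate for t in conditional_average([f1, f2])}
        b = {t.term: t.estimate for t in conditional_average([f2, f1])}
        assert a == b

    def test_single_candidate_degenerate_identity(self):
        f = _fake_fit(["L", "S"], 0.0, params=[0.1, 1.1, -0.4], bse=[0.1, 0.2, 0.3])
        f.weight = 1.0
        terms = {t.term: t for t in conditional_average([f])}
        assert terms["L"].estimate == pytest.approx(1.1)
        assert terms["S"].estimate == pytest.approx(-0.4)
        assert terms["S"].se == pytest.approx(0.3)

    def test_conditional_weights_renormalise_per_term(self):
        f1 = _fake_fit(["L"], 0.0, params=[0.0, 1.0], bse=[0.0, 0.0])
        f2 = _fake_fit([], 0.0, params=[0.0], bse=[0.0])
        f1.weight, f2.weight = 0.25, 0.75
        (avg,) = [t for t in conditional_average([f1, f2]) if t.term == "L"]
        assert avg.estimate == pytest.approx(1.0)  # weight renormalised to 1


class TestVif:
    def test_orthogonal_predictors_give_one(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1.0]})
        np.testing.assert_allclose(vif(X).to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_duplicated_predictor_is_infinite(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"a": x, "b": x})
        assert np.isinf(vif(X)).all()

    def test_matches_r2_oracle(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X["d"] = X["a"] * 0.8 + rng.normal(scale=0.5, size=50)
        values = vif(X)
        for col in X.columns:
            others = X.drop(columns=[col]).to_numpy()
            M = np.column_stack([np.ones(len(X)), others])
            beta, *_ = np.linalg.lstsq(M, X[col].to_numpy(), rcond=None)
            resid = X[col].to_numpy() - M @ beta
            r2 = 1 - (resid**2).sum() / ((X[col] - X[col].mean()) ** 2).sum()
            assert values[col] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestBuildDesign:
    def test_interaction_columns_are_products(self):
        data = pd.DataFrame({"L": [0.0, 0.5, 1.0], "S": [0.0, 1.0, 1.0], "C": [0.2, 0.4, 0.6]})
        X = build_design(data, {"L", "S", "S:C", "C"})
        np.testing.assert_allclose(X["S:C"], data["S"] * data["C"])
        assert list(X.columns) == ["L", "S", "C", "S:C"]
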