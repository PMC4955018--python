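"""Imputation model: linear predictor, fitting against an independent IRLS
oracle, coefficient resampling, and the specification grid."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtoboot import build_spec_grid, fit_model, linear_predictor, resample_coefficients
from mtoboot.model import (
    COEFFICIENT_NAMES,
    CoefficientSet,
    ConfigurationError,
    MissingRegressorError,
    ModelSpec,
    SeparationError,
)

from conftest import irls_logistic


def zero_profile():
    return {n: 0.0 for n in COEFFICIENT_NAMES if n != "intercept"}


class TestLinearPredictor:
    def test_intercept_at_zero_profile(self, published_beta):
        assert linear_predictor(published_beta, zero_profile()) == pytest.approx(
            -1.515, abs=1e-12
        )

    def test_all_zero_coefficients_give_zero(self):
        beta = CoefficientSet(list(COEFFICIENT_NAMES), np.zeros(24))
        profile = {n: 1.0 for n in COEFFICIENT_NAMES if n != "intercept"}
        assert linear_predictor(beta, profile) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        name=st.sampled_from([n for n in COEFFICIENT_NAMES if n != "intercept"]),
        base=st.integers(0, 2**20 - 1),
    )
    def test_unit_toggle_shifts_by_the_coefficient(self, published_beta, name, base):
        """Affinity: toggling one regressor 0 -> 1 moves the log-odds by
        exactly that regressor's coefficient, from any base profile."""
        profile = zero_profile()
        toggleable = [n for n in COEFFICIENT_NAMES if n not in ("intercept", "age", name)]
        for i, other in enumerate(toggleable[:20]):
            profile[other] = float((base >> i) & 1)
        profile[name] = 0.0
        lo = linear_predictor(published_beta, profile)
        profile[name] = 1.0
        hi = linear_predictor(published_beta, profile)
        assert hi - lo == pytest.approx(published_beta[name], abs=1e-12)

    def test_missing_regressor_raises_with_name(self, published_beta):
        profile = zero_profile()
        del profile["ever_raped"]
        with pytest.raises(MissingRegressorError, match="ever_raped"):
            linear_predictor(published_beta, profile)
        profile["ever_raped"] = float("nan")
        with pytest.raises(MissingRegressorError, match="ever_raped"):
            linear_predictor(published_beta, profile)


class TestFitModel:
    def test_intercept_only_closed_form(self, training_sample):
        sample = training_sample.head(200)
        k = int(sample["lifetime_ptsd"].sum())
        n = len(sample)
        beta = fit_model(sample, regressor_names=["intercept"])
        assert beta.values[0] == pytest.approx(math.log(k / (n - k)), abs=1e-8)

    def test_matches_independent_irls_oracle(self, training_sample):
        names = ["intercept", "age", "sex_female", "ever_raped", "easily_startled"]
        sample = training_sample.head(200)
        beta = fit_model(sample, regressor_names=names)
        X = np.column_stack(
            [np.ones(len(sample))]
            + [sample[n].to_numpy(float) for n in names if n != "intercept"]
        )
        oracle = irls_logistic(X, sample["lifetime_ptsd"].to_numpy(float))
        np.testing.assert_allclose(beta.values, oracle, atol=1e-6)

    def test_fit_is_a_local_likelihood_optimum(self, training_sample):
        names = ["intercept", "age", "sex_female"]
        sample = training_sample.head(300)
        beta = fit_model(sample, regressor_names=names)
        X = np.column_stack([np.ones(len(sample)), sample["age"], sample["sex_female"]])
        y = sample["lifetime_ptsd"].to_numpy(float)

        def loglik(b):
            eta = X @ b
            return float(y @ eta - np.logaddexp(0.0, eta).sum())

        best = loglik(beta.values)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert loglik(beta.values + 1e-3 * rng.standard_normal(3)) <= best

    def test_covariance_is_attached_and_symmetric(self, fitted_model):
        cov = fitted_model.covariance
        assert cov is not None and cov.shape == (24, 24)
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert (np.diag(cov) > 0).all()

    def test_spec_drops_age_and_race_and_caps_training_age(self, training_sample):
        spec = ModelSpec(include_age=False, include_race=False, training_age_cap=40)
        beta = fit_model(training_sample, spec)
        assert "age" not in beta.names
        assert not any(n.startswith("race_") for n in beta.names)
        # capping inside fit_model equals manual subsetting with no cap
        manual = fit_model(
            training_sample[training_sample["age"] <= 40],
            ModelSpec(include_age=False, include_race=False, training_age_cap=None),
        )
        np.testing.assert_array_equal(beta.values, manual.values)

    def test_degenerate_outcome_raises_separation(self, training_sample):
        sample = training_sample.head(100).copy()
        sample["lifetime_ptsd"] = 1.0
        with pytest.raises(SeparationError):
            fit_model(sample, regressor_names=["intercept", "age"])


class TestResampling:
    def test_first_draw_is_the_point_estimate(self, fitted_model):
        draws = resample_coefficients(fitted_model, k=5, seed=99)
        np.testing.assert_array_equal(draws[0].values, fitted_model.values)
        assert len(draws) == 5

    def test_zero_covariance_collapses_all_draws(self, published_beta):
        beta = CoefficientSet(
            list(published_beta.names), published_beta.values, np.zeros((24, 24))
        )
        draws = resample_coefficients(beta, k=4, seed=1)
        for d in draws:
            np.testing.assert_array_equal(d.values, beta.values)

    def test_same_seed_is_replay_identical(self, fitted_model):
        a = resample_coefficients(fitted_model, k=6, seed=42)
        b = resample_coefficients(fitted_model, k=6, seed=42)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.values, db.values)

    def test_draw_mean_converges_to_point_estimate(self, fitted_model):
        k = 10_000
        draws = resample_coefficients(fitted_model, k=k, seed=7)
        values = np.array([d.values for d in draws[1:]])  # skip forced first
        se = np.sqrt(np.diag(fitted_model.covariance))
        np.testing.assert_array_less(
            np.abs(values.mean(axis=0) - fitted_model.values), 4 * se / math.sqrt(k)
        )

    def test_requires_covariance(self, published_beta):
        with pytest.raises(ConfigurationError, match="covariance"):
            resample_coefficients(published_beta, k=3, seed=0)

    def test_rejects_non_psd_covariance(self, published_beta):
        cov = -np.eye(24)
        beta = CoefficientSet(list(published_beta.names), published_beta.values, cov)
        with pytest.raises(ConfigurationError, match="semidefinite"):
            resample_coefficients(beta, k=2, seed=0)


class TestSpecGrid:
    def test_grid_has_the_eight_labeled_members_in_order(self):
        grid = build_spec_grid()
        labels = [s.label for s in grid]
        assert labels == [
            "a0r0s40", "a0r0s99", "a0r1s40", "a0r1s99",
            "a1r0s40", "a1r0s99", "a1r1s40", "a1r1s99",
        ]
        assert len(set(labels)) == 8

    def test_original_specification_member(self):
        original = [s for s in build_spec_grid() if s.label == "a1r1s99"]
        assert len(original) == 1
        assert original[0].include_age and original[0].include_race
        assert original[0].training_age_cap is None

    def test_label_roundtrip_and_validation(self):
        for spec in build_spec_grid():
            assert ModelSpec.from_label(spec.label) == spec
        with pytest.raises(ConfigurationError):
            ModelSpec.from_label("a2r0s40")
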