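"""Estimator correctness against materialised-matrix oracles and the
defining algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import agedelta as ad
from agedelta.delta_core import _as_vector

from conftest import make_instance


def materialised_MY(Y):
    """Oracle residual-forming matrix I - Y Y+ built explicitly."""
    y = Y[:, None]
    return np.eye(len(Y)) - y @ np.linalg.pinv(y)


class TestAgeVector:
    def test_demeaning_and_projector(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(40, 80, 25))
        assert abs(Y.Y.mean()) < 1e-10
        assert np.allclose(Y.residualize(Y.Y), 0, atol=1e-10)

    def test_rejects_constant_and_tiny(self):
        with pytest.raises(ad.DegenerateInputError):
            ad.AgeVector.from_raw([50.0, 50.0, 50.0])
        with pytest.raises(ad.DegenerateInputError):
            ad.AgeVector.from_raw([50.0, 60.0])


class TestFitDelta1:
    def test_perfect_predictor(self):
        Y = ad.AgeVector.from_raw([45, 50, 55, 60, 70.0])
        X = ad.FeatureMatrix(X=Y.Y[:, None], is_demeaned=True)
        fit = ad.fit_delta1(X, Y)
        assert np.allclose(fit.beta1, [1.0])
        assert np.allclose(fit.delta1, 0, atol=1e-10)

    def test_age_orthogonal_features_give_minus_age(self, rng):
        # a useless model predicts nothing: delta1 is -1 times (demeaned) age
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 40))
        raw = rng.standard_normal((40, 5))
        X = ad.FeatureMatrix.from_raw(materialised_MY(Y.Y) @ raw)
        fit = ad.fit_delta1(X, Y)
        assert np.allclose(fit.delta1, -Y.Y, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        X, Y = make_instance(10, 3, seed=7)
        fit = ad.fit_delta1(X, Y)
        beta_oracle = np.linalg.solve(X.X.T @ X.X, X.X.T @ Y.Y)
        assert np.allclose(fit.delta1, X.X @ beta_oracle - Y.Y, atol=1e-8)
        # delta1 is orthogonal to every feature column
        assert np.allclose(X.X.T @ fit.delta1, 0, atol=1e-8)

    def test_yb1_consistency(self):
        X, Y = make_instance(15, 4, seed=3)
        fit = ad.fit_delta1(X, Y)
        assert np.allclose(fit.delta1, fit.YB1 - Y.raw, atol=1e-10)

    def test_errors(self, rng):
        X, Y = make_instance(10, 3, seed=1)
        with pytest.raises(ad.DimensionError):
            ad.fit_delta1(X, ad.AgeVector.from_raw(rng.uniform(40, 80, 11)))
        empty = ad.FeatureMatrix(X=np.empty((10, 0)), is_demeaned=True)
        with pytest.raises(ad.DegenerateInputError):
            ad.fit_delta1(empty, Y)


class TestCorrectDelta2:
    def test_pure_age_leakage_removed(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 30))
        beta2, delta2 = ad.correct_delta2(-Y.Y, Y)
        assert beta2 == pytest.approx(-1.0)
        assert np.allclose(delta2, 0, atol=1e-10)

    def test_idempotent_on_corrected_input(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 30))
        d = materialised_MY(Y.Y) @ rng.standard_normal(30)
        beta2, delta2 = ad.correct_delta2(d, Y)
        assert beta2 == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(delta2, d, atol=1e-10)

    def test_matches_projector_oracle(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 50))
        d = rng.standard_normal(50)
        _, delta2 = ad.correct_delta2(d, Y)
        assert np.allclose(delta2, materialised_MY(Y.Y) @ d, atol=1e-10)


class TestFitDelta3:
    def test_formula_oracle(self):
        X, Y = make_instance(50, 5, seed=11)
        gamma, k, delta3 = ad.fit_delta3(X, Y)
        y = Y.Y[:, None]
        k_oracle = float(Y.Y @ Y.Y) / float(Y.Y @ X.X @ X.X.T @ Y.Y)
        d3_oracle = (materialised_MY(Y.Y) @ X.X @ X.X.T @ y * k_oracle).ravel()
        assert k == pytest.approx(k_oracle)
        assert np.allclose(gamma, (np.linalg.pinv(y) @ X.X).ravel(), atol=1e-8)
        assert np.allclose(delta3, d3_oracle, atol=1e-8)
        assert abs(delta3 @ Y.Y) < 1e-8 * np.linalg.norm(delta3) * np.linalg.norm(Y.Y)

    def test_orthonormal_X_gives_k_times_delta2(self):
        X, Y = make_instance(40, 8, seed=5)
        Xo = ad.reduce_feature_matrix(X, 8)
        fit = ad.fit_delta1(Xo, Y)
        _, delta2 = ad.correct_delta2(fit.delta1, Y)
        _, k, delta3 = ad.fit_delta3(Xo, Y)
        assert np.allclose(delta3, k * delta2, atol=1e-8)

    def test_rank1_noiseless_gives_zero(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 20))
        g = rng.standard_normal(4)
        X = ad.FeatureMatrix(X=np.outer(Y.Y, g), is_demeaned=True)
        _, _, delta3 = ad.fit_delta3(X, Y)
        assert np.allclose(delta3, 0, atol=1e-8)

    def test_no_age_signal_raises(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 20))
        X = ad.FeatureMatrix(X=materialised_MY(Y.Y) @ rng.standard_normal((20, 3)),
                             is_demeaned=True)
        with pytest.raises(ad.EstimationError, match="age signal"):
            ad.fit_delta3(X, Y)


class TestQuadraticBasis:
    def test_symmetric_ages(self):
        Y = ad.AgeVector.from_raw(np.array([-2, -1, 0, 1, 2.0]) + 60)
        basis = ad.build_quadratic_basis(Y)
        assert np.allclose(basis.Yo2, [2, -1, -2, -1, 2])

    def test_construction_contract(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 35))
        basis = ad.build_quadratic_basis(Y)
        assert abs(basis.Yo2.mean()) < 1e-10
        assert abs(basis.Y @ basis.Yo2) < 1e-10 * np.linalg.norm(basis.Yo2)

    def test_matches_residualisation_oracle(self):
        r = np.random.default_rng(9)
        ages = r.uniform(45, 75, 20) ** 1.1  # asymmetric
        Y = ad.AgeVector.from_raw(ages)
        basis = ad.build_quadratic_basis(Y)
        # oracle: residual of age^2 on [1, Y] by explicit least squares
        design = np.column_stack([np.ones(20), Y.Y])
        q = Y.Y ** 2
        resid = q - design @ np.linalg.lstsq(design, q, rcond=None)[0]
        assert np.allclose(basis.Yo2, resid, atol=1e-8)

    def test_too_few_distinct_ages(self):
        with pytest.raises(ad.DegenerateInputError):
            ad.build_quadratic_basis(ad.AgeVector.from_raw([50, 50, 70, 70.0]))


class TestQuadraticEstimators:
    def test_pure_quadratic_leakage_removed(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 30))
        basis = ad.build_quadratic_basis(Y)
        _, delta2q = ad.correct_delta2q(3.7 * basis.Yo2, basis)
        assert np.allclose(delta2q, 0, atol=1e-8)

    def test_matches_projector_oracle(self, rng):
        Y = ad.AgeVector.from_raw(rng.uniform(45, 75, 40))
        basis = ad.build_quadratic_basis(Y)
        d = rng.standard_normal(40)
        _, delta2q = ad.correct_delta2q(d, basis)
        MY2 = np.eye(40) - basis.Y2 @ np.linalg.pinv(basis.Y2)
        assert np.allclose(delta2q, MY2 @ d, atol=1e-10)

    def test_collapse_to_linear_when_no_quadratic_effect(self, small_cohort):
        # alpha = 0 cohort: quadratic correction finds nothing beyond linear
        fit = ad.recommended_pipeline(small_cohort.X, small_cohort.ages, J=20)
        assert np.corrcoef(fit.delta2q, fit.delta2)[0, 1] > 0.99
        assert np.allclose(fit.delta2q, fit.delta2,
                           atol=0.25 * np.std(fit.delta2))

    def test_delta3q_formula_oracle(self):
        X, Y = make_instance(30, 6, seed=13)
        basis = ad.build_quadratic_basis(Y)
        gamma2, k, delta3q = ad.fit_delta3q(X, basis, Y)
        MY2 = np.eye(30) - basis.Y2 @ np.linalg.pinv(basis.Y2)
        oracle = MY2 @ X.X @ X.X.T @ Y.Y * k
        assert np.allclose(delta3q, oracle, atol=1e-8)
        assert gamma2.shape == (2, 6)
        assert np.allclose(gamma2, np.linalg.pinv(basis.Y2) @ X.X, atol=1e-8)

    def test_delta3q_proportional_to_delta2q_when_orthonormal(self):
        X, Y = make_instance(40, 8, seed=17)
        Xo = ad.reduce_feature_matrix(X, 8)
        basis = ad.build_quadratic_basis(Y)
        fit = ad.fit_delta1(Xo, Y)
        _, delta2q = ad.correct_delta2q(fit.delta1, basis)
        _, k, delta3q = ad.fit_delta3q(Xo, basis, Y)
        assert np.allclose(delta3q, k * delta2q, atol=1e-8)


class TestRecommendedPipeline:
    def test_composition_matches_manual_sequence(self):
        r = np.random.default_rng(21)
        ages = r.uniform(45, 75, 30)
        Xraw = r.standard_normal((30, 6))
        fit = ad.recommended_pipeline(Xraw, ages, J=4)

        Y = ad.AgeVector.from_raw(ages)
        X = ad.reduce_feature_matrix(ad.FeatureMatrix.from_raw(Xraw), 4)
        basis = ad.build_quadratic_basis(Y)
        manual = ad.fit_delta1(X, Y)
        _, d2 = ad.correct_delta2(manual.delta1, Y)
        _, d2q = ad.correct_delta2q(manual.delta1, basis)
        _, k, d3 = ad.fit_delta3(X, Y)
        _, _, d3q = ad.fit_delta3q(X, basis, Y)
        for got, want in [(fit.delta1, manual.delta1), (fit.delta2, d2),
                          (fit.delta2q, d2q), (fit.delta3, d3),
                          (fit.delta3q, d3q)]:
            assert np.allclose(got, want, atol=1e-12)
        assert np.allclose(fit.YB2, ages + d2, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(8, 40), d=st.integers(1, 6))
def test_orthogonality_invariants(seed, n, d):
    """Every corrected estimator is orthogonal to its age basis."""
    r = np.random.default_rng(seed)
    ages = r.uniform(45, 75, n)
    if np.unique(ages).size < 3:
        return
    X = ad.FeatureMatrix.from_raw(r.standard_normal((n, d)))
    Y = ad.AgeVector.from_raw(ages)
    basis = ad.build_quadratic_basis(Y)
    fit = ad.fit_delta1(X, Y)
    _, delta2 = ad.correct_delta2(fit.delta1, Y)
    _, delta2q = ad.correct_delta2q(fit.delta1, basis)
    scale = np.linalg.norm(Y.Y) + 1
    assert abs(delta2 @ Y.Y) < 1e-8 * scale * (np.linalg.norm(delta2) + 1)
    for col in (basis.Y, basis.Yo2):
        assert abs(delta2q @ col) < 1e-8 * (np.linalg.norm(col) + 1) * (
            np.linalg.norm(delta2q) + 1)
    try:
        _, _, delta3 = ad.fit_delta3(X, Y)
    except ad.EstimationError:
        return
    assert abs(delta3 @ Y.Y) < 1e-8 * scale * (np.linalg.norm(delta3) + 1)
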