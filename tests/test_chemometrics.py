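"""Splitting, NIPALS PLSR, metrics, cross-validation, latent-variable choice."""

import numpy as np
import pytest

from hsiph import (DEFAULT_GRID, compute_metrics, cross_validate, fit_plsr,
                   generate_spectra_table, is_good_model, predict,
                   preset_reduced_model, select_n_latent,
                   split_calibration_prediction)
from hsiph.chemometrics import evaluate_chain_model
from hsiph.io import spectra_matrix
from hsiph.preprocessing import parse_chain


@pytest.fixture(scope="module")
def region_table():
    """33 sausages x 5 regions = 165 rows, as in the reference experiment."""
    return generate_spectra_table(33, preset_reduced_model(), noise_sd=0.05,
                                  seed=3)


class TestSplit:
    def test_165_rows_split_110_and_55(self, region_table):
        cal, pred = split_calibration_prediction(region_table, seed=0)
        assert len(cal) == 110
        assert len(pred) == 55

    def test_split_is_disjoint_and_exhaustive(self, region_table):
        cal, pred = split_calibration_prediction(region_table, seed=5)
        assert set(cal.index).isdisjoint(pred.index)
        assert len(cal) + len(pred) == len(region_table)

    def test_same_seed_reproduces_partition(self, region_table):
        a = split_calibration_prediction(region_table, seed=9)[0]
        b = split_calibration_prediction(region_table, seed=9)[0]
        assert list(a.index) == list(b.index)

    def test_grouped_split_keeps_sausages_together(self, region_table):
        cal, pred = split_calibration_prediction(region_table, seed=2,
                                                 by_sample=True)
        assert set(cal["sample_code"]).isdisjoint(pred["sample_code"])

    def test_fraction_outside_unit_interval_rejected(self, region_table):
        with pytest.raises(ValueError, match="fraction"):
            split_calibration_prediction(region_table, fraction=1.5)


class TestFitPLSR:
    def test_single_direction_affine_response_exact_with_one_lv(self, rng):
        X = rng.normal(size=(20, 30))
        direction = rng.normal(size=30)
        y = 2.0 + X @ direction  # y affine in X along one direction... but
        # PLS needs the X-variance along that direction only; project X first
        X = np.outer(X @ direction, direction) / (direction @ direction)
        model = fit_plsr(X, y, 1)
        r2, _ = compute_metrics(y, predict(model, X))
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_fit_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, 4)
        # independent oracle: intercept-augmented normal equations
        A = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(predict(model, X), A @ beta, atol=1e-8)

    def test_matches_sklearn_reference_implementation(self, rng):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 25))
        y = rng.normal(size=40)
        for lv in (1, 3, 6):
            ours = predict(fit_plsr(X, y, lv), X)
            ref = sklearn_pls.PLSRegression(n_components=lv, scale=False)
            theirs = ref.fit(X, y).predict(X).ravel()
            assert np.allclose(ours, theirs, atol=1e-8)

    def test_score_vectors_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        T = fit_plsr(X, y, 6).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_collapsed_form_equals_latent_path(self, rng):
        # predicting the training data through (b0, b) must equal the score
        # path: t_a q_a accumulated over components
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        model = fit_plsr(X, y, 5)
        latent_path = model.y_mean + model.scores @ model.y_loadings
        assert np.allclose(predict(model, X), latent_path, atol=1e-10)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_plsr(rng.normal(size=(10, 5)), np.full(10, 5.0), 2)

    def test_excessive_latent_count_rejected(self, rng):
        with pytest.raises(ValueError, match="n_latent"):
            fit_plsr(rng.normal(size=(5, 10)), rng.normal(size=5), 5)


class TestPredictAndMetrics:
    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        model = fit_plsr(X, y, 3)
        rows = np.tile(X.mean(axis=0), (4, 1))
        assert np.allclose(predict(model, rows), y.mean(), atol=1e-10)

    def test_zero_coefficients_give_intercept_only(self, rng):
        model = fit_plsr(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        model.coef = np.zeros_like(model.coef)
        model.intercept = 7.0
        assert np.allclose(predict(model, rng.normal(size=(3, 4))), 7.0)

    def test_band_count_mismatch_rejected(self, rng):
        model = fit_plsr(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(ValueError, match="bands"):
            predict(model, rng.normal(size=(3, 5)))

    def test_perfect_fit_metrics(self):
        y = np.array([4.0, 5.0, 6.0])
        r2, rmse = compute_metrics(y, y)
        assert (r2, rmse) == (1.0, 0.0)

    def test_null_model_has_zero_r2(self):
        y = np.array([4.0, 5.0, 6.0])
        r2, _ = compute_metrics(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # residuals (0,0,1): RMSE = sqrt(1/3); SS_tot = 2 so R2 = 1 - 1/2
        r2, rmse = compute_metrics([4.0, 5.0, 6.0], [4.0, 5.0, 7.0])
        assert rmse == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-12)
        assert r2 == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compute_metrics([5.0, 5.0, 5.0], [5.0, 5.1, 4.9])


class TestCrossValidation:
    def test_noiseless_linear_problem_has_vanishing_rmsecv(self, rng):
        X = rng.normal(size=(20, 5))
        beta = rng.normal(size=5)
        y = 3.0 + X @ beta
        _, rmsecv = cross_validate(X, y, 5)
        assert rmsecv < 1e-6

    def test_loo_performs_exactly_n_refits(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        folds = []
        cross_validate(X, y, 2, fold_callback=lambda idx: folds.append(idx))
        assert len(folds) == 12
        assert sorted(int(f[0]) for f in folds) == list(range(12))

    def test_kfold_with_fixed_seed_is_reproducible(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        a = cross_validate(X, y, 3, scheme="kfold", k=5, seed=4)
        b = cross_validate(X, y, 3, scheme="kfold", k=5, seed=4)
        assert a == b

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="k"):
            cross_validate(rng.normal(size=(5, 3)), rng.normal(size=5), 1,
                           scheme="kfold", k=9)


class TestModelSelectionAndQuality:
    def test_single_latent_direction_phantom_selects_one(self, rng):
        # y generated from exactly one X direction
        t = rng.normal(size=40)
        load = rng.normal(size=20)
        X = np.outer(t, load) + 0.01 * rng.normal(size=(40, 20))
        y = 5.0 + 2.0 * t + 0.01 * rng.normal(size=40)
        assert select_n_latent(X, y, max_lv=6) == 1

    def test_max_lv_one_is_forced(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        assert select_n_latent(X, y, max_lv=1) == 1

    def test_adding_pure_noise_bands_does_not_hurt_training_fit(self, rng):
        # at full latent rank PLSR reaches the least-squares fit, and a
        # superset of columns can only lower the training residual
        X = rng.normal(size=(30, 10))
        y = 1.0 + X @ rng.normal(size=10) + 0.05 * rng.normal(size=30)
        _, rmse_base = compute_metrics(y, predict(fit_plsr(X, y, 10), X))
        X_aug = np.hstack([X, rng.normal(size=(30, 10))])
        _, rmse_aug = compute_metrics(y, predict(fit_plsr(X_aug, y, 20), X_aug))
        assert rmse_aug <= rmse_base + 1e-8

    def test_quality_gate_flags_rmsec_rmsecv_gap(self):
        from hsiph.chemometrics import ModelMetrics
        good = ModelMetrics(Rc2=0.9, RMSEC=0.3, Rcv2=0.85, RMSECV=0.35)
        drifted = ModelMetrics(Rc2=0.9, RMSEC=0.3, Rcv2=0.4, RMSECV=0.9)
        assert is_good_model(good)
        assert not is_good_model(drifted)

    def test_low_noise_phantom_prediction_r2_above_095(self, region_table):
        cal, pred = split_calibration_prediction(region_table, seed=1)
        _, metrics = evaluate_chain_model(cal, pred, parse_chain("Raw"),
                                          DEFAULT_GRID, n_latent=12)
        assert metrics.Rp2 >= 0.95
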