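"""PLSR core: oracle equivalence, LOOCV selection, metric semantics."""

import numpy as np
import pytest

from hypernitro import (
    WHOLE_PLANT_BENCHMARK,
    elimination_percentage,
    evaluate,
    fit_plsr,
    loocv_select_lvs,
)
from hypernitro.regression import calibrate_and_evaluate, cv_rmse
from tests.conftest import random_table


class TestFitPlsr:
    def test_perfect_linear_single_band(self):
        """y exactly linear in one band, no noise: 1 LV fits exactly."""
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 20)
        X = np.c_[x, np.full(20, 0.3)]
        y = 2.0 + 3.0 * x
        m = fit_plsr(X, y, 1)
        r, rmse, deg = evaluate(m, X, y)
        assert rmse == pytest.approx(0.0, abs=1e-10)
        assert r == pytest.approx(1.0)
        assert not deg

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25) + 3
        m = fit_plsr(X, y, 6)
        beta = np.linalg.lstsq(np.c_[np.ones(25), X], y, rcond=None)[0]
        np.testing.assert_allclose(m.intercept, beta[0], atol=1e-8)
        np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-8)

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against the scikit-learn PLS solver."""
        from sklearn.cross_decomposition import PLSRegression
        X = rng.uniform(size=(30, 10))
        y = rng.uniform(1, 5, size=30)
        for a in (1, 3, 5):
            mine = fit_plsr(X, y, a)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(mine.coefficients, ref.coef_.ravel(),
                                       atol=1e-8)

    def test_latent_and_linear_forms_agree(self, rng):
        X = rng.uniform(size=(18, 7))
        y = rng.uniform(1, 4, size=18)
        m = fit_plsr(X, y, 4)
        Xnew = rng.uniform(size=(6, 7))
        np.testing.assert_allclose(m.predict(Xnew), m.predict_latent(Xnew),
                                   rtol=1e-8)

    def test_one_lv_direction_proportional_to_covariance(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40) + 2
        m = fit_plsr(X, y, 1)
        cov = (X - X.mean(0)).T @ (y - y.mean())
        w = m.weights[:, 0]
        np.testing.assert_allclose(w, cov / np.linalg.norm(cov), atol=1e-10)

    def test_constant_y_degenerate(self):
        X = np.random.default_rng(2).uniform(size=(10, 4))
        y = np.full(10, 2.5)
        with pytest.warns(UserWarning):
            m = fit_plsr(X, y, 2)
        np.testing.assert_allclose(m.coefficients, 0, atol=1e-12)
        assert m.intercept == pytest.approx(2.5)
        r, rmse, deg = evaluate(m, X, y)
        assert deg and r == 0.0

    def test_rank_deficient_warns_and_clips(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=15)
        X = np.c_[x, 2 * x, 3 * x]          # rank 1
        y = 1 + x
        with pytest.warns(UserWarning, match="achievable"):
            m = fit_plsr(X, y, 3)
        assert m.n_lvs == 1


class TestLoocv:
    def test_matches_explicit_loop_oracle(self, rng):
        """RMSECV equals a hand-rolled leave-one-out loop around the
        scikit-learn PLS solver."""
        from sklearn.cross_decomposition import PLSRegression
        t = random_table(rng, n=9, p=4)
        X, y = t.X, t.y
        _, curve = loocv_select_lvs(X, y, max_lvs=3)
        for a in (1, 2, 3):
            errs = []
            for i in range(9):
                tr = [j for j in range(9) if j != i]
                ref = PLSRegression(n_components=a, scale=False)
                ref.fit(X[tr], y[tr])
                errs.append(float(np.ravel(ref.predict(X[i:i + 1]))[0]) - y[i])
            assert curve[a - 1] == pytest.approx(
                np.sqrt(np.mean(np.square(errs))), rel=1e-8)

    def test_noise_free_one_factor_minimal_at_one_lv(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 2, 15)
        X = np.c_[x, 0.5 * x + 0.1, 2 * x - 0.3] + rng.normal(
            0, 1e-12, (15, 3))
        y = 4 * x - 1
        n_lvs, curve = loocv_select_lvs(X, y, max_lvs=2)
        assert n_lvs == 1
        assert curve[0] == pytest.approx(0.0, abs=1e-6)

    def test_tie_breaks_toward_fewer_lvs(self):
        n_lvs_equal = np.argmin(np.array([0.5, 0.5, 0.7])) + 1
        assert n_lvs_equal == 1      # documents the first-minimum convention
        rng = np.random.default_rng(6)
        x = rng.uniform(size=12)
        X = np.c_[x, np.full(12, 0.2)]
        y = 3 * x
        n_lvs, curve = loocv_select_lvs(X, y, max_lvs=2)
        assert n_lvs == 1

    def test_max_lvs_clipped_with_warning(self, rng):
        t = random_table(rng, n=6, p=10)
        with pytest.warns(UserWarning, match="clipping"):
            n_lvs, curve = loocv_select_lvs(t.X, t.y, max_lvs=15)
        assert len(curve) == 4      # min(n - 2, p)


class TestEvaluate:
    def test_identity_and_shift(self, rng):
        t = random_table(rng, n=12, p=3)
        m = fit_plsr(t.X, t.y, 3, wavelengths=t.wavelengths)
        r, rmse, _ = evaluate(m, t.X, t.y)
        # shift case: predictions offset by a constant keep R = 1
        y_shift = m.predict(t.X) + 0.7
        r2, rmse2, _ = evaluate(m, t.X, y_shift)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert rmse2 == pytest.approx(0.7, abs=1e-9)

    def test_matches_formula_oracle(self, rng):
        t = random_table(rng, n=10, p=4)
        m = fit_plsr(t.X, t.y, 2, wavelengths=t.wavelengths)
        pred = m.predict(t.X)
        y = t.y
        r, rmse, _ = evaluate(m, t.X, y)
        # direct formulas, written long-hand
        r_direct = (np.sum((pred - pred.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((pred - pred.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(r_direct, rel=1e-10)
        assert rmse == pytest.approx(np.sqrt(np.mean((pred - y) ** 2)),
                                     rel=1e-12)

    def test_wavelength_mismatch_rejected(self, rng):
        t = random_table(rng, n=8, p=4)
        m = fit_plsr(t.X, t.y, 2, wavelengths=t.wavelengths)
        with pytest.raises(ValueError, match="wavelengths"):
            evaluate(m, t.X[:, :3], t.y)


class TestReports:
    def test_elimination_arithmetic(self):
        assert elimination_percentage(460, 8) == pytest.approx(98.26, abs=0.005)
        assert elimination_percentage(100, 25) == 75.0
        with pytest.raises(ValueError):
            elimination_percentage(10, 10)

    def test_benchmark_table_internally_consistent(self):
        f = WHOLE_PLANT_BENCHMARK["F-PLSR"]
        s = WHOLE_PLANT_BENCHMARK["RF-PLSR"]
        assert f["R_P"] - s["R_P"] == pytest.approx(0.032, abs=1e-9)
        assert s["RMSEP"] - f["RMSEP"] == pytest.approx(0.075, abs=1e-9)

    def test_metrics_triad_finite(self, small_table):
        from hypernitro import spxy_split
        res = spxy_split(small_table, 0.75)
        _, m = calibrate_and_evaluate(small_table, res.calibration_idx,
                                      res.prediction_idx, max_lvs=5)
        for v in (m.R_C, m.RMSEC, m.R_CV, m.RMSECV, m.R_P, m.RMSEP):
            assert np.isfinite(v)
        assert abs(m.R_C) <= 1 and m.RMSEC >= 0

    def test_cv_rmse_sanity(self, rng):
        t = random_table(rng, n=20, p=5)
        e = cv_rmse(t.X, t.y, n_lvs=2, n_folds=5)
        assert np.isfinite(e) and e >= 0
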