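import numpy as np
import pytest

from eggfresh import (
    FoldScheme,
    SpectralDataset,
    cross_validate_lv,
    fit_ipls,
    fit_ipls_lasso,
    fit_pls,
    fit_pls_s1,
    fit_pls_s2,
    lasso_fit,
    plant_interval_signal,
    predict_members,
    select_lambda,
    sweep_divisions,
)
from eggfresh.fusion import lambda_max
from eggfresh.pls import cv_predictions


def centered_orthogonal_design(rng, n, m):
    """Columns centred, mutually orthogonal, population SD exactly 1."""
    t = np.arange(n)
    cols = []
    k = 1
    while len(cols) < m:
        cols.append(np.cos(2 * np.pi * k * t / n))
        if len(cols) < m:
            cols.append(np.sin(2 * np.pi * k * t / n))
        k += 1
    Z = np.column_stack(cols)
    return Z / Z.std(axis=0)


class TestLassoFit:
    def test_lambda_zero_equals_ols(self, rng):
        Z = rng.normal(0, 1, (30, 4))
        y = Z @ np.array([1.0, -2.0, 0.0, 0.5]) + rng.normal(0, 0.1, 30)
        beta0, beta = lasso_fit(Z, y, 0.0)
        design = np.column_stack([np.ones(30), Z])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(beta0, ols[0], atol=1e-6)
        assert np.allclose(beta, ols[1:], atol=1e-6)

    def test_full_shrinkage_at_lambda_max(self, rng):
        Z = rng.normal(0, 1, (25, 3))
        y = Z[:, 0] + rng.normal(0, 0.2, 25)
        lam = lambda_max(Z, y)
        beta0, beta = lasso_fit(Z, y, lam)
        assert np.allclose(beta, 0.0)
        assert np.isclose(beta0, y.mean())

    def test_orthonormal_design_soft_thresholds_ols(self, rng):
        """Closed-form oracle: on a centred orthogonal unit-SD design the
        Lasso coefficient is the soft-thresholded OLS coefficient."""
        n = 24
        Z = centered_orthogonal_design(rng, n, 3)
        y = Z @ np.array([2.0, -0.7, 0.1]) + rng.normal(0, 0.3, n)
        lam = 0.4
        beta0, beta = lasso_fit(Z, y, lam)
        yc = y - y.mean()
        b_ols = Z.T @ yc / n  # per-column OLS on orthogonal unit-SD columns
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        assert np.allclose(beta, expected, atol=1e-6)
        assert np.isclose(beta0, y.mean())

    def test_kkt_conditions_hold(self, rng):
        """Subgradient check of the 1/(2N) SSR + lam*L1 objective on random
        5-column problems."""
        for trial in range(5):
            Z = rng.normal(0, 1, (40, 5)) * rng.uniform(0.5, 3.0, 5)
            y = Z @ rng.normal(0, 1, 5) + rng.normal(0, 0.5, 40)
            lam = 0.3 * lambda_max(Z, y)
            _, beta = lasso_fit(Z, y, lam)
            mean, sd = Z.mean(axis=0), Z.std(axis=0)
            Zs = (Z - mean) / sd
            b = beta * sd  # standardized-scale coefficients
            g = Zs.T @ ((y - y.mean()) - Zs @ b) / len(y)
            active = b != 0
            assert np.all(np.abs(g[active] - lam * np.sign(b[active])) < 1e-5)
            assert np.all(np.abs(g[~active]) <= lam + 1e-5)

    def test_matches_reference_solver_on_standardized_design(self, rng):
        from sklearn.linear_model import Lasso

        n = 50
        Z = rng.normal(0, 1, (n, 6))
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        y = Z @ np.array([1.5, 0.0, -0.8, 0.0, 0.3, 0.0]) + rng.normal(0, 0.4, n)
        lam = 0.15
        beta0, beta = lasso_fit(Z, y, lam)
        ref = Lasso(alpha=lam, fit_intercept=True, tol=1e-12,
                    max_iter=100000).fit(Z, y)
        assert np.allclose(beta, ref.coef_, atol=1e-6)
        assert np.isclose(beta0, ref.intercept_, atol=1e-6)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            lasso_fit(rng.normal(0, 1, (10, 2)), rng.normal(0, 1, 10), -0.1)


class TestSelectLambda:
    def test_noiseless_single_predictor_kept(self, rng):
        Z = rng.normal(0, 1, (40, 4))
        y = 3.0 * Z[:, 1]
        lam = select_lambda(Z, y, FoldScheme(40, 5, 0))
        _, beta = lasso_fit(Z, y, lam)
        assert beta[1] != 0.0

    def test_pure_noise_selects_sparse_models(self):
        """y independent of Z: the CV-chosen penalty keeps at most one
        spurious member in >= 80% of seeds."""
        sparse = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Z = rng.normal(0, 1, (200, 5))
            y = rng.normal(0, 1, 200)
            lam = select_lambda(Z, y, FoldScheme(200, 5, 0))
            _, beta = lasso_fit(Z, y, lam)
            sparse += int(np.count_nonzero(beta) <= 1)
        assert sparse >= 16

    def test_duplicated_columns_cv_curve_matches_merged(self, rng):
        """Duplicating a column is equivalent (for CV MSE) to the merged
        3-column problem: brute-force comparison of the CV curves."""
        n = 30
        Z3 = rng.normal(0, 1, (n, 3))
        Z3 = (Z3 - Z3.mean(axis=0)) / Z3.std(axis=0)
        y = Z3 @ np.array([1.0, -0.5, 0.0]) + rng.normal(0, 0.3, n)
        Z4 = np.column_stack([Z3, Z3[:, 0]])  # duplicate first column
        folds = FoldScheme(n, 5, 0)
        lmax = lambda_max(Z3, y)
        grid = np.geomspace(lmax, lmax * 1e-2, 12)
        for lam in grid:
            for held in folds.folds():
                tr = np.setdiff1d(np.arange(n), held)
                b0_3, b3 = lasso_fit(Z3[tr], y[tr], lam)
                # duplicated problem: split the first coefficient evenly
                b0_4, b4 = lasso_fit(Z4[tr], y[tr], lam)
                pred3 = b0_3 + Z3[held] @ b3
                pred4 = b0_4 + Z4[held] @ b4
                assert np.allclose(pred3, pred4, atol=1e-4)
                assert np.isclose(b3[0], b4[0] + b4[3], atol=1e-4)


class TestFusion:
    def test_single_division_fusion_is_plain_pls(self, small_dataset):
        folds = FoldScheme(small_dataset.n_samples, 5, 0)
        fm = fit_ipls_lasso(small_dataset, 1, folds)
        _, lv = cross_validate_lv(small_dataset.X, small_dataset.y, 18, folds)
        full = fit_pls(small_dataset.X, small_dataset.y, lv)
        assert np.array_equal(
            fm.predict(small_dataset.X), full.predict(small_dataset.X)
        )
        assert fm.selected == [1] and fm.label == "1/1"

    def test_planted_support_recovered(self):
        ds = plant_interval_signal(500, 10, (3, 7), 100, seed=4, noise_sd=0.3)
        fm = fit_ipls_lasso(ds, 10)
        assert {3, 7} <= set(fm.selected)

    def test_report_label_format(self):
        ds = plant_interval_signal(260, 26, (5,), 60, seed=1, noise_sd=0.2)
        fm = fit_ipls_lasso(ds, 26)
        k = len(fm.selected)
        assert fm.label == f"{k}/26"

    def test_selection_reproducible(self):
        ds = plant_interval_signal(200, 8, (2, 6), 70, seed=9)
        folds = FoldScheme(70, 5, 3)
        a = fit_ipls_lasso(ds, 8, folds)
        b = fit_ipls_lasso(ds, 8, folds)
        assert a.selected == b.selected
        assert np.array_equal(a.beta, b.beta)

    def test_fusion_affine_in_scale(self):
        """Scaling y (and hence member outputs) by c scales refit fusion
        predictions and bias by c."""
        ds = plant_interval_signal(120, 4, (2,), 60, seed=5)
        folds = FoldScheme(60, 5, 0)
        fm1 = fit_ipls_lasso(ds, 4, folds)
        c = 3.0
        ds2 = SpectralDataset(wavelengths=ds.wavelengths, X=ds.X.copy(),
                              y=c * ds.y, sample_ids=list(ds.sample_ids))
        fm2 = fit_ipls_lasso(ds2, 4, folds)
        assert np.allclose(fm2.predict(ds.X), c * fm1.predict(ds.X), atol=1e-6)


@pytest.fixture(scope="module")
def sweep_setup():
    ds = plant_interval_signal(180, 6, (4,), 90, seed=11, noise_sd=0.4)
    cal, pred = ds.take(range(60)), ds.take(range(60, 90))
    folds = FoldScheme(60, 5, 0)
    sweep = sweep_divisions(cal, pred, n_max=6, folds=folds)
    return cal, pred, folds, sweep


class TestSweep:
    def test_first_row_equals_plain_pls_metrics(self, sweep_setup):
        cal, pred, folds, sweep = sweep_setup
        _, lv = cross_validate_lv(cal.X, cal.y, 20, folds)
        model = fit_pls(cal.X, cal.y, lv)
        cv = cv_predictions(cal.X, cal.y, lv, folds)
        row = sweep.table.iloc[0]
        assert np.isclose(row["rmsecv"], np.sqrt(np.mean((cv - cal.y) ** 2)))
        assert np.isclose(
            row["rmsep"],
            np.sqrt(np.mean((model.predict(pred.X) - pred.y) ** 2)),
        )

    def test_table_covers_all_divisions(self, sweep_setup):
        *_, sweep = sweep_setup
        assert list(sweep.table["n"]) == list(range(1, 7))

    def test_best_n_respects_rmsecv_margin(self, sweep_setup):
        *_, sweep = sweep_setup
        t = sweep.table
        near = t[t["rmsecv"] <= t["rmsecv"].min() * 1.05]
        assert sweep.best_n in set(near["n"])
        assert t.loc[t["n"] == sweep.best_n, "rmsep"].iloc[0] == near["rmsep"].min()


class TestComparators:
    def test_s1_with_all_intervals_is_full_spectrum_pls(self, small_dataset):
        folds = FoldScheme(small_dataset.n_samples, 5, 0)
        cal = small_dataset.take(range(14))
        pred = small_dataset.take(range(14, 20))
        folds = FoldScheme(14, 5, 0)
        fm = fit_ipls_lasso(cal, 3, folds)
        fm.selected = [1, 2, 3]  # force full selection
        m_cal, m_pred = fit_pls_s1(cal, pred, fm, folds)
        _, lv = cross_validate_lv(cal.X, cal.y, 12, folds)
        full = fit_pls(cal.X, cal.y, lv)
        cv = cv_predictions(cal.X, cal.y, lv, folds)
        assert np.isclose(m_cal.rmse, np.sqrt(np.mean((cv - cal.y) ** 2)))
        assert np.isclose(
            m_pred.rmse,
            np.sqrt(np.mean((full.predict(pred.X) - pred.y) ** 2)),
        )

    def test_s1_single_interval_equals_that_ipls_member(self):
        ds = plant_interval_signal(90, 3, (2,), 60, seed=6)
        cal, pred = ds.take(range(40)), ds.take(range(40, 60))
        folds = FoldScheme(40, 5, 0)
        fm = fit_ipls_lasso(cal, 3, folds)
        fm.selected = [2]
        _, m_pred = fit_pls_s1(cal, pred, fm, folds)
        ims = fit_ipls(cal, 3, folds)
        member_pred = predict_members(ims, pred.X)[:, 1]
        expected = np.sqrt(np.mean((member_pred - pred.y) ** 2))
        assert np.isclose(m_pred.rmse, expected)

    def test_s1_empty_selection_rejected(self, small_dataset):
        fm = fit_ipls_lasso(small_dataset, 2)
        fm.selected = []
        with pytest.raises(ValueError, match="selected"):
            fit_pls_s1(small_dataset, small_dataset, fm)

    def test_s2_single_member_is_affine_recalibration_of_pls(self):
        """With one member the stack is an affine recalibration of the plain
        PLS output: prediction-stage r is identical, calibration RMSE can
        only improve (OLS optimality)."""
        ds = plant_interval_signal(80, 4, (2,), 75, seed=8)
        cal, pred = ds.take(range(50)), ds.take(range(50, 75))
        folds = FoldScheme(50, 5, 0)
        ims = fit_ipls(cal, 1, folds)
        m_cal, m_pred = fit_pls_s2(cal, pred, ims)
        _, lv = cross_validate_lv(cal.X, cal.y, 20, folds)
        model = fit_pls(cal.X, cal.y, lv)
        from eggfresh import evaluate

        m_pls = evaluate(pred.y, model.predict(pred.X))
        assert np.isclose(abs(m_pred.r), abs(m_pls.r), atol=1e-12)
        cv = cv_predictions(cal.X, cal.y, lv, folds)
        assert m_cal.rmse <= np.sqrt(np.mean((cv - cal.y) ** 2)) + 1e-12

    def test_s2_duplicated_members_minimum_norm_deterministic(self):
        """Duplicated interval columns give duplicated members; the stack is
        rank-deficient but the minimum-norm fit leaves predictions equal to
        the deduplicated stack."""
        rng = np.random.default_rng(3)
        half = rng.normal(0, 1, (60, 30))
        X = np.hstack([half, half])  # interval 2 duplicates interval 1
        y = half[:, :5] @ np.ones(5) + rng.normal(0, 0.3, 60)
        ds = SpectralDataset(wavelengths=np.arange(60.0), X=X, y=y)
        cal, pred = ds.take(range(40)), ds.take(range(40, 60))
        folds = FoldScheme(40, 5, 0)
        ims = fit_ipls(cal, 2, folds)
        with pytest.warns(UserWarning, match="rank-deficient"):
            m_cal, m_pred = fit_pls_s2(cal, pred, ims)
        # oracle: OLS on the single distinct member column
        Z = np.column_stack([np.ones(40), ims.cv_outputs[:, :1]])
        coef = np.linalg.lstsq(Z, cal.y, rcond=None)[0]
        fit = Z @ coef
        assert np.isclose(m_cal.rmse, np.sqrt(np.mean((fit - cal.y) ** 2)),
                          atol=1e-8)
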