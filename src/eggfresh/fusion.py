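"""Lasso selection-and-fusion of iPLS member models, plus stacked comparators.

The fusion regression treats the cross-validated outputs of the n interval
members as predictors of the reference Haugh units and solves

    min_{b0, b}  (1/2N) * sum_i (y_i - b0 - sum_j z_ij b_j)^2 + lambda * sum_j |b_j|

by cyclic coordinate descent on centred, unit-variance-scaled member outputs,
with the intercept unpenalised and coefficients mapped back to the original
HU scale.  (The same optimum under the unscaled residual-sum-of-squares
objective corresponds to lambda_ssr = 2N * lambda.)  Members whose
coefficient is driven exactly to zero are discarded; the survivors define
the selected spectral intervals.

``sweep_divisions`` runs the whole protocol over division counts 1..n_max;
``fit_pls_s1`` / ``fit_pls_s2`` are the two reference comparators (PLS on
the concatenated selected intervals, and an unpenalised least-squares stack
of all members).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .ipls import IntervalModelSet, fit_ipls, predict_members
from .pls import (
    FoldScheme,
    Metrics,
    cross_validate_lv,
    cv_predictions,
    evaluate,
    fit_pls,
    max_latent_variables,
)
from .spectra_io import SpectralDataset

_TOL = 1e-7
# nearly collinear member outputs (pairwise correlations > 0.99 are routine
# for adjacent spectral intervals) make cyclic descent zig-zag at the small
# end of the penalty grid; the cap must accommodate that
_MAX_SWEEPS = 2_000_000
_ZERO_COEF = 1e-10  # back-scaled coefficients below this count as discarded


class ConvergenceError(RuntimeError):
    pass


def _standardize(Z: np.ndarray):
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)  # population SD so standardized columns have z'z = N
    ok = sd > 0
    Zs = np.zeros_like(Z)
    Zs[:, ok] = (Z[:, ok] - mean[ok]) / sd[ok]
    return Zs, mean, sd, ok


def _cd_gram_kernel(G, c, diag, b, mask, lam, tol, max_sweeps):
    """Cyclic soft-thresholding in covariance form.

    G = Z'Z/N, c = Z'y/N; maintaining q = G b makes each coordinate update
    O(m) instead of O(N), and the whole penalty path cheap.  Returns the
    number of sweeps used (max_sweeps means no convergence).
    """
    m = b.size
    q = G @ b
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(m):
            if not mask[j]:
                continue
            rho = c[j] - q[j] + diag[j] * b[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / diag[j]
            delta = new - b[j]
            if delta != 0.0:
                for k in range(m):
                    q[k] += G[k, j] * delta
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
                b[j] = new
        if max_delta < tol:
            return sweep + 1
    return max_sweeps


try:  # the jitted kernel is a pure speed-up; the math is identical
    from numba import njit

    _cd_gram_kernel = njit(cache=True)(_cd_gram_kernel)
except ImportError:  # pragma: no cover
    pass


def _coordinate_descent(
    Zs: np.ndarray, yc: np.ndarray, lam: float, columns: np.ndarray,
    b_init: np.ndarray | None = None,
    gram: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Cyclic soft-thresholding on standardized columns (z'z = N).

    Supports warm starts, which make a descending penalty path cheap
    (each solution seeds the next, as in glmnet).  ``gram`` can pass a
    precomputed (G, c) pair for path fits.
    """
    N, m = Zs.shape
    if gram is None:
        G = Zs.T @ Zs / N
        c = Zs.T @ yc / N
    else:
        G, c = gram
    b = np.zeros(m) if b_init is None else b_init.copy()
    mask = np.zeros(m, dtype=np.bool_)
    mask[columns] = True
    diag = np.where(np.diag(G) > 0, np.diag(G), 1.0)
    sweeps = _cd_gram_kernel(G, c, diag, b, mask, lam, _TOL, _MAX_SWEEPS)
    if sweeps >= _MAX_SWEEPS:
        raise ConvergenceError(
            f"coordinate descent did not converge in {_MAX_SWEEPS} sweeps"
        )
    return b


def lasso_fit(
    Z: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Solve the Lasso at one penalty; returns (intercept, coefficients).

    Coordinate descent with soft-thresholding on standardized columns;
    converged when the largest coefficient change in a sweep is below 1e-7.
    Zero-variance columns get coefficient 0.  Coefficients are returned on
    the original scale of ``Z`` and ``y``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite member outputs")
    Zs, mean, sd, ok = _standardize(Z)
    b = _coordinate_descent(Zs, y - y.mean(), lam, np.flatnonzero(ok))
    beta = np.zeros(Z.shape[1])
    beta[ok] = b[ok] / sd[ok]
    beta[np.abs(beta) < _ZERO_COEF] = 0.0
    beta0 = float(y.mean() - mean @ beta)
    return beta0, beta


def lambda_max(Z: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    Zs, _, _, _ = _standardize(Z)
    yc = y - y.mean()
    return float(np.max(np.abs(Zs.T @ yc)) / Z.shape[0])


def select_lambda(
    Z: np.ndarray,
    y: np.ndarray,
    folds: FoldScheme | None = None,
    n_grid: int = 100,
    eps: float = 1e-4,
) -> float:
    """Pick the penalty by k-fold cross-validated mean squared error.

    The grid is ``n_grid`` log-spaced values from lambda_max down to
    lambda_max * eps; the minimiser of the mean out-of-fold MSE wins, with
    ties going to the larger (sparser) penalty.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    N = Z.shape[0]
    folds = folds or FoldScheme(N)
    lmax = lambda_max(Z, y)
    if lmax == 0:  # y constant or members uninformative: any penalty works
        return 0.0
    grid = np.geomspace(lmax, lmax * eps, n_grid)
    mse = np.zeros(n_grid)
    for held in folds.folds():
        train = np.setdiff1d(np.arange(N), held)
        Zt, yt = Z[train], y[train]
        Zh, yh = Z[held], y[held]
        Zs, mean, sd, ok = _standardize(Zt)
        cols = np.flatnonzero(ok)
        yt_mean = yt.mean()
        yc = yt - yt_mean
        gram = (Zs.T @ Zs / len(yt), Zs.T @ yc / len(yt))
        b = None
        for i, lam in enumerate(grid):  # descending path, warm-started
            b = _coordinate_descent(Zs, yc, lam, cols, b, gram)
            beta = np.zeros(Z.shape[1])
            beta[ok] = b[ok] / sd[ok]
            beta0 = yt_mean - mean @ beta
            pred = beta0 + Zh @ beta
            mse[i] += np.sum((pred - yh) ** 2)
    mse /= N
    return float(grid[int(np.argmin(mse))])  # first hit = largest lambda


@dataclass
class FusionModel:
    """Lasso fusion over one division's member models.

    ``selected`` lists the surviving intervals 1-based; ``label`` renders
    the report form, e.g. '10/26' when 10 of 26 members survive.
    """

    n: int
    beta0: float
    beta: np.ndarray
    lam: float
    selected: list[int]
    members: IntervalModelSet

    @property
    def label(self) -> str:
        return f"{len(self.selected)}/{self.n}"

    def predict_from_member_outputs(self, Z: np.ndarray) -> np.ndarray:
        return self.beta0 + np.atleast_2d(Z) @ self.beta

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict HU for raw spectra via the members then the fusion."""
        return self.predict_from_member_outputs(
            predict_members(self.members, X)
        )


def fit_ipls_lasso(
    cal: SpectralDataset,
    n: int,
    folds: FoldScheme | None = None,
    max_lv: int = 20,
    members: IntervalModelSet | None = None,
) -> FusionModel:
    """Build members for an n-way division and fuse them with the Lasso.

    The member cross-validated outputs form the design matrix Z; the penalty
    is chosen by 5-fold CV and the final Lasso refit on all calibration
    rows.  A 1-way division has a single member — the full-spectrum PLS —
    which passes through unchanged (identity fusion), so the n = 1 fusion
    model *is* the plain PLS model.
    """
    if cal.y is None:
        raise ValueError("calibration set has no reference values")
    folds = folds or FoldScheme(cal.n_samples)
    ims = members if members is not None else fit_ipls(cal, n, folds, max_lv)
    if n == 1:
        return FusionModel(
            n=1, beta0=0.0, beta=np.ones(1), lam=0.0, selected=[1], members=ims
        )
    Z = ims.cv_outputs
    lam = select_lambda(Z, cal.y, folds)
    beta0, beta = lasso_fit(Z, cal.y, lam)
    selected = [int(j) + 1 for j in np.flatnonzero(beta != 0)]
    return FusionModel(
        n=n, beta0=beta0, beta=beta, lam=lam, selected=selected, members=ims
    )


@dataclass
class SweepResult:
    """Tidy per-division metrics table plus the chosen division count."""

    table: pd.DataFrame  # one row per division n = 1..n_max
    best_n: int
    models: dict[int, FusionModel]


def sweep_divisions(
    cal: SpectralDataset,
    pred: SpectralDataset,
    n_max: int = 40,
    folds: FoldScheme | None = None,
    max_lv: int = 20,
    rmsecv_margin: float = 0.05,
    keep_models: bool = True,
) -> SweepResult:
    """Fit the Lasso fusion for every division count 1..n_max.

    Per division: RMSECV/r from the fusion applied to the member CV outputs,
    RMSEP/r/bias from the fusion applied to prediction-set member outputs.
    The reported ``best_n`` minimises RMSEP among the divisions whose RMSECV
    is within ``rmsecv_margin`` (relative) of the global minimum — a guard
    against divisions that cross-validate well but overfit at prediction.
    """
    if not np.array_equal(cal.wavelengths, pred.wavelengths):
        raise ValueError("calibration and prediction sets have different axes")
    folds = folds or FoldScheme(cal.n_samples)
    rows = []
    models: dict[int, FusionModel] = {}
    for n in range(1, n_max + 1):
        fm = fit_ipls_lasso(cal, n, folds, max_lv)
        cv_pred = fm.predict_from_member_outputs(fm.members.cv_outputs)
        m_cv = evaluate(cal.y, cv_pred)
        p_pred = fm.predict(pred.X)
        m_p = evaluate(pred.y, p_pred)
        rows.append(
            {
                "n": n,
                "rmsecv": m_cv.rmse,
                "r_cv": m_cv.r,
                "bias_cv": m_cv.bias,
                "rmsep": m_p.rmse,
                "r_p": m_p.r,
                "bias_p": m_p.bias,
                "n_selected": len(fm.selected),
                "selected_list": ";".join(map(str, fm.selected)),
                "lambda": fm.lam,
            }
        )
        if keep_models:
            models[n] = fm
    table = pd.DataFrame(rows)
    cv_min = table["rmsecv"].min()
    near = table[table["rmsecv"] <= cv_min * (1 + rmsecv_margin)]
    best_n = int(near.loc[near["rmsep"].idxmin(), "n"])
    return SweepResult(table=table, best_n=best_n, models=models)


def fit_pls_s1(
    cal: SpectralDataset,
    pred: SpectralDataset,
    fusion: FusionModel,
    folds: FoldScheme | None = None,
    max_lv: int = 20,
) -> tuple[Metrics, Metrics]:
    """PLS on the concatenation of the fusion-selected intervals.

    Equivalent to a synergy-interval PLS on the selected combination but
    without searching over combinations.  Returns (calibration, prediction)
    metrics; the calibration entry is cross-validated (RMSECV).
    """
    if not fusion.selected:
        raise ValueError("fusion model selected no intervals")
    division = fusion.members.division
    cols = np.concatenate(
        [division.columns(j - 1) for j in sorted(fusion.selected)]
    )
    folds = folds or FoldScheme(cal.n_samples)
    Xc = cal.X[:, cols]
    cap = max_latent_variables(cols.size, cal.n_samples, max_lv)
    _, lv = cross_validate_lv(Xc, cal.y, max_lv=cap, folds=folds)
    model = fit_pls(Xc, cal.y, lv, column_index=cols)
    cv_out = cv_predictions(Xc, cal.y, lv, folds)
    m_cal = evaluate(cal.y, cv_out)
    m_pred = evaluate(pred.y, model.predict(pred.X[:, cols]))
    return m_cal, m_pred


def fit_pls_s2(
    cal: SpectralDataset,
    pred: SpectralDataset,
    ims: IntervalModelSet,
) -> tuple[Metrics, Metrics]:
    """Unpenalised least-squares stack of all members (OLS on cv_outputs).

    The minimum-norm solution is used if the stack is rank deficient (a
    warning is emitted).  Returns (calibration, prediction) metrics, the
    prediction stage using prediction-set member outputs.
    """
    Z = np.column_stack([np.ones(ims.cv_outputs.shape[0]), ims.cv_outputs])
    coef, _, rank, _ = np.linalg.lstsq(Z, _require_y(cal), rcond=None)
    if rank < Z.shape[1]:
        warnings.warn(
            "rank-deficient member stack; using minimum-norm coefficients",
            stacklevel=2,
        )
    cv_fit = Z @ coef
    m_cal = evaluate(cal.y, cv_fit)
    Zp = np.column_stack(
        [np.ones(pred.n_samples), predict_members(ims, pred.X)]
    )
    m_pred = evaluate(pred.y, Zp @ coef)
    return m_cal, m_pred


def _require_y(ds: SpectralDataset) -> np.ndarray:
    if ds.y is None:
        raise ValueError("dataset has no reference values")
    return ds.y
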