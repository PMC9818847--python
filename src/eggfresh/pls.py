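"""PLS1 regression (NIPALS) with cross-validated latent-variable selection.

The model is the classical mean-centred single-response NIPALS recursion:
weights w_k = X'y / ||X'y||, scores t_k = X w_k, loadings p_k = X't_k/t't,
y-loadings q_k = y't_k/t't, then deflation of X and y.  The regression
vector in the original wavelength space is B = W (P'W)^-1 q, so prediction
is (x - x_mean) . B + y_mean.

Model complexity (the number of latent variables) is selected by k-fold
cross-validation at the minimum RMSECV, with ties broken toward the
smallest count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FoldScheme:
    """Deterministic k-fold assignment: seeded shuffle, then venetian blind.

    After one seeded permutation of the sample order, fold ``f`` holds every
    ``n_folds``-th sample.  Every sample is held out exactly once.
    """

    n_samples: int
    n_folds: int = 5
    seed: int = 0

    def folds(self) -> list[np.ndarray]:
        if self.n_folds < 2 or self.n_folds > self.n_samples:
            raise ValueError(
                f"cannot make {self.n_folds} folds from {self.n_samples} samples"
            )
        perm = np.random.default_rng(self.seed).permutation(self.n_samples)
        return [np.sort(perm[f :: self.n_folds]) for f in range(self.n_folds)]


@dataclass
class PLSModel:
    """Fitted PLS1 model restricted to ``column_index`` of the full matrix."""

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray          # (p, k) weights
    P: np.ndarray          # (p, k) x-loadings
    q: np.ndarray          # (k,) y-loadings
    B: np.ndarray          # (p,) regression vector, original column space
    n_lv: int
    column_index: np.ndarray | None = None  # None = all columns

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.column_index is not None:
            if X.shape[1] == self.column_index.size:
                pass  # already restricted
            else:
                X = X[:, self.column_index]
        if X.shape[1] != self.B.size:
            raise ValueError(
                f"expected {self.B.size} columns, got {X.shape[1]}"
            )
        return (X - self.x_mean) @ self.B + self.y_mean


@dataclass
class Metrics:
    """RMSE / Pearson r / bias for one model at one stage, in HU units."""

    rmse: float
    r: float
    bias: float

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r": self.r, "bias": self.bias}


def max_latent_variables(n_cols: int, n_rows: int, cap: int = 20) -> int:
    """Complexity ceiling: min(cap, columns, rows - 2)."""
    return max(1, min(cap, n_cols, n_rows - 2))


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Run the PLS1 deflation; returns (W, P, q, k_effective).

    Stops early if X is deflated to numerical zero; trailing components then
    contribute nothing (q = 0), keeping predictions well-defined at any
    requested complexity.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    y = yc.copy()
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc)
    for k in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-13 * (scale + 1e-300):
            return W, P, q, k
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= 0:
            return W, P, q, k
        pk = X.T @ t / tt
        qk = (y @ t) / tt
        X = X - np.outer(t, pk)
        y = y - qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk
    return W, P, q, n_lv


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    column_index: np.ndarray | None = None,
) -> PLSModel:
    """Fit a mean-centred PLS1 model with ``n_lv`` latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match X rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance y: nothing to regress")
    if not 1 <= n_lv <= min(20, p, n - 1):
        raise ValueError(
            f"n_lv={n_lv} outside [1, {min(20, p, n - 1)}] for {n}x{p} data"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, k = _nipals(X - x_mean, y - y_mean, n_lv)
    B = _regression_vector(W, P, q, k)
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q, B=B, n_lv=n_lv,
        column_index=None if column_index is None
        else np.asarray(column_index, dtype=int),
    )


def _regression_vector(W, P, q, k) -> np.ndarray:
    if k == 0:
        return np.zeros(W.shape[0])
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Apply centring and the regression vector; no refitting."""
    return model.predict(X)


def _predictions_per_lv(
    X_train, y_train, X_test, max_lv: int
) -> np.ndarray:
    """Test-set predictions for every LV count 1..max_lv from one fit.

    Returns an (n_test, max_lv) matrix; column k-1 is the k-component
    prediction.  One deflation pass serves all complexities.
    """
    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    W, P, q, k_eff = _nipals(X_train - x_mean, y_train - y_mean, max_lv)
    out = np.empty((X_test.shape[0], max_lv))
    Xt = np.atleast_2d(X_test) - x_mean
    # scores of new samples via the deflation recursion
    T = np.empty((Xt.shape[0], max_lv))
    Xd = Xt.copy()
    for k in range(k_eff):
        t = Xd @ W[:, k]
        T[:, k] = t
        Xd -= np.outer(t, P[:, k])
    pred = np.full(Xt.shape[0], y_mean)
    for k in range(max_lv):
        if k < k_eff:
            pred = pred + q[k] * T[:, k]
        out[:, k] = pred
    return out


def cross_validate_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 20,
    folds: FoldScheme | None = None,
) -> tuple[np.ndarray, int]:
    """RMSECV for each LV count 1..max_lv and the selected count.

    Out-of-fold predictions are assembled over all folds, RMSECV computed per
    complexity, and the minimum chosen; ties go to the smaller (more
    parsimonious) count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    folds = folds or FoldScheme(n)
    max_lv = min(max_lv, p)
    fold_sets = folds.folds()
    lv_bound = max_lv
    for held in fold_sets:
        n_train = n - held.size
        if n_train < 2:
            raise ValueError("a fold leaves fewer than 2 training samples")
        lv_bound = min(lv_bound, n_train - 1)
    max_lv = max(1, lv_bound)
    cv_pred = np.empty((n, max_lv))
    for held in fold_sets:
        train = np.setdiff1d(np.arange(n), held)
        cv_pred[held] = _predictions_per_lv(
            X[train], y[train], X[held], max_lv
        )
    rmsecv = np.sqrt(np.mean((cv_pred - y[:, None]) ** 2, axis=0))
    selected = int(np.argmin(rmsecv)) + 1  # argmin returns first = smallest LV
    return rmsecv, selected


def cv_predictions(
    X: np.ndarray, y: np.ndarray, n_lv: int, folds: FoldScheme
) -> np.ndarray:
    """Out-of-fold predictions at a fixed complexity (fold models refit)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    out = np.empty(n)
    for held in folds.folds():
        train = np.setdiff1d(np.arange(n), held)
        lv = min(n_lv, train.size - 1)
        out[held] = _predictions_per_lv(X[train], y[train], X[held], lv)[:, -1]
    return out


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """RMSE, Pearson r and bias of predictions against reference values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return Metrics(rmse=rmse, r=r, bias=bias)
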