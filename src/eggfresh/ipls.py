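"""Interval PLS: equal-width spectral intervals, one PLS member per interval.

The full axis of p variables is divided into n contiguous intervals whose
widths differ by at most one (the first p mod n intervals take the extra
variable).  A PLS model is fitted per interval with its own cross-validated
latent-variable count; members are ranked by RMSECV and the best interval is
reported 1-based, "k/n" style.  The members' out-of-fold predictions
(``cv_outputs``) are what the Lasso fusion stage consumes — never in-sample
fits, to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import (
    FoldScheme,
    PLSModel,
    cross_validate_lv,
    cv_predictions,
    fit_pls,
    max_latent_variables,
)
from .spectra_io import SpectralDataset


@dataclass(frozen=True)
class IntervalDivision:
    """Partition of column indices 0..p-1 into n contiguous blocks."""

    p: int
    n: int
    bounds: tuple[tuple[int, int], ...]  # half-open (start, end), 0-based

    def columns(self, j: int) -> np.ndarray:
        """Column indices of interval j (0-based)."""
        start, end = self.bounds[j]
        return np.arange(start, end)

    def widths(self) -> list[int]:
        return [end - start for start, end in self.bounds]

    def label(self, j: int) -> str:
        """1-based report label, e.g. '4/6' for the 4th of 6 intervals."""
        return f"{j + 1}/{self.n}"


def divide_intervals(p: int, n: int) -> IntervalDivision:
    """Divide ``p`` variables into ``n`` equal-width contiguous intervals.

    Base width is floor(p/n); the first ``p mod n`` intervals receive one
    extra variable.  E.g. 2041 variables in 6 intervals give widths
    341, 340, 340, 340, 340, 340.
    """
    if n < 1 or n > p:
        raise ValueError(f"cannot divide {p} variables into {n} intervals")
    base, extra = divmod(p, n)
    bounds = []
    start = 0
    for j in range(n):
        width = base + (1 if j < extra else 0)
        bounds.append((start, start + width))
        start += width
    return IntervalDivision(p=p, n=n, bounds=tuple(bounds))


@dataclass
class IntervalModelSet:
    """All member models for one division, with their CV diagnostics.

    ``cv_outputs[:, j]`` holds the out-of-fold predictions of member j on the
    calibration samples, produced exclusively from interval j's columns.
    ``best_index`` is 0-based internally; use ``best_label`` for reports.
    """

    division: IntervalDivision
    models: list[PLSModel]
    rmsecv: np.ndarray
    cv_outputs: np.ndarray
    best_index: int

    @property
    def best_label(self) -> str:
        return self.division.label(self.best_index)


def fit_ipls(
    cal: SpectralDataset,
    n: int,
    folds: FoldScheme | None = None,
    max_lv: int = 20,
) -> IntervalModelSet:
    """Fit one PLS member per interval of an ``n``-way division.

    Per interval, the latent-variable count is selected by cross-validation
    on that interval's columns, the final member is refit on the whole
    calibration set, and the out-of-fold predictions at the selected count
    (fold models refit) are stored for the fusion stage.  With ``n = 1``
    this reduces exactly to the full-spectrum PLS model.
    """
    if cal.y is None:
        raise ValueError("calibration set has no reference values")
    X, y = cal.X, cal.y
    n_samples, p = X.shape
    division = divide_intervals(p, n)
    folds = folds or FoldScheme(n_samples)
    models: list[PLSModel] = []
    rmsecv = np.empty(n)
    cv_outputs = np.empty((n_samples, n))
    for j in range(n):
        cols = division.columns(j)
        # a whole-axis interval reuses X itself, so the n=1 model is
        # bit-identical to the plain full-spectrum PLS
        Xj = X if cols.size == p else X[:, cols]
        cap = max_latent_variables(cols.size, n_samples, max_lv)
        _, lv = cross_validate_lv(Xj, y, max_lv=cap, folds=folds)
        model = fit_pls(Xj, y, lv, column_index=cols)
        cv_out = cv_predictions(Xj, y, lv, folds)
        models.append(model)
        cv_outputs[:, j] = cv_out
        rmsecv[j] = np.sqrt(np.mean((cv_out - y) ** 2))
    best = int(np.argmin(rmsecv))
    return IntervalModelSet(
        division=division,
        models=models,
        rmsecv=rmsecv,
        cv_outputs=cv_outputs,
        best_index=best,
    )


def predict_members(ims: IntervalModelSet, X: np.ndarray) -> np.ndarray:
    """Member predictions on new spectra: column j from interval j only."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ims.division.p:
        raise ValueError(
            f"expected {ims.division.p} columns, got {X.shape[1]}"
        )
    out = np.empty((X.shape[0], ims.division.n))
    for j, model in enumerate(ims.models):
        cols = ims.division.columns(j)
        Xj = X if cols.size == ims.division.p else X[:, cols]
        out[:, j] = model.predict(Xj)
    return out
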