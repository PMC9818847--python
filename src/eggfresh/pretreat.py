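"""Spectral pretreatments: SNV, MSC and Savitzky-Golay first derivative.

All three operate row-wise on a samples x wavelengths matrix and return a
matrix of the same shape; none of them needs the wavelength axis (the
derivative is taken per index, with the axis assumed evenly spaced).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

#: Names accepted by :func:`apply_pretreatment`.
PRETREATMENTS = ("none", "snv", "msc", "d1st_sg")


def snv(X: np.ndarray, *, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to SD 1.

    Removes multiplicative and additive scatter per spectrum.  Uses the
    sample standard deviation (``ddof=1``) by convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0)
    if degenerate.size:
        raise ValueError(f"constant spectrum at row(s) {degenerate.tolist()}")
    return (X - mu) / sd


def msc(
    X: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference (OLS slope a, intercept b)
    and corrected to ``(row - b) / a``.  The reference defaults to the mean
    spectrum of ``X``.  Returns the corrected matrix and the reference used,
    so prediction-set spectra can be corrected against the calibration
    reference.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference length does not match spectrum length")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("constant reference spectrum")
    a = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.flatnonzero(np.abs(a) < 1e-12)
    if small.size:
        raise ValueError(f"non-correctable row(s) {small.tolist()}: slope ~ 0")
    b = X.mean(axis=1) - a * ref.mean()
    return (X - b[:, None]) / a[:, None], ref


def sg_first_derivative(
    X: np.ndarray, window: int = 5, degree: int = 2
) -> np.ndarray:
    """Savitzky-Golay first derivative per spectrum, in index units.

    Edges are handled by evaluating the boundary polynomial fits, so the
    column count is preserved.  Defaults: 5-point window, 2nd-degree
    polynomial.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0 or window <= degree:
        raise ValueError(
            f"window ({window}) must be odd and greater than degree ({degree})"
        )
    if X.shape[1] < window:
        raise ValueError(f"need at least {window} columns, got {X.shape[1]}")
    return savgol_filter(
        X, window_length=window, polyorder=degree, deriv=1, delta=1.0,
        axis=1, mode="interp",
    )


def apply_pretreatment(
    X: np.ndarray, method: str, *, msc_reference: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Apply a named pretreatment; returns the matrix and fit state.

    The state dict carries whatever a later prediction-set transform needs
    (currently only the MSC reference spectrum).
    """
    if method == "none":
        return np.atleast_2d(np.asarray(X, float)), {}
    if method == "snv":
        return snv(X), {}
    if method == "msc":
        corrected, ref = msc(X, msc_reference)
        return corrected, {"msc_reference": ref}
    if method == "d1st_sg":
        return sg_first_derivative(X), {}
    raise ValueError(f"unknown pretreatment {method!r}; choose from {PRETREATMENTS}")
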