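"""Spectral dataset container and I/O.

Datasets are plain CSV matrices: the first header cell is ``id``, the rest
of the header row is the wavelength axis in nm, and every subsequent row is
a sample id followed by transmittance values (%T).  Reference Haugh units
and per-egg metadata travel in a companion CSV keyed by sample id.

Besides reading and writing, this module owns the sample-level bookkeeping
that happens before any modelling: cropping the unreliable ends of the
detector axis, averaging replicate scans of the same egg, flagging outlying
samples, and the random calibration/prediction split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV violates the matrix dialect."""


class WavelengthAxisError(ValueError):
    """Raised when a wavelength axis is not strictly increasing or empty."""


@dataclass
class SpectralDataset:
    """A spectral matrix with its wavelength axis and per-sample reference data.

    Parameters
    ----------
    wavelengths : (p,) array
        Strictly increasing axis in nm.
    X : (n, p) array
        Transmittance values (%T), one row per sample.
    y : (n,) array or None
        Reference values (Haugh units) aligned with rows of ``X``.
    sample_ids : list of str
        Row labels, unique.
    meta : DataFrame or None
        Optional per-sample table (storage day, weight, replicate ...)
        indexed like ``sample_ids``.
    """

    wavelengths: np.ndarray
    X: np.ndarray
    y: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.wavelengths.ndim != 1:
            raise WavelengthAxisError("wavelength axis must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise WavelengthAxisError("wavelength axis must be strictly increasing")
        if self.X.shape[1] != self.wavelengths.size:
            raise SpectraFormatError(
                f"X has {self.X.shape[1]} columns but axis has "
                f"{self.wavelengths.size} wavelengths"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.X.shape[0])]
        if len(self.sample_ids) != self.X.shape[0]:
            raise SpectraFormatError("sample_ids length does not match X rows")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.X.shape[0],):
                raise SpectraFormatError("y length does not match X rows")
            if not np.all(np.isfinite(self.y)):
                raise SpectraFormatError("non-finite reference values")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise SpectraFormatError(
                f"non-finite spectral value at sample {self.sample_ids[bad[0]]}, "
                f"column {bad[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def take(self, indices: Sequence[int]) -> "SpectralDataset":
        """Row-subset the dataset, keeping y and meta aligned."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            wavelengths=self.wavelengths,
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            meta=None if self.meta is None else self.meta.iloc[idx].copy(),
        )


@dataclass
class SplitResult:
    """Calibration/prediction partition plus the outliers removed before it."""

    calibration: SpectralDataset
    prediction: SpectralDataset
    outlier_ids: list[str] = field(default_factory=list)


def read_spectra(
    path, ref_path=None, *, y_column: str = "HU"
) -> SpectralDataset:
    """Read a spectra CSV (and optional reference CSV) into a dataset.

    The first header cell must be ``id``; the remaining header cells are the
    wavelength axis.  ``ref_path`` points at a CSV with an ``id`` column, a
    reference column (``HU`` by default) and any further metadata columns.
    """
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise SpectraFormatError(f"malformed spectra CSV {path}: {exc}") from exc
    try:
        wavelengths = df.columns.to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(
            f"non-numeric wavelength header in {path}: {exc}"
        ) from exc
    try:
        X = df.to_numpy(dtype=float)
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        X = coerced.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        i, j = bad[0]
        raise SpectraFormatError(
            f"missing or non-numeric value at row {df.index[i]!r}, "
            f"wavelength {df.columns[j]}"
        )
    sample_ids = [str(s) for s in df.index]
    y = None
    meta = None
    if ref_path is not None:
        ref = pd.read_csv(ref_path, dtype={"id": str}).set_index("id")
        missing = [s for s in sample_ids if s not in ref.index]
        if missing:
            raise SpectraFormatError(
                f"reference file lacks ids: {missing[:5]}"
            )
        ref = ref.loc[sample_ids]
        if y_column in ref.columns:
            y = ref[y_column].to_numpy(dtype=float)
            meta = ref.drop(columns=[y_column])
        else:
            meta = ref
        if meta.shape[1] == 0:
            meta = None
    return SpectralDataset(
        wavelengths=wavelengths, X=X, y=y, sample_ids=sample_ids, meta=meta
    )


def write_spectra(ds: SpectralDataset, path, ref_path=None, *,
                  y_column: str = "HU") -> None:
    """Write a dataset in the CSV matrix dialect (values round-trip exactly)."""
    df = pd.DataFrame(ds.X, index=pd.Index(ds.sample_ids, name="id"),
                      columns=[repr(float(w)) for w in ds.wavelengths])
    df.to_csv(path)
    if ref_path is not None:
        ref = ds.meta.copy() if ds.meta is not None else pd.DataFrame(
            index=pd.Index(ds.sample_ids, name="id"))
        ref.index = pd.Index(ds.sample_ids, name="id")
        if ds.y is not None:
            ref.insert(0, y_column, ds.y)
        ref.to_csv(ref_path)


def crop_wavelengths(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep only the columns with ``lo <= wavelength <= hi``.

    The ends of the detector axis are typically noisy; this is the standard
    way to discard them while keeping the interior untouched.
    """
    if lo >= hi:
        raise WavelengthAxisError(f"empty crop range [{lo}, {hi}]")
    keep = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not np.any(keep):
        raise WavelengthAxisError(
            f"no wavelengths inside [{lo}, {hi}] "
            f"(axis spans {ds.wavelengths[0]}..{ds.wavelengths[-1]})"
        )
    return replace(ds, wavelengths=ds.wavelengths[keep], X=ds.X[:, keep])


def average_replicates(ds: SpectralDataset, group_key: str = "egg") -> SpectralDataset:
    """Average replicate scans of the same physical sample.

    ``group_key`` names a metadata column; rows sharing its value are averaged
    into one spectrum.  Reference values must agree within a group (they
    describe the same egg) and are carried through.
    """
    if ds.meta is None or group_key not in ds.meta.columns:
        raise KeyError(f"metadata column {group_key!r} required for averaging")
    groups = ds.meta[group_key].to_numpy()
    order = pd.unique(groups)  # first-appearance order
    rows, ys, ids, meta_rows = [], [], [], []
    for g in order:
        mask = groups == g
        rows.append(ds.X[mask].mean(axis=0))
        if ds.y is not None:
            vals = ds.y[mask]
            if np.ptp(vals) > 1e-9:
                raise ValueError(
                    f"conflicting reference values within group {g!r}: {vals}"
                )
            ys.append(vals[0])
        ids.append(str(g))
        meta_rows.append(ds.meta[mask].iloc[0])
    meta = pd.DataFrame(meta_rows).reset_index(drop=True)
    meta.index = pd.Index(ids, name="id")
    meta = meta.drop(columns=[c for c in ("replicate",) if c in meta.columns])
    return SpectralDataset(
        wavelengths=ds.wavelengths,
        X=np.vstack(rows),
        y=np.asarray(ys) if ds.y is not None else None,
        sample_ids=ids,
        meta=meta,
    )


def detect_outliers(
    ds: SpectralDataset, alpha: float = 0.05, *, variance_kept: float = 0.99
) -> tuple[list[str], list[str]]:
    """Flag spectral and reference outliers at significance level ``alpha``.

    Spectral outliers: PCA scores retaining >= ``variance_kept`` of the
    variance, Mahalanobis distance against a chi-square cutoff at 1 - alpha.
    Reference outliers: two-sided z-score test on y at the same level.

    Returns ``(spectral_ids, reference_ids)``.  Deterministic given the data.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = ds.n_samples
    if n < 10:
        raise ValueError("outlier detection needs at least 10 samples")
    Xc = ds.X - ds.X.mean(axis=0)
    # SVD-based PCA; scores U*S, component variances S^2/(n-1)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    nz = var > var[0] * 1e-12 if var[0] > 0 else np.zeros_like(var, bool)
    var = var[nz]
    if var.size == 0:  # identical spectra
        spectral: list[str] = []
    else:
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, variance_kept) + 1)
        k = min(k, n - 1)
        if n <= k:
            raise ValueError(
                f"{n} samples cannot support {k} retained components"
            )
        scores = U[:, :k] * S[:k]
        comp_var = S[:k] ** 2 / (n - 1)
        d2 = np.sum(scores**2 / comp_var, axis=1)
        cutoff = stats.chi2.ppf(1 - alpha, df=k)
        spectral = [ds.sample_ids[i] for i in np.flatnonzero(d2 > cutoff)]
    reference: list[str] = []
    if ds.y is not None:
        sd = ds.y.std(ddof=1)
        if sd > 0:
            z = np.abs(ds.y - ds.y.mean()) / sd
            zc = stats.norm.ppf(1 - alpha / 2)
            reference = [ds.sample_ids[i] for i in np.flatnonzero(z > zc)]
    return spectral, reference


def split_calibration(
    ds: SpectralDataset, ratio: tuple[int, int] = (2, 1), seed: int = 0
) -> SplitResult:
    """Randomly split samples into calibration and prediction sets.

    The calibration share is rounded half-up, so 103 samples at 2:1 give a
    69-sample calibration set.  Assignment is a seeded uniform shuffle and is
    reproducible for a fixed seed.
    """
    cal_w, pred_w = ratio
    if cal_w <= 0 or pred_w <= 0:
        raise ValueError("split ratio parts must be positive")
    n = ds.n_samples
    n_cal = int(np.floor(n * cal_w / (cal_w + pred_w) + 0.5))
    if n_cal == 0 or n_cal == n:
        raise ValueError(f"split of {n} samples at {cal_w}:{pred_w} leaves an empty set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_idx = np.sort(perm[:n_cal])
    pred_idx = np.sort(perm[n_cal:])
    return SplitResult(
        calibration=ds.take(cal_idx), prediction=ds.take(pred_idx)
    )


def remove_samples(ds: SpectralDataset, ids: Sequence[str]) -> SpectralDataset:
    """Drop the named samples (used to remove flagged outliers)."""
    drop = set(ids)
    keep = [i for i, s in enumerate(ds.sample_ids) if s not in drop]
    return ds.take(keep)
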