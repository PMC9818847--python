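"""Synthetic egg cohorts and vis/SW-NIR-like semi-transmittance spectra.

Real egg spectra for this problem are not publicly deposited, so the package
ships a generator with a *known* freshness-to-spectrum link: every pipeline
stage (pretreatment, interval modelling, Lasso fusion) can be tested against
planted ground truth.  The generator emulates the headline features of a
storage study:

* a cohort of eggs (default 105) measured in batches over storage days
  1..13, weights ~ Normal(57.53 g, 4.095 g) truncated to the observed range;
* Haugh units starting near 85, declining gently to ~79 by day 7, dropping
  to ~70 by day 9 and drifting lower to day 13, clipped to [56, 91], with
  egg-level heterogeneity;
* albumen height back-solved from the Haugh formula so the indicator module
  reproduces the assigned HU exactly;
* smooth transmittance spectra on a 550-985 nm grid (2041 points) with
  absorption valleys near 645 / 770 / 880 / 970 nm whose depths are affine
  in HU and in storage day, broad per-egg nuisance structure uncorrelated
  with HU, multiplicative/additive replicate scatter, and white noise;
* three replicate scans per egg, tagged in the metadata.

The HU -> valley-depth link is a Beer-Lambert-style surrogate, not a
physical model; see the methods note for what that does and does not let
the tests claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .freshness import albumen_height_for_hu
from .spectra_io import SpectralDataset

# population HU trajectory: piecewise-linear through these (day, mean HU) knots
_HU_KNOT_DAYS = np.array([1.0, 7.0, 9.0, 13.0])
_HU_KNOT_MEANS = np.array([85.0, 79.0, 70.0, 64.0])


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_eggs: int = 105
    days: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13)
    seed: int = 0
    replicates: int = 3

    # wavelength grid
    wl_start: float = 550.0
    wl_stop: float = 985.0
    n_wavelengths: int = 2041

    # cohort
    weight_mean: float = 57.53
    weight_sd: float = 4.095
    weight_range: tuple[float, float] = (49.1, 69.5)
    hu_start_mean: float = 85.0
    hu_start_sd: float = 4.0
    hu_egg_sd: float = 3.0       # persistent egg-level HU offset
    hu_day_noise_sd: float = 1.5  # measurement-day scatter
    hu_clip: tuple[float, float] = (56.0, 91.0)
    shape_index_mean: float = 1.273
    shape_index_sd: float = 0.037

    # spectrum model (%T units)
    baseline_level: float = 18.0
    baseline_amplitude: float = 30.0
    baseline_center: float = 760.0
    baseline_width: float = 170.0
    band_centers: tuple[float, ...] = (645.0, 770.0, 880.0, 970.0)
    band_widths: tuple[float, ...] = (22.0, 14.0, 18.0, 16.0)
    band_depths: tuple[float, ...] = (6.0, 9.0, 5.0, 7.0)
    hu_coeffs: tuple[float, ...] = (0.10, 0.18, 0.08, 0.14)  # %T per HU below pivot
    day_coeffs: tuple[float, ...] = (0.08, 0.12, 0.05, 0.10)  # %T per storage day
    hu_pivot: float = 75.0
    day_level_slope: float = 0.30   # overall %T lost per storage day
    link_noise_sd: float = 2.0      # per-egg valley-depth noise, %T
    nuisance_centers: tuple[float, ...] = (600.0, 720.0, 830.0, 940.0)
    nuisance_width: float = 60.0
    nuisance_sd: float = 1.0        # per-egg broad structure, %T
    scatter_slope_sd: float = 0.05  # lognormal sigma of multiplicative scatter
    scatter_offset_sd: float = 1.0  # additive scatter, %T
    noise_sd: float = 0.35          # white noise per channel, %T

    def __post_init__(self) -> None:
        if min(self.scatter_slope_sd, self.scatter_offset_sd,
               self.noise_sd, self.link_noise_sd, self.nuisance_sd) < 0:
            raise ValueError("noise/scatter SDs must be nonnegative")
        if self.hu_clip[0] >= self.hu_clip[1]:
            raise ValueError("infeasible HU clip bounds")
        if len(self.band_centers) != len(self.band_widths) or \
                len(self.band_centers) != len(self.band_depths):
            raise ValueError("band parameter tuples must have equal length")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_stop, self.n_wavelengths)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated normal whose *truncated* mean equals ``mean``.

    Asymmetric bounds shift the mean of a plainly truncated normal, so the
    location parameter is solved for such that the expectation after
    truncation is the requested one.
    """
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = brentq(trunc_mean, lo, hi, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size,
                               random_state=rng)


def _mean_hu(day: np.ndarray) -> np.ndarray:
    return np.interp(day, _HU_KNOT_DAYS, _HU_KNOT_MEANS)


def generate_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Simulate the egg cohort: one row per egg with all freshness indicators.

    Eggs are spread over the sampling days (batch design), each assigned the
    day it is measured and cracked on.  The albumen height is back-solved
    from the Haugh formula, so ``haugh_unit(albumen_height_mm, weight_g)``
    reproduces the ``HU`` column to machine precision.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_eggs
    days = np.array(cfg.days, dtype=float)[
        np.arange(n) % len(cfg.days)
    ]
    days.sort()
    arrival_w = _truncated_normal(
        rng, cfg.weight_mean, cfg.weight_sd, *cfg.weight_range, size=n
    )
    # weight loss accumulates ~0.55 %/day with egg-level spread
    wlr = np.clip(days * rng.normal(0.55, 0.12, size=n), 0.0, None)
    weight = arrival_w * (1 - wlr / 100.0)

    start_hu = rng.normal(cfg.hu_start_mean, cfg.hu_start_sd, size=n)
    egg_offset = rng.normal(0.0, cfg.hu_egg_sd, size=n)
    hu = (
        _mean_hu(days)
        + (start_hu - cfg.hu_start_mean)
        + egg_offset
        + rng.normal(0.0, cfg.hu_day_noise_sd, size=n)
    )
    hu = np.clip(hu, *cfg.hu_clip)
    albumen = albumen_height_for_hu(hu, weight)

    yolk_diam = rng.normal(39.5, 1.4, size=n)
    yc = np.clip(0.45 - 0.012 * days + rng.normal(0, 0.02, size=n), 0.12, None)
    yolk_height = yc * yolk_diam

    short_axis = _truncated_normal(rng, 43.2, 1.3, 40.24, 46.16, size=n)
    shape = np.clip(
        rng.normal(cfg.shape_index_mean, cfg.shape_index_sd, size=n), 1.0, None
    )
    long_axis = short_axis * shape

    return pd.DataFrame(
        {
            "egg": [f"e{i:03d}" for i in range(n)],
            "day": days.astype(int),
            "arrival_weight_g": arrival_w,
            "weight_g": weight,
            "HU": hu,
            "albumen_height_mm": albumen,
            "wlr_pct": wlr,
            "yolk_height_mm": yolk_height,
            "yolk_diameter_mm": yolk_diam,
            "yolk_coefficient": yc,
            "long_axis_mm": long_axis,
            "short_axis_mm": short_axis,
            "shape_index": shape,
        }
    )


def clean_spectrum(hu, day, cfg: SimConfig) -> np.ndarray:
    """Noise-free transmittance for one egg: baseline minus HU/day valleys."""
    wl = cfg.wavelengths
    base = cfg.baseline_level + cfg.baseline_amplitude * np.exp(
        -(((wl - cfg.baseline_center) / cfg.baseline_width) ** 2)
    ) - cfg.day_level_slope * day
    spec = base.copy()
    for c, w, d0, sh, sd_ in zip(
        cfg.band_centers, cfg.band_widths, cfg.band_depths,
        cfg.hu_coeffs, cfg.day_coeffs,
    ):
        depth = d0 + sh * (cfg.hu_pivot - hu) + sd_ * day
        spec -= depth * np.exp(-(((wl - c) / w) ** 2) / 2.0)
    return spec


def generate_spectra(cohort: pd.DataFrame, cfg: SimConfig) -> SpectralDataset:
    """Replicate semi-transmittance spectra for every egg in the cohort.

    Each replicate is ``a_i * clean + b_i + noise`` with lognormal
    multiplicative scatter ``a_i`` and normal additive offset ``b_i``,
    plus per-egg broad nuisance structure and valley-depth link noise that
    are *not* explained by HU — these bound the achievable calibration
    accuracy.  Deterministic for a fixed config seed; transmittance is
    clipped at zero (counted in ``dataset.meta.attrs['n_clipped']``).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream from cohort
    wl = cfg.wavelengths
    nuis_shapes = np.stack(
        [np.exp(-(((wl - c) / cfg.nuisance_width) ** 2) / 2.0)
         for c in cfg.nuisance_centers]
    )
    gauss = np.stack(
        [np.exp(-(((wl - c) / w) ** 2) / 2.0)
         for c, w in zip(cfg.band_centers, cfg.band_widths)]
    )
    rows, ids, y, meta = [], [], [], []
    n_clipped = 0
    for rec in cohort.itertuples(index=False):
        spec = clean_spectrum(rec.HU, rec.day, cfg)
        spec = spec + rng.normal(0, cfg.nuisance_sd, len(nuis_shapes)) @ nuis_shapes
        spec = spec - rng.normal(0, cfg.link_noise_sd, len(gauss)) @ gauss
        for rep in range(1, cfg.replicates + 1):
            a = rng.lognormal(0.0, cfg.scatter_slope_sd)
            b = rng.normal(0.0, cfg.scatter_offset_sd)
            noisy = a * spec + b + rng.normal(0.0, cfg.noise_sd, wl.size)
            clipped = noisy < 0
            n_clipped += int(clipped.sum())
            noisy[clipped] = 0.0
            rows.append(noisy)
            ids.append(f"{rec.egg}_r{rep}")
            y.append(rec.HU)
            meta.append(
                {"egg": rec.egg, "day": rec.day, "weight_g": rec.weight_g,
                 "replicate": rep}
            )
    meta_df = pd.DataFrame(meta, index=pd.Index(ids, name="id"))
    ds = SpectralDataset(
        wavelengths=wl, X=np.vstack(rows), y=np.asarray(y),
        sample_ids=ids, meta=meta_df,
    )
    ds.meta.attrs["n_clipped"] = n_clipped
    return ds


def plant_interval_signal(
    p: int,
    n: int,
    signal_intervals: tuple[int, ...],
    n_samples: int,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> SpectralDataset:
    """Oracle dataset: y depends only on columns inside the named intervals.

    ``signal_intervals`` is 1-based (report convention).  All columns are iid
    standard normal; y is a unit-variance linear combination of each signal
    interval's columns under a smooth band-shaped weight profile (an
    absorption feature spans a band, not isolated channels), plus Gaussian
    noise.  Used to test that interval ranking and Lasso selection recover
    planted support.
    """
    from .ipls import divide_intervals  # local import avoids a cycle

    if not signal_intervals:
        raise ValueError("need at least one signal interval")
    division = divide_intervals(p, n)
    if not set(signal_intervals) <= set(range(1, n + 1)):
        raise ValueError(f"signal intervals must be within 1..{n}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, p))
    y = np.zeros(n_samples)
    for j in signal_intervals:
        cols = division.columns(j - 1)
        # Gaussian band profile over the interval, unit L2 norm
        x = np.arange(cols.size, dtype=float)
        w = np.exp(-(((x - x.mean()) / (max(cols.size, 2) / 6.0)) ** 2) / 2.0)
        y += X[:, cols] @ (w / np.linalg.norm(w))
    y += rng.normal(0.0, noise_sd, n_samples)
    return SpectralDataset(
        wavelengths=np.arange(p, dtype=float), X=X, y=y,
        sample_ids=[f"s{i:04d}" for i in range(n_samples)],
    )
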