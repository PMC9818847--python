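"""Egg freshness and morphology indicators.

The Haugh unit is the commercial standard for interior egg quality: it
combines the thick-albumen height H (mm, averaged over four measurement
sites) with the egg weight W (g) as

    HU = 100 * log10(H - 1.7 * W**0.37 + 7.57)

Higher HU means fresher; retail eggs span roughly 50-100.  The remaining
indicators are simple ratios: weight loss rate (percent of arrival weight
lost in storage), yolk coefficient (yolk height / diameter, declines with
age) and the egg shape index (long axis / short axis).
"""

from __future__ import annotations

import warnings

import numpy as np


def haugh_unit(albumen_height_mm, weight_g):
    """Haugh unit from thick-albumen height (mm) and egg weight (g).

    Vectorised; raises if the log argument H - 1.7 W^0.37 + 7.57 is not
    positive (physically meaningless input).
    """
    H = np.asarray(albumen_height_mm, dtype=float)
    W = np.asarray(weight_g, dtype=float)
    arg = H - 1.7 * W**0.37 + 7.57
    if np.any(arg <= 0):
        raise ValueError(
            f"non-positive Haugh argument for H={albumen_height_mm}, "
            f"W={weight_g}"
        )
    out = 100.0 * np.log10(arg)
    return float(out) if out.ndim == 0 else out


def albumen_height_for_hu(hu, weight_g):
    """Invert the Haugh formula: the H (mm) that yields ``hu`` at ``weight_g``."""
    hu = np.asarray(hu, dtype=float)
    W = np.asarray(weight_g, dtype=float)
    out = 10.0 ** (hu / 100.0) + 1.7 * W**0.37 - 7.57
    return float(out) if out.ndim == 0 else out


def weight_loss_rate(arrival_g, current_g):
    """Percent weight lost relative to the arrival weight.

    A current weight above arrival is physically suspect; the (negative)
    rate is returned with a warning rather than an error.
    """
    arrival = np.asarray(arrival_g, dtype=float)
    current = np.asarray(current_g, dtype=float)
    if np.any(arrival <= 0):
        raise ValueError("arrival weight must be positive")
    wlr = 100.0 * (arrival - current) / arrival
    if np.any(wlr < 0):
        warnings.warn("negative weight loss rate (gain in storage?)", stacklevel=2)
    return float(wlr) if wlr.ndim == 0 else wlr


def yolk_coefficient(height_mm, diameter_mm):
    """Yolk centre height divided by yolk diameter."""
    h = np.asarray(height_mm, dtype=float)
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("yolk dimensions must be positive")
    out = h / d
    return float(out) if out.ndim == 0 else out


def shape_index(long_mm, short_mm):
    """Egg shape index: long axis over short axis (>= 1 by convention)."""
    lo = np.asarray(long_mm, dtype=float)
    sh = np.asarray(short_mm, dtype=float)
    if np.any(sh <= 0):
        raise ValueError("short axis must be positive")
    if np.any(lo < sh):
        raise ValueError("long axis shorter than short axis: swapped inputs?")
    out = lo / sh
    return float(out) if out.ndim == 0 else out
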