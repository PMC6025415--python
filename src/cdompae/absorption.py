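"""CDOM absorption coefficients and derived spectral metrics.

The Napierian absorption coefficient is obtained from measured decadic
optical density OD(λ) in a cuvette of path length γ (m):

    a(λ) = 2.303 · OD(λ) / γ        [m⁻¹]

From the coefficient spectrum the standard composition proxies follow:

* ``S275–295`` — exponential spectral slope over 275–295 nm, fitted by
  ordinary least squares on ln a(λ); inversely tracks molecular weight.
* ``E250:365`` — a(250)/a(365); higher means lower aromaticity/weight.
* ``SUVA254`` — a(254)/DOC in L·mg C⁻¹·m⁻¹; aromaticity per unit carbon.
* ``S_R`` — slope ratio S275–295 / S350–400.

Slopes are reported positive for spectra decaying with wavelength.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import AbsorptionSpectrum
from .exceptions import ValidationError

__all__ = [
    "CDOMIndices",
    "napierian_absorption",
    "a_at",
    "spectral_slope",
    "e_ratio",
    "suva",
    "slope_ratio",
    "cdom_indices",
]

LN10 = 2.303  # decadic→Napierian conversion constant, as conventionally rounded


@dataclass
class CDOMIndices:
    """Per-sample absorption/fluorescence summary (one row of the indices table)."""

    sample_id: str = ""
    a350_per_m: float = math.nan
    a254_per_m: float = math.nan
    s275_295_per_nm: float = math.nan
    e250_365: float = math.nan
    suva254_l_per_mgc_per_m: float = math.nan
    s350_400_per_nm: float = math.nan
    slope_ratio_sr: float = math.nan
    fi370: float = math.nan
    fi310: float = math.nan
    source_origin: str = ""
    source_autochthony: str = ""


def napierian_absorption(spec: AbsorptionSpectrum) -> pd.Series:
    """Napierian absorption coefficients a(λ) = 2.303·OD(λ)/γ in m⁻¹.

    Returned as a Series indexed by wavelength (nm), linear in OD.
    """
    coeffs = LN10 * spec.optical_density / spec.path_length_m
    return pd.Series(coeffs, index=pd.Index(spec.wavelength_nm, name="wavelength_nm"),
                     name="a_per_m")


def a_at(a: pd.Series, wavelength: float) -> float:
    """Coefficient at a wavelength (linear interpolation inside the range)."""
    wl = a.index.to_numpy(dtype=float)
    if not wl[0] <= wavelength <= wl[-1]:
        raise ValidationError(f"wavelength {wavelength} nm outside coefficient range")
    return float(np.interp(wavelength, wl, a.to_numpy(dtype=float)))


def spectral_slope(a: pd.Series, window: tuple[float, float] = (275.0, 295.0),
                   min_points: int = 5) -> float:
    """Exponential slope S (nm⁻¹) over a closed window, by log-linear OLS.

    Fits ln a(λ) = ln a0 − S·λ over the window; non-positive coefficients
    are dropped and if fewer than ``min_points`` remain the slope is NaN
    with a warning.  Scale-invariant: multiplying a(λ) by any c > 0 leaves
    S unchanged.
    """
    wl = a.index.to_numpy(dtype=float)
    sel = (wl >= window[0]) & (wl <= window[1])
    wl_fit = wl[sel]
    a_fit = a.to_numpy(dtype=float)[sel]
    positive = a_fit > 0
    wl_fit, a_fit = wl_fit[positive], a_fit[positive]
    if wl_fit.size < min_points:
        warnings.warn(
            f"spectral_slope: only {wl_fit.size} positive coefficients in "
            f"[{window[0]:g}, {window[1]:g}] nm (need {min_points}); returning NaN",
            stacklevel=2)
        return math.nan
    slope, _ = np.polyfit(wl_fit, np.log(a_fit), 1)
    return float(-slope)


def e_ratio(a: pd.Series) -> float:
    """E250:365 = a(250)/a(365); requires a(365) > 0."""
    a250 = a_at(a, 250.0)
    a365 = a_at(a, 365.0)
    if a365 <= 0:
        raise ValidationError("a(365) must be positive for E250:365")
    return a250 / a365


def suva(a254_per_m: float, doc_mg_per_l: float) -> float:
    """SUVA254 = a(254)/DOC in L·mg C⁻¹·m⁻¹; NaN when DOC is not positive."""
    if not doc_mg_per_l > 0:
        return math.nan
    return a254_per_m / doc_mg_per_l


def slope_ratio(a: pd.Series) -> float:
    """S_R = S275–295 / S350–400; NaN when either slope is missing or S350–400 is 0."""
    s_short = spectral_slope(a, (275.0, 295.0))
    s_long = spectral_slope(a, (350.0, 400.0))
    # a numerically flat window gives a slope at rounding level, not a ratio
    if math.isnan(s_short) or math.isnan(s_long) or abs(s_long) < 1e-12:
        return math.nan
    return s_short / s_long


def cdom_indices(spec: AbsorptionSpectrum, doc_mg_per_l: float = math.nan,
                 eem=None) -> CDOMIndices:
    """All absorption metrics for one sample, plus FI/source labels if an EEM is given."""
    from .fri import classify_source, fluorescence_index  # local import, avoids cycle

    a = napierian_absorption(spec)
    a254 = a_at(a, 254.0)
    out = CDOMIndices(
        sample_id=spec.sample_id,
        a350_per_m=a_at(a, 350.0),
        a254_per_m=a254,
        s275_295_per_nm=spectral_slope(a),
        e250_365=e_ratio(a),
        suva254_l_per_mgc_per_m=suva(a254, doc_mg_per_l),
        s350_400_per_nm=spectral_slope(a, (350.0, 400.0)),
        slope_ratio_sr=slope_ratio(a),
    )
    if eem is not None:
        out.fi370 = fluorescence_index(eem, "FI370")
        out.fi310 = fluorescence_index(eem, "FI310")
        if math.isfinite(out.fi370) and math.isfinite(out.fi310):
            out.source_origin, out.source_autochthony = classify_source(out.fi370, out.fi310)
    return out
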