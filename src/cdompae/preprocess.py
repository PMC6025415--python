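"""EEM corrections applied before regional integration.

Three steps, normally run in the order blank → inner-filter → scatter:

1. **Blank subtraction** — the Milli-Q water EEM is subtracted elementwise;
   negative residuals are floored at zero (and counted) so integration
   volumes are never reduced by negative noise.
2. **Inner-filter correction** — intensities are rescaled by
   ``10 ** ((A(λex) + A(λem)) / 2)`` using the sample's own decadic optical
   density, both spectra being acquired in 1 cm cells.
3. **Scatter excision** — first-order Rayleigh (λem ≈ λex) and second-order
   (λem ≈ 2λex) bands are excised within a configurable half-width and
   either zeroed or re-filled by linear interpolation along the emission
   axis (zero-fill where a band touches the spectrum edge).
"""

from __future__ import annotations

import logging

import numpy as np

from .dataio import AbsorptionSpectrum, EEMGrid
from .exceptions import ValidationError

__all__ = [
    "subtract_blank",
    "remove_scatter",
    "inner_filter_correct",
    "scatter_mask",
]

logger = logging.getLogger(__name__)


def _check_axes_match(a: EEMGrid, b: EEMGrid) -> None:
    if (a.excitation_nm.shape != b.excitation_nm.shape
            or a.emission_nm.shape != b.emission_nm.shape
            or not np.allclose(a.excitation_nm, b.excitation_nm, atol=1e-6)
            or not np.allclose(a.emission_nm, b.emission_nm, atol=1e-6)):
        raise ValidationError("sample and blank EEMs have different wavelength axes")


def subtract_blank(eem: EEMGrid, blank: EEMGrid) -> EEMGrid:
    """Subtract a water blank elementwise, flooring negatives at zero."""
    _check_axes_match(eem, blank)
    diff = eem.intensity - blank.intensity
    n_floored = int(np.count_nonzero(diff < 0))
    if n_floored:
        logger.info("blank subtraction floored %d negative cells in %s",
                    n_floored, eem.sample_id or "<unnamed>")
    return eem.with_intensity(np.maximum(diff, 0.0), add_corrections={"blank"})


def scatter_mask(excitation_nm: np.ndarray, emission_nm: np.ndarray,
                 first_order_halfwidth_nm: float = 15.0,
                 second_order_halfwidth_nm: float = 15.0) -> np.ndarray:
    """Boolean mask of excised cells: True where a cell falls in a scatter band.

    A cell (λex, λem) is excised iff ``|λem − λex| <= w1`` or
    ``|λem − 2·λex| <= w2``; membership is decided by these inequalities
    only, with no special-casing at the grid edges.
    """
    ex = np.asarray(excitation_nm, dtype=float)[:, None]
    em = np.asarray(emission_nm, dtype=float)[None, :]
    return (np.abs(em - ex) <= first_order_halfwidth_nm) | (
        np.abs(em - 2.0 * ex) <= second_order_halfwidth_nm)


def remove_scatter(eem: EEMGrid,
                   first_order_halfwidth_nm: float = 15.0,
                   second_order_halfwidth_nm: float = 15.0,
                   mode: str = "interpolate") -> EEMGrid:
    """Excise Rayleigh scatter bands of first and second order.

    ``mode="interpolate"`` refills each excised cell by linear interpolation
    along the emission axis between the nearest retained neighbours, with
    zero fill where the band touches the first or last emission point;
    ``mode="zero"`` sets excised cells to 0.  Cells outside both bands are
    left bit-identical.
    """
    if first_order_halfwidth_nm <= 0 or second_order_halfwidth_nm <= 0:
        raise ValidationError("scatter half-widths must be positive")
    if mode not in ("zero", "interpolate"):
        raise ValidationError(f"unknown scatter mode {mode!r}")
    mask = scatter_mask(eem.excitation_nm, eem.emission_nm,
                        first_order_halfwidth_nm, second_order_halfwidth_nm)
    out = eem.intensity.copy()
    if mode == "zero":
        out[mask] = 0.0
    else:
        em = eem.emission_nm
        for i in range(out.shape[0]):
            excised = mask[i]
            if not excised.any():
                continue
            kept = ~excised
            if not kept.any():
                out[i] = 0.0
                continue
            out[i, excised] = np.interp(
                em[excised], em[kept], out[i, kept], left=0.0, right=0.0)
    return eem.with_intensity(out, add_corrections={"scatter"})


def inner_filter_correct(eem: EEMGrid, abs_spectrum: AbsorptionSpectrum) -> EEMGrid:
    """Absorbance-based inner-filter correction.

    ``I_corr(λex, λem) = I(λex, λem) · 10 ** ((A(λex) + A(λem)) / 2)`` with
    A the decadic optical density in the measurement cell.  The absorbance
    spectrum must cover every EEM wavelength; there is no extrapolation.
    """
    for axis in (eem.excitation_nm, eem.emission_nm):
        if not abs_spectrum.covers(axis):
            raise ValidationError(
                "absorbance spectrum does not cover the EEM wavelength range "
                f"({axis.min():g}–{axis.max():g} nm)")
    a_ex = abs_spectrum.od_at(eem.excitation_nm)[:, None]
    a_em = abs_spectrum.od_at(eem.emission_nm)[None, :]
    factor = 10.0 ** ((a_ex + a_em) / 2.0)
    return eem.with_intensity(eem.intensity * factor, add_corrections={"inner_filter"})
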