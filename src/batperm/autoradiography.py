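"""Quantitative autoradiography (QAR): intensity -> ng/g calibration.

Phosphor-screen intensity is converted to tissue radiolabel concentration
through co-exposed tissue-calibrated standards.  The default calibration
is a straight line with intercept (screen fog is absorbed by the
intercept); concentration maps are then summarised by square ROIs
(100 x 100 um, 50 x 50 um inside the BAT band) or by signed-distance
radial bins reusing the ring geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import LesionSet, RadialProfile
from .rings import build_rings, signed_distance_map

__all__ = [
    "CalibrationCurve",
    "ConcentrationMap",
    "fit_calibration",
    "intensity_to_concentration",
    "square_roi_concentration",
    "radial_concentration_profile",
]


@dataclass
class CalibrationCurve:
    """OLS line ``intensity = intercept + slope * concentration``."""

    slope: float  # AU per (ng/g); must be > 0 for an invertible curve
    intercept: float  # AU (screen fog / background)
    r_squared: float
    n_standards: int
    valid_range: tuple[float, float]  # ng/g span of the standards

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if self.n_standards < 3:
            raise ValueError("need >= 3 standards")


@dataclass
class ConcentrationMap:
    """Per-pixel drug concentration in ng/g with range bookkeeping.

    ``out_of_range`` flags pixels whose inverted value fell below zero
    (floored at 0) or above the calibrated span — flagged, never clipped
    silently at the top end.
    """

    raster: np.ndarray
    pixel_size: float
    out_of_range: np.ndarray
    valid_range: tuple[float, float]


def _as_standards_frame(standards) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of (concentration, intensity)."""
    if isinstance(standards, pd.DataFrame):
        cols = {c.lower(): c for c in standards.columns}
        conc_col = next(
            (cols[c] for c in cols if c.startswith("conc")), None
        )
        int_col = next((cols[c] for c in cols if c.startswith("intens")), None)
        if conc_col is None or int_col is None:
            raise ValueError(
                "standards frame needs concentration* and intensity* columns"
            )
        return pd.DataFrame(
            {
                "concentration": standards[conc_col].to_numpy(dtype=float),
                "intensity": standards[int_col].to_numpy(dtype=float),
            }
        )
    arr = np.asarray(list(standards), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (concentration, intensity) pairs")
    return pd.DataFrame({"concentration": arr[:, 0], "intensity": arr[:, 1]})


def fit_calibration(standards) -> CalibrationCurve:
    """Fit the straight-line calibration to co-exposed standards.

    Requires at least 3 standards with at least 2 distinct concentration
    levels (duplicated levels are fine, zero spread is not).
    """
    df = _as_standards_frame(standards)
    if len(df) < 3:
        raise ValueError(f"need >= 3 calibration standards, got {len(df)}")
    if np.any(df["concentration"] < 0):
        raise ValueError("standard concentrations must be >= 0")
    if np.unique(df["concentration"]).size < 2:
        raise ValueError("standards span zero concentration range; curve unfittable")

    fit = stats.linregress(df["concentration"], df["intensity"])
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_standards=len(df),
        valid_range=(float(df["concentration"].min()), float(df["concentration"].max())),
    )


def intensity_to_concentration(
    curve: CalibrationCurve, raster: np.ndarray, pixel_size: float = 1.0
) -> ConcentrationMap:
    """Invert the calibration per pixel: c = (intensity - intercept) / slope.

    Negative inversions are floored at 0 and flagged; values above the top
    standard are kept as-is but flagged out-of-range.
    """
    raster = np.asarray(raster, dtype=float)
    conc = (raster - curve.intercept) / curve.slope
    below = conc < 0
    above = conc > curve.valid_range[1]
    out = below | above
    conc = np.where(below, 0.0, conc)
    return ConcentrationMap(
        raster=conc, pixel_size=pixel_size, out_of_range=out, valid_range=curve.valid_range
    )


def square_roi_concentration(
    cmap: ConcentrationMap, center_um: tuple[float, float], size_um: float
) -> float:
    """Mean concentration over an axis-aligned square ROI.

    ``center_um`` is (row, col) in pixel-center micrometre coordinates.
    A pixel belongs to the square when its center lies in the half-open
    box ``[c - s/2, c + s/2)`` on both axes (half-open at the max edges so
    adjacent squares tile without double counting).  The square must lie
    fully inside the raster.
    """
    if size_um <= 0:
        raise ValueError("size_um must be > 0")
    h, w = cmap.raster.shape
    px = cmap.pixel_size
    rows = np.arange(h) * px
    cols = np.arange(w) * px
    r0, c0 = center_um
    if (
        r0 - size_um / 2 < rows[0] - px / 2
        or r0 + size_um / 2 > rows[-1] + px / 2
        or c0 - size_um / 2 < cols[0] - px / 2
        or c0 + size_um / 2 > cols[-1] + px / 2
    ):
        raise ValueError("square ROI extends outside the raster")
    rsel = (rows >= r0 - size_um / 2) & (rows < r0 + size_um / 2)
    csel = (cols >= c0 - size_um / 2) & (cols < c0 + size_um / 2)
    if not rsel.any() or not csel.any():
        raise ValueError("square ROI contains no pixel centers")
    return float(cmap.raster[np.ix_(rsel, csel)].mean())


def radial_concentration_profile(
    cmap: ConcentrationMap,
    lesions: LesionSet,
    k: int,
    bin_width: float = 50.0,
    extent: float = 300.0,
    exclusions: np.ndarray | None = None,
) -> RadialProfile:
    """Mean ng/g per signed-distance bin around lesion ``k``.

    Reuses the circumferential ring geometry with autoradiography bin
    widths (50 um inside the BAT band by default; 100 um elsewhere is a
    config choice).
    """
    dmap = signed_distance_map(lesions, k)
    rings = build_rings(
        dmap,
        ring_width=bin_width,
        extent=extent,
        exclusions=exclusions,
        pixel_size=cmap.pixel_size,
        lesion_id=k,
    )
    n_pix = rings.n_pixels
    flat_idx = rings.bin_index.ravel()
    sel = flat_idx >= 0
    sums = np.bincount(
        flat_idx[sel], weights=cmap.raster.ravel()[sel], minlength=rings.n_bins
    )
    keep = n_pix > 0
    means = sums[keep] / n_pix[keep]
    return RadialProfile(
        bin_lo=rings.bins[keep, 0],
        bin_hi=rings.bins[keep, 1],
        n_pixels=n_pix[keep],
        value=means,
        units="ng_per_g",
        reference=None,
        lesion_id=k,
    )
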