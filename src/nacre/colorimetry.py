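"""Band statistics and CIE 1931 colorimetry of reflectance spectra.

Two quantifications of "how colorful" a spectrum is:

* :func:`peak_stats` — the band description used throughout: peak position
  λ_max, full width at half maximum, peak reflectance, and the off-band
  baseline (the "white noise" that washes a color out);
* :func:`spectrum_to_chromaticity` — CIE 1931 chromaticity (x, y, z with
  x + y + z = 1) of the spectrum under an illuminant, plus a scalar
  saturation: the Euclidean (x, y) distance from the illuminant white
  point. Narrow bands on a dark baseline sit near the spectral locus
  (high saturation); broad or noise-lifted spectra collapse toward the
  white point.

The CIE 1931 2° color-matching functions are embedded as the standard 5 nm
table and linearly interpolated to the working grid; the D65 illuminant is
embedded at 10 nm. White points are computed from the same tables, so a
flat spectrum maps exactly to its illuminant's white point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tmm import Spectrum

__all__ = [
    "PeakStats",
    "Chromaticity",
    "peak_stats",
    "spectrum_to_chromaticity",
    "white_point",
    "compare_saturation",
    "CMF_5NM",
    "D65_10NM",
]

# CIE 1931 2-degree standard observer color-matching functions,
# 380-780 nm at 5 nm: columns (lambda_nm, xbar, ybar, zbar).
CMF_5NM = np.array([
    [380, 0.001368, 0.000039, 0.006450],
    [385, 0.002236, 0.000064, 0.010550],
    [390, 0.004243, 0.000120, 0.020050],
    [395, 0.007650, 0.000217, 0.036210],
    [400, 0.014310, 0.000396, 0.067850],
    [405, 0.023190, 0.000640, 0.110200],
    [410, 0.043510, 0.001210, 0.207400],
    [415, 0.077630, 0.002180, 0.371300],
    [420, 0.134380, 0.004000, 0.645600],
    [425, 0.214770, 0.007300, 1.039050],
    [430, 0.283900, 0.011600, 1.385600],
    [435, 0.328500, 0.016840, 1.622960],
    [440, 0.348280, 0.023000, 1.747060],
    [445, 0.348060, 0.029800, 1.782600],
    [450, 0.336200, 0.038000, 1.772110],
    [455, 0.318700, 0.048000, 1.744100],
    [460, 0.290800, 0.060000, 1.669200],
    [465, 0.251100, 0.073900, 1.528100],
    [470, 0.195360, 0.090980, 1.287640],
    [475, 0.142100, 0.112600, 1.041900],
    [480, 0.095640, 0.139020, 0.812950],
    [485, 0.057950, 0.169300, 0.616200],
    [490, 0.032010, 0.208020, 0.465180],
    [495, 0.014700, 0.258600, 0.353300],
    [500, 0.004900, 0.323000, 0.272000],
    [505, 0.002400, 0.407300, 0.212300],
    [510, 0.009300, 0.503000, 0.158200],
    [515, 0.029100, 0.608200, 0.111700],
    [520, 0.063270, 0.710000, 0.078250],
    [525, 0.109600, 0.793200, 0.057250],
    [530, 0.165500, 0.862000, 0.042160],
    [535, 0.225750, 0.914850, 0.029840],
    [540, 0.290400, 0.954000, 0.020300],
    [545, 0.359700, 0.980300, 0.013400],
    [550, 0.433450, 0.994950, 0.008750],
    [555, 0.512050, 1.000000, 0.005750],
    [560, 0.594500, 0.995000, 0.003900],
    [565, 0.678400, 0.978600, 0.002750],
    [570, 0.762100, 0.952000, 0.002100],
    [575, 0.842500, 0.915400, 0.001800],
    [580, 0.916300, 0.870000, 0.001650],
    [585, 0.978600, 0.816300, 0.001400],
    [590, 1.026300, 0.757000, 0.001100],
    [595, 1.056700, 0.694900, 0.001000],
    [600, 1.062200, 0.631000, 0.000800],
    [605, 1.045600, 0.566800, 0.000600],
    [610, 1.002600, 0.503000, 0.000340],
    [615, 0.938400, 0.441200, 0.000240],
    [620, 0.854450, 0.381000, 0.000190],
    [625, 0.751400, 0.321000, 0.000100],
    [630, 0.642400, 0.265000, 0.000050],
    [635, 0.541900, 0.217000, 0.000030],
    [640, 0.447900, 0.175000, 0.000020],
    [645, 0.360800, 0.138200, 0.000010],
    [650, 0.283500, 0.107000, 0.000000],
    [655, 0.218700, 0.081600, 0.000000],
    [660, 0.164900, 0.061000, 0.000000],
    [665, 0.121200, 0.044580, 0.000000],
    [670, 0.087400, 0.032000, 0.000000],
    [675, 0.063600, 0.023200, 0.000000],
    [680, 0.046770, 0.017000, 0.000000],
    [685, 0.032900, 0.011920, 0.000000],
    [690, 0.022700, 0.008210, 0.000000],
    [695, 0.015840, 0.005723, 0.000000],
    [700, 0.011359, 0.004102, 0.000000],
    [705, 0.008111, 0.002929, 0.000000],
    [710, 0.005790, 0.002091, 0.000000],
    [715, 0.004109, 0.001484, 0.000000],
    [720, 0.002899, 0.001047, 0.000000],
    [725, 0.002049, 0.000740, 0.000000],
    [730, 0.001440, 0.000520, 0.000000],
    [735, 0.001000, 0.000361, 0.000000],
    [740, 0.000690, 0.000249, 0.000000],
    [745, 0.000476, 0.000172, 0.000000],
    [750, 0.000332, 0.000120, 0.000000],
    [755, 0.000235, 0.000085, 0.000000],
    [760, 0.000166, 0.000060, 0.000000],
    [765, 0.000117, 0.000042, 0.000000],
    [770, 0.000083, 0.000030, 0.000000],
    [775, 0.000059, 0.000021, 0.000000],
    [780, 0.000042, 0.000015, 0.000000],
])

# CIE standard illuminant D65 relative spectral power, 380-780 nm at 10 nm.
D65_10NM = np.array([
    [380, 49.98], [390, 54.65], [400, 82.75], [410, 91.49], [420, 93.43],
    [430, 86.68], [440, 104.86], [450, 117.01], [460, 117.81], [470, 114.86],
    [480, 115.92], [490, 108.81], [500, 109.35], [510, 107.80], [520, 104.79],
    [530, 107.69], [540, 104.41], [550, 104.05], [560, 100.00], [570, 96.33],
    [580, 95.79], [590, 88.69], [600, 90.01], [610, 89.60], [620, 87.70],
    [630, 83.29], [640, 83.70], [650, 80.03], [660, 80.21], [670, 82.28],
    [680, 78.28], [690, 69.72], [700, 71.61], [710, 74.35], [720, 61.60],
    [730, 69.89], [740, 75.09], [750, 63.59], [760, 46.42], [770, 66.81],
    [780, 63.38],
])

_FLAT_TOL = 1e-12


@dataclass(frozen=True)
class PeakStats:
    """Band description of a reflectance spectrum.

    ``lambda_max`` and ``fwhm`` are None when the spectrum is flat or the
    band cannot be resolved at half maximum.
    """

    lambda_max: Optional[float]
    fwhm: Optional[float]
    peak_reflectance: float
    baseline: float


@dataclass(frozen=True)
class Chromaticity:
    """CIE 1931 chromaticity with x + y + z = 1 and a scalar saturation."""

    x: float
    y: float
    z: float
    saturation: float


def _half_crossings(wl: np.ndarray, v: np.ndarray, i_peak: int, half: float):
    """Outermost half-maximum crossings, linearly interpolated.

    The left crossing is the first rise through ``half`` scanning from the
    short-wavelength edge, the right crossing the last fall scanning to the
    long-wavelength edge. Taking the outermost (rather than the nearest)
    crossings makes the width robust to coherent ripple that dips below
    half maximum inside a broad band (e.g. chirped-period stacks).
    """
    above = v > half
    if above[0] or above[-1] or not above[i_peak]:
        return None, None  # band not bracketed by the grid
    idx = np.flatnonzero(above)
    i_lo, i_hi = idx[0], idx[-1]
    frac_l = (half - v[i_lo - 1]) / (v[i_lo] - v[i_lo - 1])
    left = wl[i_lo - 1] + frac_l * (wl[i_lo] - wl[i_lo - 1])
    frac_r = (v[i_hi] - half) / (v[i_hi] - v[i_hi + 1])
    right = wl[i_hi] + frac_r * (wl[i_hi + 1] - wl[i_hi])
    return float(left), float(right)


def peak_stats(spectrum: Spectrum) -> PeakStats:
    """λ_max, FWHM, peak height and off-band baseline of a spectrum.

    The FWHM is taken at half maximum *above baseline*, with the baseline
    estimated as the median reflectance outside λ_max ± 1.5×FWHM (one
    refinement pass, starting from the global median). A flat spectrum has
    no defined peak; a band whose half-maximum crossings are not bracketed
    by the grid reports ``fwhm=None``.
    """
    wl, v = spectrum.wavelengths, spectrum.values
    peak = float(v.max())
    if peak - v.min() < _FLAT_TOL:
        return PeakStats(lambda_max=None, fwhm=None, peak_reflectance=peak,
                         baseline=float(np.median(v)))
    i_peak = int(np.argmax(v))
    lam = float(wl[i_peak])

    baseline = float(np.median(v))
    fwhm = None
    for _ in range(2):  # initial estimate, then one baseline refinement
        half = baseline + 0.5 * (peak - baseline)
        left, right = _half_crossings(wl, v, i_peak, half)
        if left is None or right is None:
            fwhm = None
            break
        fwhm = float(right - left)
        mask = (wl < lam - 1.5 * fwhm) | (wl > lam + 1.5 * fwhm)
        if not np.any(mask):
            break
        baseline = float(np.median(v[mask]))
    baseline = min(baseline, peak)
    return PeakStats(lambda_max=lam, fwhm=fwhm, peak_reflectance=peak, baseline=baseline)


def _illuminant_power(name: str, wl: np.ndarray) -> np.ndarray:
    if name == "E":
        return np.ones_like(wl)
    if name == "D65":
        return np.interp(wl, D65_10NM[:, 0], D65_10NM[:, 1])
    raise ValueError(f"unknown illuminant {name!r}; use 'E' or 'D65'")


def _tristimulus(wl: np.ndarray, reflectance: np.ndarray, illuminant: str) -> np.ndarray:
    lo, hi = CMF_5NM[0, 0], CMF_5NM[-1, 0]
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2 or (wl[mask][-1] - wl[mask][0]) < 100.0:
        raise ValueError("spectrum must cover a substantial part of the 380-780 nm band")
    w = wl[mask]
    refl = reflectance[mask]
    power = _illuminant_power(illuminant, w)
    xyz_bar = np.column_stack(
        [np.interp(w, CMF_5NM[:, 0], CMF_5NM[:, 1 + k]) for k in range(3)]
    )
    return np.array([np.trapezoid(refl * power * xyz_bar[:, k], w) for k in range(3)])


def white_point(illuminant: str = "E",
                wavelengths: Optional[np.ndarray] = None) -> tuple:
    """(x, y) chromaticity of the illuminant itself on the given grid."""
    wl = CMF_5NM[:, 0] if wavelengths is None else np.asarray(wavelengths, dtype=float)
    XYZ = _tristimulus(wl, np.ones_like(wl), illuminant)
    return (XYZ[0] / XYZ.sum(), XYZ[1] / XYZ.sum())


def spectrum_to_chromaticity(spectrum: Spectrum, illuminant: str = "E") -> Chromaticity:
    """CIE 1931 chromaticity of a reflectance spectrum under an illuminant.

    X, Y, Z are the reflectance × illuminant spectra weighted by the 2°
    color-matching functions; (x, y, z) = (X, Y, Z)/(X+Y+Z). Saturation is
    the Euclidean distance of (x, y) from the illuminant white point — zero
    for a flat (white/gray) spectrum, large for narrow bands near the
    spectral locus. Chromaticity is scale-invariant: overall brightness
    cancels in the normalization.
    """
    wl, v = spectrum.wavelengths, spectrum.values
    if np.any(v < 0):
        raise ValueError("reflectance must be non-negative")
    XYZ = _tristimulus(wl, v, illuminant)
    total = XYZ.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum has undefined chromaticity")
    x, y, z = XYZ / total
    wx, wy = white_point(illuminant, wl)
    return Chromaticity(x=float(x), y=float(y), z=float(z),
                        saturation=float(np.hypot(x - wx, y - wy)))


def compare_saturation(spectra: Sequence[Spectrum], illuminant: str = "E") -> pd.DataFrame:
    """Rank spectra by color saturation (most saturated first).

    Ties are broken by λ_max (ascending), then by input order. Returns a
    DataFrame with columns ``spectrum`` (input position), ``lambda_max``,
    ``saturation`` and ``rank`` (1 = most saturated).
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to rank")
    rows = []
    for i, sp in enumerate(spectra):
        chrom = spectrum_to_chromaticity(sp, illuminant)
        stats = peak_stats(sp)
        rows.append({
            "spectrum": i,
            "lambda_max": np.nan if stats.lambda_max is None else stats.lambda_max,
            "saturation": chrom.saturation,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["saturation", "lambda_max", "spectrum"],
        ascending=[False, True, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
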