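"""Closed-form interference models for nacre-like multilayers.

Three analytic pieces connect stack geometry to color without running the
full solver:

* the Bragg-Snell condition ``2 d sqrt(n_eff^2 - sin^2 θ) = m λ`` with the
  effective-medium index ``n_eff = sqrt(n1² φ1 + n2² φ2)`` of one lamination
  period (plate volume fraction φ1 = d1/d, gap fraction φ2 = d2/d);
* the Airy multiple-reflection reflectance of a single interlamellar gap
  sandwiched between aragonite half-spaces — for a 4 nm air gap at 500 nm
  this is ~1e-3, i.e. each individual nanogap is an extremely weak mirror;
* the penetration-depth heuristic: weaker per-gap reflectance lets light
  reach more reflection planes (N_eff ∝ 1/sqrt(R_gap)), and the interference
  bandwidth narrows as the number of contributing planes grows. The
  bandwidth side is evaluated numerically from solved spectra
  (:func:`fwhm_vs_planes`).

Together these give the causal chain behind the brilliant color of
Ammolite: thin air nanogaps ⇒ weak per-plane reflection ⇒ many contributing
planes ⇒ narrow band ⇒ saturated color.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .structure import LayerStack, StackSpec, sample_stack
from .tmm import DEFAULT_WAVELENGTHS, IncidenceGeometry, tmm_reflectance

__all__ = [
    "BraggPrediction",
    "effective_index",
    "bragg_wavelength",
    "bragg_prediction",
    "choose_order",
    "single_gap_reflectance",
    "effective_plane_count",
    "fwhm_vs_planes",
    "VISIBLE_RANGE",
]

#: Visible band used for order selection, nm.
VISIBLE_RANGE = (380.0, 780.0)


@dataclass(frozen=True)
class BraggPrediction:
    """Predicted constructive-interference peak of a periodic stack."""

    m: int
    lambda_peak: float
    n_eff: float
    d: float
    theta: float = 0.0


def effective_index(d1: float, d2: float, n1: float, n2: float) -> float:
    """Volume-fraction effective index of one plate+gap period.

    n_eff = sqrt(n1² d1/d + n2² d2/d) with d = d1 + d2. This is the
    root-mean-square mixing rule appropriate for deep-subwavelength layering.
    """
    if d1 <= 0 or d2 < 0:
        raise ValueError(f"require d1 > 0 and d2 >= 0, got d1={d1}, d2={d2}")
    d = d1 + d2
    return math.sqrt((n1**2 * d1 + n2**2 * d2) / d)


def bragg_wavelength(d: float, n_eff: float, theta: float = 0.0, m: int = 1) -> float:
    """Bragg-Snell peak wavelength λ = (2d/m)·sqrt(n_eff² − sin²θ), nm.

    At normal incidence and first order this is exactly 2·n_eff·d. The peak
    blue-shifts with both the viewing angle θ (iridescence) and the order m.
    """
    if m < 1:
        raise ValueError(f"order m must be >= 1, got {m}")
    if d <= 0 or n_eff <= 0:
        raise ValueError("d and n_eff must be positive")
    s = math.sin(math.radians(theta))
    if s >= n_eff:
        raise ValueError(f"sin(theta)={s:.4f} >= n_eff={n_eff:.4f}: evanescent regime")
    return (2.0 * d / m) * math.sqrt(n_eff**2 - s**2)


def choose_order(
    d: float,
    n_eff: float,
    visible_range: Tuple[float, float] = VISIBLE_RANGE,
) -> Optional[int]:
    """Smallest reflection order m whose Bragg peak falls in the visible.

    Ammolite-scale periods (~150–200 nm) land in the visible at m = 1;
    the thicker abalone periods (~260–310 nm) only at m = 2. Returns None
    when no order lands in range (the m=1 peak is already too blue).
    """
    lo, hi = visible_range
    m = 1
    while True:
        lam = bragg_wavelength(d, n_eff, 0.0, m)
        if lam < lo:
            return None  # λ decreases with m; nothing further can land in range
        if lam <= hi:
            return m
        m += 1


def bragg_prediction(
    d1: float,
    d2: float,
    n1: float = 1.63,
    n2: float = 1.00,
    theta: float = 0.0,
    m: Optional[int] = None,
) -> BraggPrediction:
    """Convenience wrapper: n_eff + order selection + peak wavelength.

    If ``m`` is None the smallest visible-range order is chosen (falling
    back to m = 1 when none lands in the visible).
    """
    d = d1 + d2
    n_eff = effective_index(d1, d2, n1, n2)
    if m is None:
        m = choose_order(d, n_eff) or 1
    return BraggPrediction(
        m=m, lambda_peak=bragg_wavelength(d, n_eff, theta, m), n_eff=n_eff, d=d, theta=theta
    )


def single_gap_reflectance(
    d2: float, n1: float, n2: float, wavelength: float, theta: float = 0.0
) -> float:
    """Airy multiple-reflection reflectance of one interlamellar gap.

    A single film of index ``n2`` and thickness ``d2`` between semi-infinite
    media of index ``n1``: summing the internal multiple reflections gives

        R = |r (1 − e^{2iδ})|² / |1 − r² e^{2iδ}|²,   δ = 2π n2 d2 cosθ2 / λ,

    with r the single-interface Fresnel coefficient. R vanishes as d2 → 0
    (the two interface reflections cancel) and grows ∝ d2² while
    d2 ≪ λ/4n2 — the reason a 4 nm nanogap reflects only ~0.1% or less.
    Unpolarized: mean of s and p (identical at θ = 0).
    """
    if d2 < 0:
        raise ValueError(f"d2 must be >= 0, got {d2}")
    if d2 == 0:
        return 0.0
    s0 = n1 * math.sin(math.radians(theta))
    cos2 = np.sqrt(1.0 - (s0 / n2) ** 2 + 0j)
    delta = 2.0 * np.pi * n2 * d2 * cos2 / wavelength
    phase = np.exp(2j * delta)

    def _airy(pol: str) -> float:
        from .tmm import fresnel_interface

        r, _ = fresnel_interface(n1, n2, theta, pol)
        amp = r * (1.0 - phase) / (1.0 - r**2 * phase)
        return float(np.abs(amp) ** 2)

    return 0.5 * (_airy("s") + _airy("p"))


def effective_plane_count(r_gap: float) -> float:
    """Heuristic number of reflection planes the light reaches, ∝ 1/√R_gap.

    The amplitude reflected per gap is √R_gap, so coherent build-up to
    order-unity reflection engages ~1/√R_gap planes. Only the ordering
    matters (weaker gaps ⇒ deeper penetration ⇒ more planes ⇒ narrower
    band); the constant is set to 1.
    """
    if not 0.0 < r_gap < 1.0:
        raise ValueError(f"R_gap must be in (0, 1), got {r_gap}")
    return 1.0 / math.sqrt(r_gap)


def fwhm_vs_planes(
    spec: StackSpec,
    n_list: Sequence[int],
    wavelengths: Optional[np.ndarray] = None,
) -> list:
    """FWHM of the solved interference band versus number of periods.

    Builds ordered (zero-SD) stacks from ``spec`` with each period count in
    ``n_list``, solves them, and measures the band FWHM. The width falls
    with N until it saturates at the intrinsic stop-band width set by the
    index contrast. A band whose contrast (peak minus baseline) is below
    ``min_contrast`` — e.g. the residual interface fringes of a single
    period — is reported as unresolved (None).
    Returns ``[(N, fwhm_nm_or_None), ...]``.
    """
    from .colorimetry import peak_stats

    min_contrast = 0.05  # band must rise above the bare-interface fringe level
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, dtype=float)
    out = []
    for n in n_list:
        ordered = spec.with_(d1_sd=0.0, d2_sd=0.0, n_periods=int(n))
        spectrum = tmm_reflectance(sample_stack(ordered), wl, IncidenceGeometry())
        stats = peak_stats(spectrum)
        fwhm = stats.fwhm
        if fwhm is not None and stats.peak_reflectance - stats.baseline < min_contrast:
            fwhm = None
        out.append((int(n), fwhm))
    return out
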