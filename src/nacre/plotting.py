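"""Optional matplotlib views of spectra and chromaticities."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .colorimetry import CMF_5NM, spectrum_to_chromaticity, white_point
from .tmm import Spectrum


def plot_spectra(spectra: Sequence[Spectrum], labels: Optional[Sequence[str]] = None, ax=None):
    """Overlay reflectance spectra on one axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, sp in enumerate(spectra):
        label = labels[i] if labels else None
        ax.plot(sp.wavelengths, sp.values, label=label)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    ax.set_ylim(bottom=0)
    if labels:
        ax.legend()
    return ax


def plot_chromaticity(spectra: Sequence[Spectrum], labels: Optional[Sequence[str]] = None,
                      illuminant: str = "E", ax=None):
    """Spectra as points on the CIE 1931 (x, y) plane with the spectral locus."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    # spectral locus from the embedded CMF table
    s = CMF_5NM[:, 1:].sum(axis=1)
    keep = s > 1e-6
    ax.plot(CMF_5NM[keep, 1] / s[keep], CMF_5NM[keep, 2] / s[keep], "k-", lw=0.8)
    wx, wy = white_point(illuminant)
    ax.plot([wx], [wy], "k+", ms=10)
    for i, sp in enumerate(spectra):
        c = spectrum_to_chromaticity(sp, illuminant)
        label = labels[i] if labels else None
        ax.plot([c.x], [c.y], "o", label=label)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_aspect("equal")
    if labels:
        ax.legend()
    return ax
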