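"""CIE 1931 2° observer color-matching functions.

Analytic multi-lobe piecewise-Gaussian fit (Wyman, Sloan & Shirley, JCGT 2013),
accurate to about 1% of peak over the visible range. Used only to render
synthetic emission spectra into tristimulus values; exact-matrix colorimetry
(sRGB/D65) lives in :mod:`qdvision.colorimetry`.
"""

from __future__ import annotations

import numpy as np


def _lobe(lam: np.ndarray, mu: float, s_lo: float, s_hi: float, amp: float) -> np.ndarray:
    sigma = np.where(lam < mu, s_lo, s_hi)
    return amp * np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def cmf_xyz(wavelengths_nm) -> np.ndarray:
    """Evaluate (x̄, ȳ, z̄) at the given wavelengths.

    Parameters
    ----------
    wavelengths_nm : array_like
        Wavelengths in nanometres.

    Returns
    -------
    ndarray, shape (..., 3)
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    xbar = (
        _lobe(lam, 599.8, 37.9, 31.0, 1.056)
        + _lobe(lam, 442.0, 16.0, 26.7, 0.362)
        - _lobe(lam, 501.1, 20.4, 26.2, 0.065)
    )
    ybar = _lobe(lam, 568.8, 46.9, 40.5, 0.821) + _lobe(lam, 530.9, 16.3, 31.1, 0.286)
    zbar = _lobe(lam, 437.0, 11.8, 36.0, 1.217) + _lobe(lam, 459.0, 26.0, 13.8, 0.681)
    return np.stack([xbar, ybar, zbar], axis=-1)


def spectral_to_xyz(wavelengths_nm, radiance) -> np.ndarray:
    """Integrate a sampled spectral radiance against the CMFs (trapezoid rule).

    Returns an un-normalised (X, Y, Z) triple in the radiance's own units.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    rad = np.asarray(radiance, dtype=float)
    if lam.shape != rad.shape:
        raise ValueError("wavelengths and radiance must have the same shape")
    cmf = cmf_xyz(lam)
    return np.trapezoid(cmf * rad[:, None], lam, axis=0)
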