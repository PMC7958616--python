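"""Gaussian line-shape primitives shared by preprocessing and decomposition."""

from __future__ import annotations

import math

import numpy as np

#: FWHM = FWHM_OVER_SIGMA * sigma for a Gaussian: 2 sqrt(2 ln 2).
FWHM_OVER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.35482...

SQRT_2PI = math.sqrt(2.0 * math.pi)


def sigma_from_fwhm(fwhm: float) -> float:
    return fwhm / FWHM_OVER_SIGMA


def gaussian(x, center: float, fwhm: float, amplitude: float):
    """Amplitude-parameterized Gaussian: amplitude * exp(-(x-c)^2 / (2 sigma^2))."""
    s = sigma_from_fwhm(fwhm)
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-0.5 * ((x - center) / s) ** 2)


def gaussian_area(amplitude: float, fwhm: float) -> float:
    """Analytic area under an amplitude-parameterized Gaussian."""
    return amplitude * sigma_from_fwhm(fwhm) * SQRT_2PI
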