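"""Spectral preprocessing ahead of sub-band decomposition.

The water association band (WAB) sits on a background made of a constant
offset plus the low-frequency tail of the very strong CH stretching bands
(2800-3000 cm-1). That background is modeled as a constant plus a single
Gaussian tail, fitted over a high-wavenumber anchor window and the extreme
low-frequency edge of the WAB region where the sub-band contribution is
smallest, then subtracted pointwise. The residual band is area-normalized
over the WAB region because only the *relative* sub-band fractions are the
observable of interest — the total WAB area is only roughly proportional to
water content.

Also provided: a straight-baseline band-area integral used to monitor sample
water content via the nu2+nu3 water combination band (~5200 cm-1) during
drying, with a stabilization predicate on successive scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from wabkit.errors import DataError, FitError, RangeError
from wabkit.gaussians import gaussian
from wabkit.spectra_io import Spectrum


@dataclass(frozen=True)
class Region:
    """A wavenumber interval [lo, hi] in cm-1."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise DataError(f"region requires lo < hi, got ({self.lo}, {self.hi})")

    def contains(self, w: float) -> bool:
        return self.lo <= w <= self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: Default observation window of the water association band.
WAB_REGION = Region(2000.0, 2500.0)

#: Default background-fit anchor window on the high-wavenumber side.
ANCHOR_REGION = Region(2400.0, 2600.0)

#: Allowed range for the CH-stretch tail center.
TAIL_CENTER_BOUNDS = (2700.0, 3100.0)

#: Default relative band-area change below which drying is called stable.
STABILIZATION_TOL = 0.005


@dataclass(frozen=True)
class BackgroundModel:
    """Constant offset + Gaussian tail centered in the CH-stretch region."""

    offset: float
    tail_center: float
    tail_fwhm: float
    tail_amplitude: float

    def __post_init__(self):
        if self.tail_fwhm <= 0:
            raise DataError("tail_fwhm must be > 0")
        if self.tail_amplitude < 0:
            raise DataError("tail_amplitude must be >= 0")
        if self.tail_center < 2700.0:
            raise DataError("tail_center must lie on the CH-stretch side (>= 2700 cm-1)")

    def evaluate(self, w) -> np.ndarray:
        return self.offset + gaussian(w, self.tail_center, self.tail_fwhm, self.tail_amplitude)


def _region_mask(spectrum: Spectrum, region: Region) -> np.ndarray:
    w = spectrum.wavenumbers
    return (w >= region.lo) & (w <= region.hi)


def fit_background(
    spectrum: Spectrum,
    wab_region: Region = WAB_REGION,
    anchor_region: Region = ANCHOR_REGION,
    tail_center_bounds: tuple[float, float] = TAIL_CENTER_BOUNDS,
    n_edge_points: int = 0,
    max_iterations: int = 2000,
) -> BackgroundModel:
    """Fit the constant + Gaussian-tail background model.

    The fit support is ``anchor_region``: the band-free window between the
    WAB (sub-bands end near 2270 cm-1) and the CH-stretch bands, where the
    tail's curvature separates it from the constant offset. Offset, tail
    center, width and amplitude are fitted jointly by bounded least squares.
    ``n_edge_points`` optionally adds that many lowest-wavenumber samples of
    ``wab_region`` to the support; this is only safe when the band truly
    vanishes at its low edge — a strongly populated W0a sub-band at the
    2000 cm-1 edge biases the offset badly, so the default is 0.
    """
    if not spectrum.covers(anchor_region.lo, anchor_region.hi):
        raise RangeError(
            f"anchor region ({anchor_region.lo}, {anchor_region.hi}) outside "
            f"data span {spectrum.span}"
        )
    if not spectrum.covers(wab_region.lo, wab_region.hi):
        raise RangeError(
            f"WAB region ({wab_region.lo}, {wab_region.hi}) outside data span {spectrum.span}"
        )
    anchor = _region_mask(spectrum, anchor_region)
    edge_idx = np.flatnonzero(_region_mask(spectrum, wab_region))[:n_edge_points]
    support = anchor.copy()
    support[edge_idx] = True
    w = spectrum.wavenumbers[support]
    y = spectrum.absorbance[support]

    tc_lo, tc_hi = tail_center_bounds
    y_min = float(np.min(y))
    amp0 = max(float(np.max(y)) - y_min, 0.0)
    x0 = np.array([y_min, 0.5 * (tc_lo + tc_hi), 200.0, amp0])
    lb = np.array([-np.inf, tc_lo, 20.0, 0.0])
    ub = np.array([np.inf, tc_hi, 2000.0, np.inf])

    def resid(p):
        off, tc, fw, amp = p
        return off + gaussian(w, tc, fw, amp) - y

    def jac(p):
        off, tc, fw, amp = p
        s = fw / 2.3548200450309493
        z = (w - tc) / s
        g = np.exp(-0.5 * z**2)
        d_off = np.ones_like(w)
        d_tc = amp * g * z / s
        d_fw = amp * g * z**2 / fw
        d_amp = g
        return np.column_stack([d_off, d_tc, d_fw, d_amp])

    sol = least_squares(
        resid, x0, jac=jac, bounds=(lb, ub),
        ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=max_iterations,
    )
    if sol.status <= 0:
        raise FitError(
            "background fit did not converge",
            diagnostics={"status": sol.status, "message": sol.message, "nfev": sol.nfev,
                         "cost": sol.cost},
        )
    off, tc, fw, amp = sol.x
    return BackgroundModel(float(off), float(tc), float(fw), float(max(amp, 0.0)))


def subtract_background(spectrum: Spectrum, bg: BackgroundModel) -> Spectrum:
    """Pointwise subtraction of the evaluated background; metadata preserved.

    Negative residual values are kept, not clipped — downstream
    normalization will flag a genuinely non-positive band.
    """
    return spectrum.with_absorbance(spectrum.absorbance - bg.evaluate(spectrum.wavenumbers))


def extract_region(spectrum: Spectrum, region: Region) -> Spectrum:
    """Restrict a spectrum to the grid points inside ``region``."""
    if not spectrum.covers(region.lo, region.hi):
        raise RangeError(f"region ({region.lo}, {region.hi}) outside data span {spectrum.span}")
    mask = _region_mask(spectrum, region)
    return Spectrum(spectrum.wavenumbers[mask], spectrum.absorbance[mask], spectrum.meta)


def region_area(spectrum: Spectrum, region: Region) -> float:
    """Signed trapezoidal area over ``region`` (endpoints interpolated)."""
    if not spectrum.covers(region.lo, region.hi):
        raise RangeError(f"region ({region.lo}, {region.hi}) outside data span {spectrum.span}")
    inside = _region_mask(spectrum, region)
    w_in = spectrum.wavenumbers[inside]
    x = np.concatenate(([region.lo], w_in[(w_in > region.lo) & (w_in < region.hi)], [region.hi]))
    y = spectrum.interp(x)
    return float(np.trapezoid(y, x))


def normalize_area(spectrum: Spectrum, region: Region = WAB_REGION) -> Spectrum:
    """Divide absorbance by the trapezoidal area over ``region``.

    Idempotent and scale-invariant; the result integrates to 1 over
    ``region``. A non-positive area signals an empty or negative band and
    raises :class:`~wabkit.errors.DataError`.
    """
    area = region_area(spectrum, region)
    if area <= 0:
        raise DataError(f"non-positive band area ({area}) over ({region.lo}, {region.hi})")
    return spectrum.with_absorbance(spectrum.absorbance / area)


def band_area(spectrum: Spectrum, region: Region) -> float:
    """Trapezoidal band area above a straight baseline through the region endpoints.

    Used to monitor the nu2+nu3 water combination band during drying; units
    absorbance * cm-1.
    """
    if not spectrum.covers(region.lo, region.hi):
        raise RangeError(f"region ({region.lo}, {region.hi}) outside data span {spectrum.span}")
    inside = _region_mask(spectrum, region)
    w_in = spectrum.wavenumbers[inside]
    x = np.concatenate(([region.lo], w_in[(w_in > region.lo) & (w_in < region.hi)], [region.hi]))
    y = spectrum.interp(x)
    y_lo, y_hi = y[0], y[-1]
    baseline = y_lo + (y_hi - y_lo) * (x - region.lo) / (region.hi - region.lo)
    return float(np.trapezoid(y - baseline, x))


def is_stabilized(area_prev: float, area_current: float, tol: float = STABILIZATION_TOL) -> bool:
    """True when the relative band-area change between successive scans < tol.

    The denominator is the previous scan's area; two zero areas count as
    stable.
    """
    if area_prev == 0.0:
        return area_current == 0.0
    return abs(area_current - area_prev) / abs(area_prev) < tol
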