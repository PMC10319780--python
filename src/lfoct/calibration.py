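"""Emission-line wavelength calibration of the spectral axis.

The pixel -> wavelength map of the spectrograph is established from a set
of known emission lines (e.g. an argon lamp recorded through the slit):
peak pixel positions paired with catalogue wavelengths are fitted with a
low-degree polynomial, and the per-line FWHM measured from the same
spectrum gives the realized spectral resolution across the band.  Line
wavelengths are supplied by the user as a CSV (columns ``pixel,
wavelength_nm``); no lamp catalogue is built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.optimize import curve_fit

from . import system
from .forward_sim import SpectrographModel, wavelength_grid

__all__ = ["CalibrationTable", "fit_wavelength_map", "measure_line_fwhm",
           "LineWidth"]


@dataclass
class CalibrationTable:
    """Pixel -> wavelength polynomial with fit diagnostics.

    Attributes
    ----------
    poly
        ``numpy.polynomial.Polynomial`` mapping pixel index to nm,
        strictly monotonic over ``[0, n_pixels)``.
    line_list
        The ``(pixel, wavelength_nm)`` pairs the fit used (empty for a
        nominal grid).
    residual_rms_nm
        RMS of the fit residuals at the line positions.
    sampling_interval_nm
        Mean local derivative d(lambda)/d(pixel) over the pixel range.
    line_fwhm_nm
        Optional per-line measured FWHM resolution, keyed by wavelength.
    """

    poly: Polynomial
    n_pixels: int
    line_list: list[tuple[float, float]] = field(default_factory=list)
    residual_rms_nm: float = 0.0
    sampling_interval_nm: float = 0.0
    line_fwhm_nm: dict[float, float] = field(default_factory=dict)

    def wavelengths(self, pixels: np.ndarray | None = None) -> np.ndarray:
        """Wavelength (nm) at the given pixel indices (default: full axis)."""
        if pixels is None:
            pixels = np.arange(self.n_pixels)
        return self.poly(np.asarray(pixels, dtype=float))

    def derivative_nm_per_px(self, pixels: np.ndarray) -> np.ndarray:
        return self.poly.deriv()(np.asarray(pixels, dtype=float))

    @classmethod
    def from_grid(cls, spectrograph: SpectrographModel | None = None,
                  binning: int = 1) -> "CalibrationTable":
        """Nominal linear calibration from the spectrograph design values."""
        sg = spectrograph or SpectrographModel()
        lam = wavelength_grid(sg, binning=binning)
        poly = Polynomial([lam[0], lam[1] - lam[0]])
        return cls(poly=poly, n_pixels=lam.size,
                   sampling_interval_nm=lam[1] - lam[0])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "poly_coeffs": [float(c) for c in self.poly.coef],
            "n_pixels": int(self.n_pixels),
            "line_list": [[float(p), float(w)] for p, w in self.line_list],
            "residual_rms_nm": float(self.residual_rms_nm),
            "sampling_interval_nm": float(self.sampling_interval_nm),
            "line_fwhm_nm": {float(k): float(v)
                             for k, v in self.line_fwhm_nm.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTable":
        return cls(poly=Polynomial(np.asarray(d["poly_coeffs"], dtype=float)),
                   n_pixels=int(d["n_pixels"]),
                   line_list=[tuple(x) for x in d.get("line_list", [])],
                   residual_rms_nm=float(d.get("residual_rms_nm", 0.0)),
                   sampling_interval_nm=float(d.get("sampling_interval_nm", 0.0)),
                   line_fwhm_nm={float(k): float(v) for k, v in
                                 d.get("line_fwhm_nm", {}).items()})


def fit_wavelength_map(peaks: Sequence[tuple[float, float]],
                       degree: int = 3,
                       n_pixels: int = system.N_SPECTRAL_PIXELS
                       ) -> CalibrationTable:
    """Least-squares pixel -> wavelength polynomial from emission-line peaks.

    Parameters
    ----------
    peaks
        ``(pixel, known_wavelength_nm)`` pairs; at least ``degree + 1``
        lines with distinct pixel positions.
    degree
        Polynomial degree (default 3).

    Raises
    ------
    ValueError
        If the system is underdetermined, pixels repeat, or the fitted
        map is not strictly monotonic over the pixel range.
    """
    peaks = [(float(p), float(w)) for p, w in peaks]
    if len(peaks) < degree + 1:
        raise ValueError(
            f"need at least degree+1 = {degree + 1} lines, got {len(peaks)}")
    px = np.array([p for p, _ in peaks])
    wl = np.array([w for _, w in peaks])
    if np.unique(px).size != px.size:
        raise ValueError("line pixel positions must be distinct")

    poly = Polynomial.fit(px, wl, deg=degree).convert()
    grid = np.arange(n_pixels, dtype=float)
    deriv = poly.deriv()(grid)
    if not (np.all(deriv > 0) or np.all(deriv < 0)):
        raise ValueError("fitted wavelength map is not monotonic over the "
                         "pixel range")
    resid = poly(px) - wl
    return CalibrationTable(
        poly=poly,
        n_pixels=n_pixels,
        line_list=peaks,
        residual_rms_nm=float(np.sqrt(np.mean(resid ** 2))),
        sampling_interval_nm=float(np.mean(np.abs(deriv))),
    )


class LineWidth(NamedTuple):
    """Result of a single-line FWHM measurement."""

    fwhm_nm: float
    center_px: float
    under_resolved: bool


def _gauss(x, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def measure_line_fwhm(spectrum: np.ndarray, approx_pixel: int,
                      calib: CalibrationTable | None = None,
                      search_px: int = 10, window_px: int = 5) -> LineWidth:
    """Measure one emission line's FWHM in nm by a windowed Gaussian fit.

    The peak is located as the sample maximum within ``search_px`` of
    ``approx_pixel``, refined by parabolic interpolation of the three
    highest samples, then fitted with a Gaussian over a ``+-window_px``
    window.  The pixel-domain FWHM is converted to nm through the local
    calibration derivative.  A width at or below one sampling interval is
    flagged under-resolved (the optical line is narrower than the
    instrument can measure).

    The measurement is invariant to amplitude scaling of the spectrum.
    """
    calib = calib or CalibrationTable.from_grid()
    y = np.asarray(spectrum, dtype=float)
    n = y.size
    lo = max(int(approx_pixel) - search_px, 1)
    hi = min(int(approx_pixel) + search_px + 1, n - 1)
    if hi <= lo:
        raise ValueError("approx_pixel too close to the spectrum edge")
    p = lo + int(np.argmax(y[lo:hi]))
    if not (y[p] >= y[p - 1] and y[p] >= y[p + 1]) or y[p] <= 0:
        raise ValueError(f"no local maximum near pixel {approx_pixel}")

    # parabolic refinement of the apex from the 3 highest samples
    denom = y[p - 1] - 2.0 * y[p] + y[p + 1]
    shift = 0.0 if denom == 0 else 0.5 * (y[p - 1] - y[p + 1]) / denom
    center = p + float(np.clip(shift, -1.0, 1.0))

    wlo = max(p - window_px, 0)
    whi = min(p + window_px + 1, n)
    xs = np.arange(wlo, whi, dtype=float)
    ys = y[wlo:whi]
    base = float(ys.min())
    amp0 = float(y[p] - base)
    if amp0 <= 0:
        raise ValueError("line has no amplitude above the local baseline")
    try:
        popt, _ = curve_fit(_gauss, xs, ys, p0=(amp0, center, 1.0, base),
                            maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise ValueError(f"Gaussian fit failed near pixel {p}") from exc
    amp, mu, sigma, _ = popt
    sigma = abs(float(sigma))
    if amp <= 0 or sigma == 0 or not np.isfinite(sigma):
        raise ValueError("Gaussian fit returned a non-physical line shape")
    fwhm_px = sigma / system.FWHM_TO_SIGMA
    d_nm = float(np.abs(calib.derivative_nm_per_px(np.array([mu]))[0]))
    under = fwhm_px <= 1.0
    fwhm_nm = min(fwhm_px, 1.0) * d_nm if under else fwhm_px * d_nm
    return LineWidth(fwhm_nm=float(fwhm_nm), center_px=float(mu),
                     under_resolved=bool(under))


def read_line_list(path) -> list[tuple[float, float]]:
    """Read an emission-line CSV with columns ``pixel, wavelength_nm``."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "pixel" not in cols or "wavelength_nm" not in cols:
        raise ValueError("line list CSV needs columns 'pixel' and 'wavelength_nm'")
    return list(zip(df[cols["pixel"]].astype(float),
                    df[cols["wavelength_nm"]].astype(float)))
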