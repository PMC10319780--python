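"""System performance metrology: axial PSF, sensitivity, roll-off.

Conventions: amplitudes are compared with ``20 log10``; power-like
roll-off of squared magnitudes with ``10 log10``.  The analytic roll-off
model is the standard spectrometer-based form — a sinc^2 pixel-
integration factor times a Gaussian finite-resolution factor::

    R(z) = sinc^2(zeta * pi / 2) * exp(-w^2 pi^2 zeta^2 / (8 ln 2))

with ``zeta = z / z_max`` and ``w = dlambda_res / dlambda_s``.  The
simulator produces the same roll-off *emergently* (resolution-kernel
convolution plus subpixel integration), so agreement between
:func:`rolloff_curve` and :func:`analytic_rolloff` is a cross-check of
the forward model, not a tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import system
from .calibration import CalibrationTable
from .forward_sim import CameraModel, SourceSpectrum, SpectrographModel, \
    simulate_background, simulate_frame
from .phantom import make_mirror_phantom
from .recon import BScan, process_frame

__all__ = [
    "theoretical_axial_resolution",
    "measure_axial_psf_fwhm",
    "SensitivityResult",
    "measure_sensitivity",
    "RollOffCurve",
    "rolloff_curve",
    "analytic_rolloff",
]


def theoretical_axial_resolution(center_nm: float, fwhm_nm: float) -> float:
    """Coherence-length axial resolution (um, in air) of a Gaussian source.

    ``dz = (2 ln 2 / pi) * lambda_0^2 / dlambda``.
    """
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be > 0")
    return (2.0 * math.log(2.0) / math.pi) * center_nm ** 2 / fwhm_nm * 1e-3


def _gauss(x, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def measure_axial_psf_fwhm(bscan: BScan, min_depth_um: float = 100.0) -> float:
    """Gaussian-fit FWHM (um) of the axial point-spread function.

    Averages the A-scans of a mirror B-scan into one linear-magnitude
    depth profile, locates the dominant peak beyond ``min_depth_um`` (the
    first few bins hold the residual sample-arm DC hump), and fits a
    Gaussian to the contiguous region above 5% of the peak.  The fitted
    width converts to micrometres through the depth scale; zero padding
    at reconstruction refines the sampling of the fit.

    Raises
    ------
    ValueError
        If no peak stands clearly above the background.
    """
    profile = bscan.amplitude.mean(axis=0)
    z0 = int(min_depth_um / bscan.depth_scale_um_per_bin)
    if z0 >= profile.size - 3:
        raise ValueError("min_depth_um leaves no depth range to search")
    p = z0 + int(np.argmax(profile[z0:]))
    peak = float(profile[p])
    floor = float(np.median(profile))
    if peak <= 0 or peak < 5.0 * max(floor, np.finfo(float).tiny):
        raise ValueError("no dominant peak above the noise floor")
    thresh = floor + 0.05 * (peak - floor)
    lo = p
    while lo > 0 and profile[lo - 1] > thresh:
        lo -= 1
    hi = p
    while hi < profile.size - 1 and profile[hi + 1] > thresh:
        hi += 1
    xs = np.arange(lo, hi + 1, dtype=float)
    ys = profile[lo:hi + 1]
    if xs.size >= 6:
        popt, _ = curve_fit(_gauss, xs, ys,
                            p0=(peak - floor, float(p), (hi - lo) / 4.0, floor),
                            maxfev=10000)
    else:
        # coarse sampling (no zero padding): too few points above the
        # threshold for a 4-parameter fit; drop the offset term
        if xs.size < 4:
            raise ValueError("peak too narrow to fit (increase zero padding)")
        popt, _ = curve_fit(lambda x, a, m, s: _gauss(x, a, m, s, 0.0),
                            xs, ys, p0=(peak, float(p), (hi - lo) / 2.0),
                            maxfev=10000)
    sigma = abs(float(popt[2]))
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError("Gaussian fit returned a non-physical PSF width")
    return sigma / system.FWHM_TO_SIGMA * bscan.depth_scale_um_per_bin


class SensitivityResult(NamedTuple):
    """Sensitivity in dB and whether the image was noise-free."""

    db: float
    noise_free: bool


def measure_sensitivity(bscan: BScan, attenuation_db: float = 0.0,
                        peak_exclude_bins: int = 10,
                        min_depth_um: float = 100.0) -> SensitivityResult:
    """System sensitivity from an attenuated mirror measurement.

    ``20 log10(peak / noise-floor SD) + attenuation_db`` with the noise
    floor taken from the deepest 20% of depth bins, excluding the peak
    ``+- peak_exclude_bins``.  The peak search starts beyond
    ``min_depth_um`` to skip the residual DC hump.  A noise-free
    reconstruction (no camera noise simulated, or an exactly zero floor)
    returns ``inf`` flagged ``noise_free`` — its residual floor is FFT
    leakage, not noise, so a finite figure would be meaningless.
    """
    profile = bscan.amplitude.mean(axis=0)
    nz = profile.size
    z0 = min(int(min_depth_um / bscan.depth_scale_um_per_bin), nz - 2)
    p = z0 + int(np.argmax(profile[z0:]))
    peak = float(profile[p])
    sel = np.zeros(nz, dtype=bool)
    sel[int(0.8 * nz):] = True
    sel[max(p - peak_exclude_bins, 0):p + peak_exclude_bins + 1] = False
    floor = bscan.amplitude[:, sel]
    sd = float(floor.std())
    if sd == 0.0 or not bscan.noise_on:
        return SensitivityResult(float("inf"), True)
    if peak <= sd:
        raise ValueError("mirror peak does not stand above the noise floor")
    return SensitivityResult(20.0 * math.log10(peak / sd) + attenuation_db,
                             False)


@dataclass
class RollOffCurve:
    """Measured sensitivity roll-off vs depth, 0 dB at the shallowest point."""

    opd_um: np.ndarray
    rolloff_db: np.ndarray
    sampling_interval_nm: float
    resolution_fwhm_nm: float
    center_nm: float

    def analytic_db(self) -> np.ndarray:
        """The analytic model evaluated at the measured depths, re-normalized
        to 0 dB at the first depth (same convention as the measurement)."""
        model = np.array([
            analytic_rolloff(z, self.sampling_interval_nm,
                             self.resolution_fwhm_nm, self.center_nm)
            for z in self.opd_um])
        return model - model[0]


def rolloff_curve(opd_list: Sequence[float],
                  source: SourceSpectrum | None = None,
                  spectrograph: SpectrographModel | None = None,
                  camera: CameraModel | None = None,
                  zero_pad_factor: int = 8,
                  n_ascans: int = 4,
                  oversample: int = 4) -> RollOffCurve:
    """Simulate + reconstruct a mirror at each OPD and record the peak decay.

    Noise-free frames, rectangular window (so the peak magnitude is the
    fringe amplitude), strong zero padding (so peak-bin scalloping is
    negligible).  Roll-off is reported in power dB relative to the
    shallowest depth: ``20 log10(peak(z) / peak(z_0))``.
    """
    source = source or SourceSpectrum()
    spectrograph = spectrograph or SpectrographModel()
    camera = camera or CameraModel()
    calib = CalibrationTable.from_grid(spectrograph)
    z_max = spectrograph.nyquist_depth_um()
    opds = np.asarray(sorted(opd_list), dtype=float)
    if np.any(opds >= z_max) or np.any(opds <= 0):
        raise ValueError(f"OPDs must lie in (0, {z_max:.0f}) um")

    background = simulate_background(n_ascans, source, spectrograph, camera,
                                     noise_on=False)
    peaks = []
    for opd in opds:
        ph = make_mirror_phantom(opd, n_ascans=n_ascans,
                                 max_depth_um=z_max)
        frame = simulate_frame(ph, 0, source, spectrograph, camera,
                               noise_on=False, oversample=oversample)
        bscan = process_frame(frame, background, calib,
                              zero_pad_factor=zero_pad_factor, window="rect")
        profile = bscan.amplitude.mean(axis=0)
        # search near the known mirror depth so the residual DC hump and
        # deep-depth noise cannot masquerade as the peak
        c = int(opd / bscan.depth_scale_um_per_bin)
        margin = 20 * zero_pad_factor
        peaks.append(float(profile[max(c - margin, 0):c + margin].max()))
    peaks = np.asarray(peaks)
    rolloff = 20.0 * np.log10(peaks / peaks[0])
    return RollOffCurve(
        opd_um=opds, rolloff_db=rolloff,
        sampling_interval_nm=spectrograph.sampling_interval_nm,
        resolution_fwhm_nm=spectrograph.resolution_fwhm_nm,
        center_nm=0.5 * (spectrograph.lambda_min_nm + spectrograph.lambda_max_nm))


def analytic_rolloff(z_um: float, sampling_interval_nm: float,
                     resolution_fwhm_nm: float, center_nm: float) -> float:
    """Analytic spectrometer roll-off at depth ``z_um``, in power dB (<= 0).

    ``10 log10( sinc^2(zeta pi / 2) * exp(-w^2 pi^2 zeta^2 / (8 ln 2)) )``
    with ``zeta = z / z_max``, ``z_max = lambda_0^2 / (4 dlambda_s)`` and
    ``w = dlambda_res / dlambda_s``.
    """
    z_max = system.nyquist_depth_um(sampling_interval_nm, center_nm)
    if z_um >= z_max:
        raise ValueError(f"depth {z_um} um is at or beyond z_max {z_max:.0f} um")
    zeta = z_um / z_max
    w = resolution_fwhm_nm / sampling_interval_nm
    sinc_term = np.sinc(zeta / 2.0) ** 2          # np.sinc(x) = sin(pi x)/(pi x)
    gauss_term = math.exp(-(w ** 2) * math.pi ** 2 * zeta ** 2
                          / (8.0 * math.log(2.0)))
    return 10.0 * math.log10(sinc_term * gauss_term)
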