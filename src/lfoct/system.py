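"""Nominal optical parameters of the modelled line-field FD-OCT instrument.

These constants describe the as-built system the package emulates: a
superluminescent-diode source imaged through a transmission-grating
spectrograph onto a 2D machine-vision camera, with one camera axis spectral
and the other spatial (the illumination line).  Every default elsewhere in
the package derives from the values collected here.
"""

from __future__ import annotations

import math

# --- spectrograph ---------------------------------------------------------
LAMBDA_MIN_NM: float = 796.0     #: shortest wavelength on the spectral axis
LAMBDA_MAX_NM: float = 879.0     #: longest wavelength on the spectral axis
N_SPECTRAL_PIXELS: int = 1920    #: camera pixels along the spectral axis
N_SPATIAL_PIXELS: int = 1200     #: camera pixels along the line (spatial) axis
N_ILLUMINATED: int = 850         #: spatial pixels covered by the line focus
RESOLUTION_FWHM_NM: float = 0.08  #: practical (two-pixel) spectral resolution

# --- source ---------------------------------------------------------------
SOURCE_CENTER_NM: float = 833.0
SOURCE_FWHM_NM: float = 40.0
SOURCE_POWER_MW: float = 1.8     #: illumination power on the sample

# --- camera ---------------------------------------------------------------
FULL_WELL_E: float = 30000.0
BIT_DEPTH: int = 12
READ_NOISE_E: float = 7.0
EXPOSURE_MS: float = 0.5
FRAME_RATE_FPS: float = 120.0

FWHM_TO_SIGMA: float = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def sampling_interval_nm(lambda_min_nm: float = LAMBDA_MIN_NM,
                         lambda_max_nm: float = LAMBDA_MAX_NM,
                         n_pixels: int = N_SPECTRAL_PIXELS) -> float:
    """Per-pixel wavelength sampling interval of the spectrograph in nm.

    Uses the half-open grid convention ``lambda(p) = lambda_min + p * d``
    with ``d = (lambda_max - lambda_min) / n_pixels``, which makes the
    nominal interval (879 - 796) / 1920 = 0.0432 nm round to the quoted
    0.04 nm.
    """
    return (lambda_max_nm - lambda_min_nm) / n_pixels


def practical_resolution_nm(lambda_min_nm: float = LAMBDA_MIN_NM,
                            lambda_max_nm: float = LAMBDA_MAX_NM,
                            n_pixels: int = N_SPECTRAL_PIXELS) -> float:
    """Two-pixel (Airy-disk sampled) spectral resolution in nm.

    The optical spot covers two camera pixels, so the usable resolution is
    twice the sampling interval, quoted at the printed two-decimal
    precision of the interval (2 x 0.04 nm = 0.08 nm).
    """
    return 2.0 * round(sampling_interval_nm(lambda_min_nm, lambda_max_nm,
                                            n_pixels), 2)


def band_center_nm(lambda_min_nm: float = LAMBDA_MIN_NM,
                   lambda_max_nm: float = LAMBDA_MAX_NM) -> float:
    """Centre wavelength of the detected band in nm."""
    return 0.5 * (lambda_min_nm + lambda_max_nm)


def nyquist_depth_um(sampling_nm: float | None = None,
                     center_nm: float | None = None) -> float:
    """Maximum unambiguous (Nyquist) imaging depth ``lambda0^2/(4 dlambda)``.

    Parameters
    ----------
    sampling_nm
        Spectral sampling interval; defaults to the nominal grid interval.
    center_nm
        Centre wavelength of the band; defaults to the nominal band centre.

    Returns
    -------
    float
        One-sided depth range in micrometres (air equivalent).
    """
    if sampling_nm is None:
        sampling_nm = sampling_interval_nm()
    if center_nm is None:
        center_nm = band_center_nm()
    return center_nm ** 2 / (4.0 * sampling_nm) * 1e-3
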