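"""Layered test objects with exact ground truth.

A :class:`Phantom` is an ordered stack of :class:`Layer` objects below a
height-mapped first surface, sampled on the lateral scan grid
``(b, y)`` = (B-scan index, A-scan position on the illumination line).
Each layer contributes one interface (its top); the last layer is treated
as semi-infinite and only its top reflects.  Layers may carry random
sub-resolution scatterers which give the reconstructed images speckle.

Presets reproduce the measured objects used to characterize the modelled
instrument: a multi-layer cornea (epithelium / stroma / endothelium), a
conformally coated PCB with raised resistors, a periodic adhesive-tape
stack, and a single mirror reflector for metrology.

All depths are optical path differences (OPD) in micrometres, air
equivalent; layer thicknesses are geometric micrometres, converted to
optical path through the layer's group index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import system

__all__ = [
    "Layer",
    "Phantom",
    "GroundTruth",
    "make_mirror_phantom",
    "make_cornea_phantom",
    "make_pcb_phantom",
    "make_tape_phantom",
]


@dataclass(frozen=True)
class Layer:
    """One layer of a phantom.

    Parameters
    ----------
    name
        Layer label, used as the key in ground-truth thickness maps.
    thickness_um
        Geometric thickness in um; scalar or an array over the lateral
        grid ``(b, y)``.  ``np.inf`` marks a semi-infinite terminating
        layer (allowed only in the last position, and only without
        scatterers).
    group_index
        Group refractive index (>= 1); converts geometric thickness to
        optical path.
    top_reflectivity
        Fractional *amplitude* reflectance of the layer's upper interface,
        in [0, 1]; scalar or lateral array.
    scatter_amplitude
        Mean amplitude of random sub-resolution scatterers inside the
        layer; 0 disables speckle.
    scatterers_per_ascan
        Number of scatterers drawn per A-scan column within this layer.
    """

    name: str
    thickness_um: float | np.ndarray
    group_index: float = 1.0
    top_reflectivity: float | np.ndarray = 0.0
    scatter_amplitude: float = 0.0
    scatterers_per_ascan: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.thickness_um, dtype=float)
        if not np.all(t > 0):
            raise ValueError(f"layer {self.name!r}: thickness must be > 0 everywhere")
        if self.group_index < 1.0:
            raise ValueError(f"layer {self.name!r}: group_index must be >= 1")
        r = np.asarray(self.top_reflectivity, dtype=float)
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError(f"layer {self.name!r}: top_reflectivity must lie in [0, 1]")
        if self.scatter_amplitude < 0:
            raise ValueError(f"layer {self.name!r}: scatter_amplitude must be >= 0")
        if (self.scatter_amplitude > 0 and self.scatterers_per_ascan > 0
                and not np.all(np.isfinite(t))):
            raise ValueError(f"layer {self.name!r}: scattering layers need finite thickness")


@dataclass
class GroundTruth:
    """Exact interface depths and layer thicknesses of a phantom.

    Attributes
    ----------
    interface_depth_um
        Array ``(n_bscans, n_ascans, n_interfaces)`` of optical depth
        (air-equivalent um relative to zero OPD), strictly increasing
        along the last axis.
    thickness_um
        Mapping layer name -> geometric thickness array ``(b, y)`` for
        every layer above the terminating one.
    labels
        Optional ``(b, y)`` array of region labels (e.g. ``"resistor"`` /
        ``"mask"`` for the PCB preset).
    """

    interface_depth_um: np.ndarray
    thickness_um: dict[str, np.ndarray]
    labels: np.ndarray | None = None

    def to_csv(self, path) -> None:
        """Export interface depths as CSV with columns b, y, interface, depth_um."""
        nb, ny, ni = self.interface_depth_um.shape
        b, y, i = np.meshgrid(np.arange(nb), np.arange(ny), np.arange(ni),
                              indexing="ij")
        pd.DataFrame({
            "b": b.ravel(),
            "y": y.ravel(),
            "interface": i.ravel(),
            "depth_um": self.interface_depth_um.ravel(),
        }).to_csv(path, index=False)


@dataclass
class Phantom:
    """Layered sample on a lateral ``(b, y)`` grid.

    ``surface_height_um`` is the height of the first interface above the
    reference plane at ``base_opd_um``: positive height moves the surface
    closer to the probe (smaller OPD).  Interface ``i`` then lies at::

        z_0(b, y) = base_opd_um - surface_height_um(b, y) * ambient_index
        z_{i+1}   = z_i + thickness_i * group_index_i
    """

    layers: list[Layer]
    surface_height_um: np.ndarray
    base_opd_um: float
    lateral_extent_mm: tuple[float, float] = (4.0, 4.0)
    ambient_index: float = 1.0
    seed: int = 0
    labels: np.ndarray | None = None
    max_depth_um: float | None = None
    _scatterers: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = field(
        init=False, repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        self.surface_height_um = np.atleast_2d(
            np.asarray(self.surface_height_um, dtype=float))
        for lay in self.layers[:-1]:
            if not np.all(np.isfinite(np.asarray(lay.thickness_um, dtype=float))):
                raise ValueError("only the last layer may be semi-infinite")
        depth = self.interface_depth_um()
        if np.any(depth[..., 0] <= 0):
            raise ValueError("first interface must lie at positive OPD "
                             "(zero OPD is the DC term)")
        limit = self.max_depth_um
        if limit is None:
            limit = system.nyquist_depth_um()
        if np.any(depth[..., -1] >= limit):
            raise ValueError(
                f"deepest interface ({np.max(depth[..., -1]):.1f} um) exceeds "
                f"the imaging depth range ({limit:.1f} um)")
        self._draw_scatterers()

    # -- geometry ----------------------------------------------------------

    @property
    def n_bscans(self) -> int:
        return self.surface_height_um.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.surface_height_um.shape[1]

    @property
    def n_interfaces(self) -> int:
        return len(self.layers)

    def interface_depth_um(self) -> np.ndarray:
        """Optical depth of every interface, shape ``(b, y, n_interfaces)``."""
        nb, ny = self.surface_height_um.shape
        z = np.empty((nb, ny, len(self.layers)))
        z[..., 0] = self.base_opd_um - self.surface_height_um * self.ambient_index
        for i, lay in enumerate(self.layers[:-1]):
            t = np.broadcast_to(np.asarray(lay.thickness_um, dtype=float), (nb, ny))
            z[..., i + 1] = z[..., i] + t * lay.group_index
        return z

    def ground_truth(self) -> GroundTruth:
        thick = {
            lay.name: np.broadcast_to(
                np.asarray(lay.thickness_um, dtype=float),
                self.surface_height_um.shape).copy()
            for lay in self.layers[:-1]
        }
        return GroundTruth(self.interface_depth_um(), thick, self.labels)

    # -- scatterers --------------------------------------------------------

    def _draw_scatterers(self) -> None:
        """Draw sub-resolution scatterers once, deterministically from seed.

        Each scattering layer gets `scatterers_per_ascan` reflectors per
        column with uniform depth fraction, Rayleigh amplitude of the
        requested mean, and uniform extra phase.
        """
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5CA7]))
        nb, ny = self.surface_height_um.shape
        self._scatterers = []
        for li, lay in enumerate(self.layers):
            n = lay.scatterers_per_ascan
            if lay.scatter_amplitude <= 0 or n <= 0:
                continue
            u = rng.random((nb, ny, n))
            amp = rng.rayleigh(scale=lay.scatter_amplitude / np.sqrt(np.pi / 2.0),
                               size=(nb, ny, n))
            phi = rng.uniform(0.0, 2.0 * np.pi, size=(nb, ny, n))
            self._scatterers.append((li, u, amp, phi))

    def emitters(self, b: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All reflectors of B-scan ``b`` as per-row arrays.

        Returns
        -------
        z, a, phi : ndarray, shape ``(n_ascans, n_emitters)``
            Optical depth (um), amplitude reflectance and extra phase of
            every interface and scatterer, per A-scan row.
        """
        if not 0 <= b < self.n_bscans:
            raise IndexError(f"B-scan index {b} outside [0, {self.n_bscans})")
        nb, ny = self.surface_height_um.shape
        depth = self.interface_depth_um()[b]                     # (y, L)
        refl = np.stack([
            np.broadcast_to(np.asarray(lay.top_reflectivity, dtype=float),
                            (nb, ny))[b]
            for lay in self.layers], axis=1)                     # (y, L)
        z_parts = [depth]
        a_parts = [refl]
        p_parts = [np.zeros_like(refl)]
        for li, u, amp, phi in self._scatterers:
            lay = self.layers[li]
            t = np.broadcast_to(np.asarray(lay.thickness_um, dtype=float),
                                (nb, ny))[b]
            z_parts.append(depth[:, li, None] + u[b] * t[:, None] * lay.group_index)
            a_parts.append(amp[b])
            p_parts.append(phi[b])
        return (np.concatenate(z_parts, axis=1),
                np.concatenate(a_parts, axis=1),
                np.concatenate(p_parts, axis=1))


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def make_mirror_phantom(opd_um: float,
                        n_bscans: int = 1,
                        n_ascans: int = 8,
                        lateral_extent_mm: tuple[float, float] = (1.0, 1.0),
                        max_depth_um: float | None = None) -> Phantom:
    """Single perfectly flat reflector at a fixed OPD (metrology target).

    Parameters
    ----------
    opd_um
        Optical path difference of the mirror in um; must be positive and
        below the Nyquist depth.
    """
    limit = max_depth_um if max_depth_um is not None else system.nyquist_depth_um()
    if not 0 < opd_um < limit:
        raise ValueError(
            f"mirror OPD {opd_um} um outside the depth range (0, {limit:.1f}) um")
    height = np.zeros((n_bscans, n_ascans))
    return Phantom(
        layers=[Layer("mirror", np.inf, 1.0, 1.0)],
        surface_height_um=height,
        base_opd_um=float(opd_um),
        lateral_extent_mm=lateral_extent_mm,
        max_depth_um=max_depth_um,
    )


def _random_field(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, corr_px: tuple[float, float]) -> np.ndarray:
    """Smooth zero-mean Gaussian random field with exact sample mean 0."""
    if sd <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=corr_px, mode="wrap")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    smooth = smooth * (sd / s)
    return smooth - smooth.mean()


def make_cornea_phantom(total_um: float = 743.2,
                        epithelium_um: float = 69.2,
                        curvature_radius_mm: float = 8.8,
                        seed: int = 0,
                        n_bscans: int = 100,
                        n_ascans: int = 256,
                        lateral_extent_mm: tuple[float, float] = (4.0, 4.0),
                        group_index: float = 1.376,
                        base_opd_um: float = 400.0,
                        epithelium_sd_um: float = 1.2,
                        total_sd_um: float = 3.0,
                        peripheral_thickening_um: float = 25.0,
                        correlation_length_mm: float = 1.5) -> Phantom:
    """Three-layer cornea: epithelium, stroma, and the endothelial surface.

    The anterior surface is a spherical cap of the given radius (default:
    the ~8.8 mm anterior radius of a porcine cornea, apex towards the
    probe).  Total thickness varies like a real pachymetry map: thinnest
    at the apex and increasing quadratically with lateral radius by
    ``peripheral_thickening_um`` towards the field corner, plus a smooth
    Gaussian random residual of SD ``total_sd_um``; the epithelium
    carries only the random component.  All sample means equal the
    nominal values exactly, so ground-truth volume means are the nominal
    thicknesses.  The stroma carries scatterers for speckle.

    ``curvature_radius_mm=np.inf`` gives a flat cornea; with
    ``peripheral_thickening_um`` and the variation SDs set to 0 the
    thickness is then identical at every ``(b, y)``.
    """
    if not 0 < epithelium_um < total_um:
        raise ValueError("need 0 < epithelium_um < total_um")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0211EA]))
    shape = (n_bscans, n_ascans)
    wx, wy = lateral_extent_mm
    pitch_b_mm = wx / n_bscans
    pitch_y_mm = wy / n_ascans
    corr_px = (max(correlation_length_mm / pitch_b_mm, 1e-6),
               max(correlation_length_mm / pitch_y_mm, 1e-6))

    # lateral grid in um from the field centre
    xb = (np.arange(n_bscans) - (n_bscans - 1) / 2.0) * pitch_b_mm * 1e3
    yy = (np.arange(n_ascans) - (n_ascans - 1) / 2.0) * pitch_y_mm * 1e3
    r2 = xb[:, None] ** 2 + yy[None, :] ** 2

    # radial (apex-thin) pachymetry structure, zero mean over the field
    radial = np.zeros(shape)
    if peripheral_thickening_um:
        radial = peripheral_thickening_um * r2 / r2.max()
        radial -= radial.mean()

    epi = epithelium_um + _random_field(rng, shape, epithelium_sd_um, corr_px)
    total = total_um + radial + _random_field(rng, shape, total_sd_um, corr_px)
    stroma = total - epi
    if np.any(stroma <= 0):
        raise ValueError("lateral variation produced non-positive stroma thickness")
    if np.isfinite(curvature_radius_mm):
        R = curvature_radius_mm * 1e3
        if np.any(r2 >= R ** 2):
            raise ValueError("lateral extent exceeds the curvature radius")
        sag = R - np.sqrt(R ** 2 - r2)
    else:
        sag = np.zeros(shape)

    layers = [
        Layer("epithelium", epi, group_index, 0.158,
              scatter_amplitude=0.0015, scatterers_per_ascan=6),
        Layer("stroma", stroma, group_index, 0.02,
              scatter_amplitude=0.004, scatterers_per_ascan=30),
        Layer("aqueous", np.inf, 1.336, 0.04),
    ]
    return Phantom(
        layers=layers,
        surface_height_um=-sag,
        base_opd_um=base_opd_um,
        lateral_extent_mm=lateral_extent_mm,
        seed=seed,
    )


# two 2 x 1 mm blocks side by side along the scan axis, sharing one lateral
# band (as adjacent components on a board do); every B-scan then keeps the
# solder mask as its majority region
_DEFAULT_FOOTPRINTS: tuple[tuple[float, float, float, float], ...] = (
    (0.6, 2.6, 0.7, 1.7),
    (3.0, 5.0, 0.7, 1.7),
)


def make_pcb_phantom(coating_over_mask_um: float = 82.9,
                     coating_over_resistor_um: float = 27.2,
                     resistor_height_um: float | None = None,
                     resistor_footprints: Sequence[tuple[float, float, float, float]]
                     | None = None,
                     seed: int = 0,
                     n_bscans: int = 60,
                     n_ascans: int = 256,
                     lateral_extent_mm: tuple[float, float] = (5.0, 4.0),
                     coating_index: float = 1.50,
                     tilt_um: tuple[float, float] = (30.0, 60.0),
                     waviness_sd_um: float = 4.0,
                     edge_transition_mm: float = 0.25,
                     base_opd_um: float = 300.0) -> Phantom:
    """Conformal coating over solder mask with raised resistor blocks.

    Resistor blocks of height ``resistor_height_um`` rise above the
    solder mask; the coating is thinner on the block tops than on the
    mask (the two thickness parameters).  Block edges carry a smooth
    fillet of width ``edge_transition_mm`` — the sloped meniscus a
    sprayed coating and the solder form along component edges — over
    which both the substrate topography and the coating thickness ramp
    between their two levels.  ``resistor_height_um=None`` picks the
    self-leveling default ``coating_over_mask - coating_over_resistor``,
    for which the coating's outer surface stays flush across the blocks.
    A mild board tilt and surface waviness emulate PCB warp; both cancel
    out of the coating thickness.

    Ground truth labels each lateral position ``"resistor"`` (on a block
    top, coating exactly ``coating_over_resistor_um``), ``"mask"`` (flat
    solder mask, exactly ``coating_over_mask_um``), or ``"edge"`` (inside
    a fillet, intermediate thickness).

    Parameters
    ----------
    resistor_footprints
        Rectangles ``(b0_mm, b1_mm, y0_mm, y1_mm)`` in lateral scan
        coordinates; must not overlap.  Defaults to two 2 x 1 mm blocks.
    """
    if coating_over_mask_um <= 0 or coating_over_resistor_um <= 0:
        raise ValueError("coating thicknesses must be > 0")
    if resistor_height_um is None:
        resistor_height_um = coating_over_mask_um - coating_over_resistor_um
    if resistor_height_um < 0:
        raise ValueError("resistor_height_um must be >= 0")
    if edge_transition_mm <= 0:
        raise ValueError("edge_transition_mm must be > 0")
    if resistor_footprints is None:
        resistor_footprints = _DEFAULT_FOOTPRINTS
    wx, wy = lateral_extent_mm
    for b0, b1, y0, y1 in resistor_footprints:
        if not (0 <= b0 < b1 <= wx and 0 <= y0 < y1 <= wy):
            raise ValueError(f"footprint ({b0},{b1},{y0},{y1}) outside the "
                             f"{wx} x {wy} mm field")
    fp = list(resistor_footprints)
    for i in range(len(fp)):
        for j in range(i + 1, len(fp)):
            a, c = fp[i], fp[j]
            if a[0] < c[1] and c[0] < a[1] and a[2] < c[3] and c[2] < a[3]:
                raise ValueError("resistor footprints overlap")

    shape = (n_bscans, n_ascans)
    bc = (np.arange(n_bscans) + 0.5) * wx / n_bscans
    yc = (np.arange(n_ascans) + 0.5) * wy / n_ascans
    # fraction of "resistor-ness": 1 on block tops, 0 on flat mask,
    # smoothstep of distance outside the footprint within the fillet
    frac = np.zeros(shape)
    bgrid = np.broadcast_to(bc[:, None], shape)
    ygrid = np.broadcast_to(yc[None, :], shape)
    for b0, b1, y0, y1 in fp:
        db = np.clip(np.maximum(b0 - bgrid, bgrid - b1), 0.0, None)
        dy = np.clip(np.maximum(y0 - ygrid, ygrid - y1), 0.0, None)
        dist = np.hypot(db, dy)
        t = np.clip(1.0 - dist / edge_transition_mm, 0.0, 1.0)
        frac = np.maximum(frac, t * t * (3.0 - 2.0 * t))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9CB]))
    tb, ty = tilt_um
    tilt = (tb * (bc[:, None] / wx - 0.5) + ty * (yc[None, :] / wy - 0.5))
    wav = _random_field(rng, shape, waviness_sd_um,
                        (max(0.8 / (wx / n_bscans), 1e-6),
                         max(0.8 / (wy / n_ascans), 1e-6)))
    coating = coating_over_mask_um + frac * (coating_over_resistor_um
                                             - coating_over_mask_um)
    height = tilt + wav + frac * resistor_height_um + coating
    height -= height.max()

    labels = np.where(frac >= 1.0, "resistor",
                      np.where(frac <= 0.0, "mask", "edge"))
    # amplitude reflectances: Fresnel air/acrylic for the coating top;
    # epoxy solder mask (n ~ 1.6) and the glass-overcoated resistor top
    # reflect comparably under the coating
    layers = [
        Layer("coating", coating, coating_index, 0.2,
              scatter_amplitude=0.002, scatterers_per_ascan=6),
        Layer("substrate", np.inf, 1.6,
              0.032 + frac * (0.045 - 0.032)),
    ]
    return Phantom(
        layers=layers,
        surface_height_um=height,
        base_opd_um=base_opd_um,
        lateral_extent_mm=lateral_extent_mm,
        seed=seed,
        labels=labels,
    )


def make_tape_phantom(n_layers: int = 10,
                      layer_um: float = 60.0,
                      index: float = 1.5,
                      n_bscans: int = 1,
                      n_ascans: int = 256,
                      lateral_extent_mm: tuple[float, float] = (4.0, 4.0),
                      base_opd_um: float = 200.0,
                      max_depth_um: float | None = None) -> Phantom:
    """Periodic stack of identical adhesive-tape layers.

    ``n_layers`` layers of geometric thickness ``layer_um`` produce
    ``n_layers + 1`` interfaces at an optical spacing of
    ``layer_um * index``.  The default preset spans about 1 mm of optical
    depth; passing larger ``n_layers``/``layer_um`` builds the ~2 mm-deep
    stack used to probe the usable depth range (deep interfaces are
    attenuated by the emergent sensitivity roll-off, not rejected).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if layer_um <= 0:
        raise ValueError("layer_um must be > 0")
    layers = [Layer("tape_0", layer_um, index, 0.2)]
    layers += [Layer(f"tape_{i}", layer_um, index, 0.04)
               for i in range(1, n_layers)]
    layers.append(Layer("backing", np.inf, index, 0.04))
    return Phantom(
        layers=layers,
        surface_height_um=np.zeros((n_bscans, n_ascans)),
        base_opd_um=base_opd_um,
        lateral_extent_mm=lateral_extent_mm,
        max_depth_um=max_depth_um,
    )
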