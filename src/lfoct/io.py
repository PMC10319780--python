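"""File I/O: multi-page TIFF for frames and volumes, CSV tables, PNG views.

Raw frames are stored as 16-bit multi-page TIFF (one page per scan
position, background as a separate file) with a YAML sidecar carrying
exposure, seed and saturation metadata.  Reconstructed volumes are
32-bit float TIFF.  Tables (surfaces, thicknesses, ground truth,
calibration lines) are plain CSV.  Nothing here contains timestamps, so
outputs are byte-identical for a fixed (config, seed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .forward_sim import SpectralFrame
from .recon import BScan, Volume

__all__ = [
    "save_frames",
    "load_frames",
    "save_volume",
    "load_volume",
    "save_log_view_png",
    "write_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_frames(path: str | Path, frames: list[SpectralFrame],
                background: SpectralFrame | None = None) -> None:
    """Write raw frames as multi-page uint16 TIFF plus a metadata sidecar.

    Noise-free float frames are rounded to the nearest count for storage.
    The background frame, if given, is appended as the final page and
    marked in the sidecar.
    """
    path = Path(path)
    pages = list(frames) + ([background] if background is not None else [])
    stack = np.stack([np.asarray(np.rint(f.counts), dtype=np.uint16)
                      for f in pages])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "n_frames": len(frames),
        "has_background": background is not None,
        "exposure_ms": float(pages[0].exposure_ms),
        "noise_on": bool(pages[0].noise_on),
        "binning": int(pages[0].binning),
        "saturated_rows": {int(f.b): [int(r) for r in f.saturated_rows]
                           for f in frames if f.saturated_rows.size},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def load_frames(path: str | Path
                ) -> tuple[list[SpectralFrame], SpectralFrame | None]:
    """Read frames written by :func:`save_frames`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    n = int(meta.get("n_frames", stack.shape[0]))
    has_bg = bool(meta.get("has_background", False))
    sat = meta.get("saturated_rows", {})
    frames = [
        SpectralFrame(stack[b], b=b,
                      exposure_ms=float(meta.get("exposure_ms", 0.5)),
                      noise_on=bool(meta.get("noise_on", True)),
                      saturated_rows=np.asarray(sat.get(b, []), dtype=int),
                      binning=int(meta.get("binning", 1)))
        for b in range(n)
    ]
    background = None
    if has_bg:
        background = SpectralFrame(stack[n], b=-1,
                                   exposure_ms=float(meta.get("exposure_ms", 0.5)),
                                   noise_on=bool(meta.get("noise_on", True)))
    return frames, background


def save_volume(path: str | Path, volume: Volume) -> None:
    """Write a reconstructed volume as multi-page float32 TIFF + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.as_array().astype(np.float32),
                     photometric="minisblack")
    meta = {
        "depth_scale_um_per_bin": float(volume.depth_scale_um_per_bin),
        "scan_pitch_um": float(volume.scan_pitch_um),
        "zero_pad_factor": int(volume.bscans[0].zero_pad_factor),
        "window": volume.bscans[0].window,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def load_volume(path: str | Path) -> Volume:
    """Read a volume written by :func:`save_volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stack = tifffile.imread(path).astype(np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    scale = float(meta.get("depth_scale_um_per_bin", 1.0))
    bscans = [BScan(amplitude=stack[b], depth_scale_um_per_bin=scale, b=b,
                    zero_pad_factor=int(meta.get("zero_pad_factor", 1)),
                    window=meta.get("window", "hann"))
              for b in range(stack.shape[0])]
    return Volume(bscans=bscans, scan_pitch_um=float(meta.get("scan_pitch_um", 0.0)))


def save_log_view_png(path: str | Path, bscan: BScan,
                      dynamic_range_db: float = 40.0) -> None:
    """8-bit log-scaled view of a B-scan (depth vertical) for inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    amp = bscan.amplitude
    peak = amp.max() or 1.0
    db = 20.0 * np.log10(np.clip(amp / peak, 10 ** (-dynamic_range_db / 20.0), 1.0))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(db.T, cmap="gray", aspect="auto", origin="upper",
              vmin=-dynamic_range_db, vmax=0.0)
    ax.set_xlabel("A-scan (y)")
    ax.set_ylabel("depth bin (z)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_manifest(path: str | Path, config_dict: dict, seed: int,
                   config_digest: str, outputs: list[str]) -> None:
    """Record (config, seed, outputs) so a run is reproducible from the file."""
    from . import __version__

    meta = {
        "lfoct_version": __version__,
        "seed": int(seed),
        "config_hash": config_digest,
        "config": config_dict,
        "outputs": sorted(outputs),
    }
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
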