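"""Shared fixtures: nominal calibration, noise-free mirror data, and the
two full-scale end-to-end runs (reused by several test modules so the
expensive simulations happen once per session)."""

import numpy as np
import pytest

from lfoct import (CalibrationTable, make_mirror_phantom, process_frame,
                   simulate_background, simulate_frame)
from lfoct.pipeline import run_e2e


@pytest.fixture(scope="session")
def calib():
    return CalibrationTable.from_grid()


@pytest.fixture(scope="session")
def quiet_background():
    """Noise-free reference-only frame for 8 A-scan rows."""
    return simulate_background(8, noise_on=False)


@pytest.fixture(scope="session")
def mirror_bscan_factory(calib, quiet_background):
    """Reconstructed noise-free mirror B-scan at a requested OPD."""

    def make(opd_um, zero_pad_factor=4, window="rect"):
        frame = simulate_frame(make_mirror_phantom(opd_um), noise_on=False)
        return process_frame(frame, quiet_background, calib,
                             zero_pad_factor=zero_pad_factor, window=window)

    return make


@pytest.fixture(scope="session")
def cornea_run():
    """Full cornea pipeline at the scaled-down study size, seed 1."""
    return run_e2e(preset="cornea", seed=1, n_bscans=100, n_ascans=256)


@pytest.fixture(scope="session")
def pcb_run():
    """Full PCB pipeline at the scaled-down study size, seed 1."""
    return run_e2e(preset="pcb", seed=1, n_bscans=60, n_ascans=256)
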