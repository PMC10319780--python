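"""Reconstruction chain: background, k-linearization, FFT, depth scaling."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from lfoct.forward_sim import (SpectrographModel, simulate_background,
                               simulate_frame, wavelength_grid)
from lfoct.phantom import Layer, Phantom, make_mirror_phantom
from lfoct.recon import (CorrectedFrame, reconstruct_bscan,
                         reconstruct_volume, resample_to_k,
                         subtract_background, _resample_rows)

NO_BLUR = SpectrographModel(resolution_fwhm_nm=0.0)


class TestBackgroundSubtraction:
    def test_frame_minus_itself_is_zero(self, calib, quiet_background):
        out = subtract_background(quiet_background, quiet_background)
        assert np.all(out.data == 0.0)

    def test_shape_mismatch_rejected(self, quiet_background):
        small = simulate_background(4, noise_on=False)
        with pytest.raises(ValueError, match="shape"):
            subtract_background(small, quiet_background)

    def test_mirror_minus_background_matches_closed_form(self):
        """Residual = envelope * (a^2 + 2 a cos(2 k z)) to within 1 count."""
        frame = simulate_frame(make_mirror_phantom(1000.0),
                               spectrograph=NO_BLUR, noise_on=False,
                               oversample=1, precision="exact")
        bg = simulate_background(8, spectrograph=NO_BLUR, noise_on=False)
        out = subtract_background(frame, bg)
        lam = wavelength_grid()
        k = 2 * np.pi / lam
        env_counts = bg.counts[0]
        expected = env_counts * (1.0 + 2.0 * np.cos(2 * k * 1000e3))
        assert np.max(np.abs(out.data[0] - expected)) < 1.0

    def test_saturation_flags_propagate(self):
        frame = simulate_frame(make_mirror_phantom(500.0), noise_on=False)
        bg = simulate_background(8, noise_on=False)
        out = subtract_background(frame, bg)
        assert out.saturated_rows.size == 8


class TestResampleToK:
    def test_constant_rows_stay_constant(self, calib):
        cf = CorrectedFrame(data=np.full((3, 1920), 7.5))
        out = resample_to_k(cf, calib)
        np.testing.assert_allclose(out.data, 7.5, rtol=1e-9)
        assert out.grid == "k"
        assert np.all(np.diff(out.k_grid) > 0)

    def test_nan_input_rejected(self, calib):
        data = np.zeros((2, 1920))
        data[1, 7] = np.nan
        with pytest.raises(ValueError, match="finite"):
            resample_to_k(CorrectedFrame(data=data), calib)

    def test_round_trip_through_warped_grid(self):
        """Forward + inverse fractional resampling reproduces the input to
        <1e-3 relative even for fringes at 0.8x Nyquist."""
        x = np.arange(1920, dtype=float)
        sig = np.cos(0.8 * np.pi * x) * np.exp(-((x - 960) / 500.0) ** 2)
        targets = x + 0.4 * np.sin(x / 150.0)
        warped = _resample_rows(sig, targets)
        inverse = np.interp(x, targets, x)
        back = _resample_rows(warped, inverse)[0]
        err = np.abs(back[50:-50] - sig[50:-50]).max()
        assert err / np.abs(sig).max() < 1e-3

    def test_linearization_sharpens_deep_peak(self, calib, quiet_background):
        """At 2 mm OPD the chirped fringe transforms to a broad smear unless
        resampled to uniform wavenumber first."""
        frame = simulate_frame(make_mirror_phantom(2000.0), noise_on=False)
        corrected = subtract_background(frame, quiet_background)

        def three_db_width(amplitude):
            prof = amplitude.mean(axis=0)
            prof = prof[50:]
            p = np.argmax(prof)
            above = prof >= prof[p] / np.sqrt(2.0)
            lo = p
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = p
            while hi < prof.size - 1 and above[hi + 1]:
                hi += 1
            return hi - lo + 1

        with_k = reconstruct_bscan(resample_to_k(corrected, calib), calib,
                                   window="rect")
        without = reconstruct_bscan(
            CorrectedFrame(data=corrected.data, grid="k", b=corrected.b),
            calib, window="rect")
        assert three_db_width(with_k.amplitude) <= 2
        assert three_db_width(without.amplitude) >= 3


class TestReconstruction:
    def test_mirror_lands_on_predicted_depth_bin(self, calib,
                                                 quiet_background):
        frame = simulate_frame(make_mirror_phantom(1000.0), noise_on=False)
        bscan = reconstruct_bscan(
            resample_to_k(subtract_background(frame, quiet_background),
                          calib), calib, window="rect")
        assert bscan.depth_scale_um_per_bin == pytest.approx(4.2253,
                                                             abs=2e-3)
        prof = bscan.amplitude.mean(axis=0)
        peak_bin = 50 + int(np.argmax(prof[50:])) + 1  # bin 1 = first AC bin
        assert abs(peak_bin - 1000.0 / 4.2253) <= 1.5
        assert bscan.amplitude.shape == (8, 960)

    def test_zero_input_reconstructs_to_zero(self, calib):
        cf = CorrectedFrame(data=np.zeros((2, 1920)), grid="k")
        bscan = reconstruct_bscan(cf, calib)
        assert np.all(bscan.amplitude == 0.0)

    def test_invalid_zero_pad_rejected(self, calib):
        cf = CorrectedFrame(data=np.zeros((2, 1920)), grid="k")
        with pytest.raises(ValueError):
            reconstruct_bscan(cf, calib, zero_pad_factor=0)

    def test_two_reflectors_twenty_microns_apart_resolve(self, calib,
                                                         quiet_background):
        ph = Phantom(layers=[Layer("gap", 20.0, 1.0, 0.3),
                             Layer("back", np.inf, 1.0, 0.3)],
                     surface_height_um=np.zeros((1, 8)), base_opd_um=1000.0)
        frame = simulate_frame(ph, noise_on=False)
        bscan = reconstruct_bscan(
            resample_to_k(subtract_background(frame, quiet_background),
                          calib), calib, zero_pad_factor=4, window="rect")
        prof = bscan.amplitude.mean(axis=0)
        region = prof[200 * 4:280 * 4]
        peaks, _ = find_peaks(region, height=0.3 * region.max())
        assert len(peaks) == 2
        sep_um = abs(peaks[1] - peaks[0]) * bscan.depth_scale_um_per_bin
        assert sep_um == pytest.approx(20.0, abs=3.0)

    def test_parseval_energy_conserved_in_k_rows(self, calib,
                                                 quiet_background):
        frame = simulate_frame(make_mirror_phantom(900.0), noise_on=False)
        resampled = resample_to_k(
            subtract_background(frame, quiet_background), calib)
        row = resampled.data[0]
        spectrum = np.fft.fft(row)
        assert np.sum(np.abs(spectrum) ** 2) / row.size == pytest.approx(
            np.sum(row ** 2), rel=1e-6)

    def test_peak_position_linear_in_opd(self, calib, quiet_background):
        """Depth-bin vs OPD regression: R^2 > 0.9999 and slope within 0.5%
        of 1/depth_scale."""
        opds = np.array([200.0, 600.0, 1000.0, 1500.0, 2000.0, 2500.0,
                         3000.0, 3500.0])
        bins = []
        for opd in opds:
            frame = simulate_frame(make_mirror_phantom(opd), noise_on=False)
            bscan = reconstruct_bscan(
                resample_to_k(subtract_background(frame, quiet_background),
                              calib), calib, zero_pad_factor=4,
                window="rect")
            prof = bscan.amplitude.mean(axis=0)
            z0 = int(100.0 / bscan.depth_scale_um_per_bin)
            c = int(opd / bscan.depth_scale_um_per_bin)
            lo = max(c - 80, z0)
            bins.append(lo + int(np.argmax(prof[lo:c + 80])))
        bins = np.asarray(bins, dtype=float)
        slope, intercept = np.polyfit(opds, bins, 1)
        fitted = slope * opds + intercept
        ss_res = np.sum((bins - fitted) ** 2)
        ss_tot = np.sum((bins - bins.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.9999
        scale = bscan.depth_scale_um_per_bin
        assert slope == pytest.approx(1.0 / scale, rel=0.005)

    def test_hann_window_suppresses_sidelobes(self, calib, quiet_background):
        frame = simulate_frame(make_mirror_phantom(1000.0), noise_on=False)
        corrected = resample_to_k(
            subtract_background(frame, quiet_background), calib)
        levels = {}
        for window in ("rect", "hann"):
            bscan = reconstruct_bscan(corrected, calib, zero_pad_factor=4,
                                      window=window)
            prof = bscan.amplitude.mean(axis=0)
            c = int(1000.0 / bscan.depth_scale_um_per_bin)
            peak = prof[c - 40:c + 40].max()
            side = np.concatenate([prof[c - 160:c - 40], prof[c + 40:c + 160]])
            levels[window] = side.max() / peak
        assert levels["hann"] < levels["rect"]


class TestVolumeReconstruction:
    def test_frame_order_permutes_output_identically(self, calib):
        ph = make_mirror_phantom(800.0, n_bscans=3, n_ascans=4)
        from lfoct.forward_sim import simulate_volume
        frames, background = simulate_volume(ph, seed=3)
        fwd = reconstruct_volume(frames, background, calib)
        rev = reconstruct_volume(frames[::-1], background, calib)
        for a, b in zip(fwd.bscans, rev.bscans[::-1]):
            np.testing.assert_array_equal(a.amplitude, b.amplitude)

    def test_inconsistent_frame_shapes_rejected(self, calib):
        from lfoct.forward_sim import simulate_volume
        f1, bg = simulate_volume(make_mirror_phantom(800.0, n_ascans=4),
                                 seed=0)
        f2, _ = simulate_volume(make_mirror_phantom(800.0, n_ascans=8),
                                seed=0)
        with pytest.raises(ValueError, match="shapes"):
            reconstruct_volume(f1 + f2, bg, calib)

    def test_mirror_volume_peak_bin_stable_across_bscans(self, calib):
        ph = make_mirror_phantom(1200.0, n_bscans=4, n_ascans=4)
        from lfoct.forward_sim import simulate_volume
        frames, background = simulate_volume(ph, noise_on=False, seed=0)
        vol = reconstruct_volume(frames, background, calib, window="rect")
        bins = []
        for bs in vol.bscans:
            prof = bs.amplitude.mean(axis=0)
            z0 = int(100.0 / bs.depth_scale_um_per_bin)
            bins.append(z0 + int(np.argmax(prof[z0:])))
        assert max(bins) - min(bins) <= 1
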