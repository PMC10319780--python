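"""Gradient-based segmentation: artifacts, surfaces, inner layers, thickness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfoct.recon import BScan
from lfoct.segmentation import (coarse_surface, detect_vertical_artifacts,
                                offset_search, refine_surface,
                                remove_artifacts, segment_inner_layer,
                                thickness_map, wiener_denoise, SurfaceMap)
from lfoct.segmentation import axial_gradient, _decrement_weights


def as_bscan(image, scale=2.0):
    return BScan(amplitude=np.asarray(image, dtype=float),
                 depth_scale_um_per_bin=scale)


def psf_image(depths, ny=32, nz=128, sigma=0.8, amplitude=100.0):
    """Synthetic noiseless B-scan: one Gaussian axial PSF per column."""
    z = np.arange(nz)
    depths = np.broadcast_to(np.asarray(depths, dtype=float), (ny,))
    img = amplitude * np.exp(-0.5 * ((z[None, :] - depths[:, None])
                                     / sigma) ** 2)
    return img


# --------------------------------------------------------------------------
# step 1: artifact handling
# --------------------------------------------------------------------------

class TestArtifactDetection:
    def test_flags_exactly_the_hot_columns(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 100))
        img[20:23, :] += 50.0
        flags = detect_vertical_artifacts(as_bscan(img))
        assert list(flags) == [20, 21, 22]

    def test_clean_uniform_bscan_has_no_flags(self):
        # noiseless mirror: every A-scan identical, sigma = 0 guarded
        img = np.tile(psf_image([40], ny=1), (16, 1))
        assert detect_vertical_artifacts(as_bscan(img)).size == 0

    def test_constant_image_has_no_flags(self):
        assert detect_vertical_artifacts(as_bscan(np.ones((8, 16)))).size == 0

    def test_empty_bscan_rejected(self):
        with pytest.raises(ValueError):
            detect_vertical_artifacts(np.zeros((0, 0)))


class TestArtifactRemoval:
    def test_constant_image_is_wiener_fixed_point(self):
        img = np.full((16, 32), 5.0)
        np.testing.assert_array_equal(wiener_denoise(img), img)

    def test_horizontal_band_removed_by_row_mean_subtraction(self):
        img = psf_image(np.linspace(30, 70, 32))
        img[:, 100] += 40.0  # constant horizontal band at one depth
        cleaned = remove_artifacts(as_bscan(img), flags=np.zeros(0, int))
        # the band's uniform component is gone (row mean ~ 0 after clip)
        assert cleaned.amplitude[:, 100].mean() < 2.0

    def test_flagged_columns_replaced_by_neighbour_interpolation(self):
        img = psf_image(np.full(32, 50.0))
        img[10, :] = 500.0
        flags = detect_vertical_artifacts(as_bscan(img))
        assert list(flags) == [10]
        cleaned = remove_artifacts(as_bscan(img), flags)
        col_means = cleaned.amplitude.mean(axis=1)
        assert (col_means[10] - col_means.mean()) < 2.0 * col_means.std() + 1e-9

    def test_all_columns_flagged_rejected(self):
        with pytest.raises(ValueError, match="flagged"):
            remove_artifacts(as_bscan(np.ones((4, 8))), np.arange(4))


# --------------------------------------------------------------------------
# steps 2-3: surfaces
# --------------------------------------------------------------------------

class TestCoarseSurface:
    def test_per_column_argmax(self):
        depths = np.linspace(20, 90, 32).round()
        f = coarse_surface(psf_image(depths))
        np.testing.assert_array_equal(f, depths.astype(int))

    def test_ties_break_towards_smaller_depth(self):
        img = np.zeros((1, 50))
        img[0, [10, 30]] = 5.0
        assert coarse_surface(img)[0] == 10

    def test_zero_columns_filled_from_neighbours(self):
        img = psf_image(np.full(9, 40.0), ny=9)
        img[4, :] = 0.0
        f = coarse_surface(img)
        assert f[4] == 40


class TestRefineSurface:
    def test_exact_on_noiseless_flat_interface(self):
        depths = np.full(32, 60.0)
        line = refine_surface(psf_image(depths), coarse_surface(
            psf_image(depths)))
        np.testing.assert_array_equal(line.depth_bin, 60)
        assert line.quality.all()

    def test_exact_on_noiseless_sloped_interface(self):
        depths = np.round(np.linspace(40, 70, 32))
        img = psf_image(depths)
        line = refine_surface(img, coarse_surface(img))
        assert np.abs(line.depth_bin - depths).max() <= 1

    def test_matches_stepwise_reference_implementation(self):
        """The vectorized tracker equals an independent nested-loop
        transcription of the centre-outward recurrence on random images."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            img = rng.random((48, 64)) ** 2 * 10
            f = rng.integers(5, 58, size=48)
            w_half = 5
            line = refine_surface(img, f, half_width=w_half)

            g = np.zeros_like(img)
            g[:, 1:] = img[:, 1:] - img[:, :-1]
            ny, nz = g.shape
            z = np.zeros(ny, dtype=int)
            y0 = ny // 2
            lo, hi = max(f[y0] - w_half, 0), min(f[y0] + w_half + 1, nz)
            j = lo + int(np.argmax(g[y0, lo:hi]))
            z[y0] = j if g[y0, j] > 0 else f[y0]
            order = list(range(y0 + 1, ny)) + list(range(y0 - 1, -1, -1))
            for y in order:
                prev = z[y + 1] if y < y0 else z[y - 1]
                best, best_val = prev, 0.0
                for cand in range(max(prev - w_half, 0),
                                  min(prev + w_half + 1, nz)):
                    val = (1.0 - abs(cand - prev) / (w_half + 1.0)) \
                        * g[y, cand]
                    if val > best_val:
                        best, best_val = cand, val
                z[y] = best
            np.testing.assert_array_equal(line.depth_bin, z)

    def test_step_within_window_caught_immediately(self):
        """A step no larger than W is picked up within 2W columns of the
        edge (here: immediately, since the new level is inside the window)."""
        w_half = 5
        depths = np.where(np.arange(64) < 32, 44.0, 48.0)  # 4-bin step
        img = psf_image(depths, ny=64)
        line = refine_surface(img, coarse_surface(img), half_width=w_half)
        err = np.abs(line.depth_bin - depths)
        wrong = np.flatnonzero(err > 1)
        assert wrong.size <= 2 * w_half
        assert np.all(np.abs(wrong - 32) <= 2 * w_half)

    def test_ramp_within_window_slope_tracked_exactly(self):
        """An interface ramp of <= W bins per column (a coated component
        edge fillet) is followed without loss of lock."""
        depths = np.concatenate([np.full(20, 40.0),
                                 40.0 + 4.0 * np.arange(10),  # 4 bins/column
                                 np.full(34, 76.0)])
        img = psf_image(depths, ny=64, nz=160)
        line = refine_surface(img, coarse_surface(img), half_width=5)
        assert np.abs(line.depth_bin - depths).max() <= 1

    def test_cliff_beyond_window_held_and_flagged(self):
        """A step larger than W has no gradient evidence in reach: the
        tracker holds the old level and flags the columns low quality
        instead of walking into noise."""
        depths = np.where(np.arange(64) < 32, 30.0, 48.0)  # 18-bin cliff
        img = psf_image(depths, ny=64)
        line = refine_surface(img, coarse_surface(img), half_width=5)
        left = slice(0, 28)
        assert np.all(np.abs(line.depth_bin[left] - 48.0) <= 1)
        assert not line.quality[left].all()

    def test_output_invariant_to_intensity_scaling(self):
        rng = np.random.default_rng(5)
        img = psf_image(np.linspace(30, 60, 32)) + rng.random((32, 128))
        f = coarse_surface(img)
        a = refine_surface(img, f)
        b = refine_surface(737.5 * img, f)
        np.testing.assert_array_equal(a.depth_bin, b.depth_bin)

    def test_boundary_error_grows_with_noise(self):
        depths = np.round(np.linspace(40, 60, 64))
        base = psf_image(depths, ny=64)
        errors = []
        for i, amp in enumerate((0.5, 5.0, 30.0)):
            rng = np.random.default_rng(1000 + i)
            noisy = np.clip(base + amp * rng.standard_normal(base.shape),
                            0.0, None)
            line = refine_surface(noisy, coarse_surface(wiener_denoise(noisy)))
            errors.append(np.abs(line.depth_bin - depths).mean())
        assert errors[0] <= errors[1] <= errors[2]

    def test_decrement_weights_taper_linearly(self):
        w = _decrement_weights(5)
        assert w[5] == 1.0
        np.testing.assert_allclose(w, 1.0 - np.abs(np.arange(-5, 6)) / 6.0)


class TestInnerLayer:
    def test_offset_search_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        img = rng.random((40, 120)) * 10
        g = axial_gradient(img)
        f = rng.integers(10, 40, size=40)
        mu, scores = offset_search(g, f, (3, 50))
        # independent brute-force enumeration
        best_mu, best_score = None, -np.inf
        for cand in range(3, 51):
            s = 0.0
            for y in range(40):
                pos = f[y] + cand
                if 0 <= pos < 120:
                    s += g[y, pos]
            assert s == pytest.approx(scores[cand - 3])
            if s > best_score:
                best_mu, best_score = cand, s
        assert mu == best_mu

    def test_constructed_uniform_offset_is_found(self):
        depths = np.linspace(30, 45, 32)
        img = psf_image(depths) + psf_image(depths + 30.0, amplitude=60.0)
        f = coarse_surface(img)
        line = segment_inner_layer(img, f, alpha=(5, 60))
        np.testing.assert_allclose(line.depth_bin, np.round(depths) + 30,
                                   atol=1.0)

    def test_zero_gradient_window_raises(self):
        img = psf_image(np.full(16, 20.0), ny=16, nz=200)
        f = coarse_surface(img)
        with pytest.raises(ValueError, match="no inner layer"):
            segment_inner_layer(img, f, alpha=(100, 150))

    def test_alpha_outside_depth_range_raises(self):
        img = psf_image(np.full(16, 20.0), ny=16, nz=64)
        f = coarse_surface(img)
        with pytest.raises(ValueError):
            segment_inner_layer(img, f, alpha=(50, 80))
        with pytest.raises(ValueError):
            segment_inner_layer(img, f, alpha=(0, 10))


# --------------------------------------------------------------------------
# thickness maps
# --------------------------------------------------------------------------

class TestThicknessMap:
    def test_arithmetic_against_direct_formula(self):
        upper = np.full((2, 8), 100)
        lower = np.full((2, 8), 200)
        tm = thickness_map(upper, lower, 2.1, 1.376)
        assert tm.mean_um == pytest.approx(100 * 2.1 / 1.376)
        assert tm.sd_um == 0.0
        assert not tm.degenerate

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 60), st.floats(1.0, 5.0), st.floats(1.0, 1.8))
    def test_uniform_gap_matches_oracle(self, gap, scale, index):
        upper = np.full((1, 4), 10)
        tm = thickness_map(upper, upper + gap, scale, index)
        assert tm.mean_um == pytest.approx(gap * scale / index)

    def test_identical_surfaces_flagged_degenerate(self):
        s = np.full((1, 8), 50)
        tm = thickness_map(s, s, 2.0, 1.0)
        assert tm.mean_um == 0.0
        assert tm.degenerate

    def test_crossing_surfaces_masked_with_warning(self):
        upper = np.full((1, 8), 50)
        lower = np.full((1, 8), 70)
        lower[0, 3] = 40
        with pytest.warns(UserWarning, match="crossing"):
            tm = thickness_map(upper, lower, 1.0, 1.0)
        assert np.isnan(tm.thickness_um[0, 3])
        assert tm.mean_um == pytest.approx(20.0)

    def test_region_statistics_split_by_labels(self):
        upper = np.zeros((1, 8), dtype=int)
        lower = np.array([[10, 10, 10, 10, 30, 30, 30, 30]])
        labels = np.array([["a"] * 4 + ["b"] * 4])
        tm = thickness_map(upper, lower, 1.0, 1.0, labels=labels)
        assert tm.region_stats["a"][0] == pytest.approx(10.0)
        assert tm.region_stats["b"][0] == pytest.approx(30.0)
        assert tm.region_stats["a"][2] == 4

    def test_csv_export_includes_region_column(self, tmp_path):
        import pandas as pd
        upper = np.zeros((1, 4), dtype=int)
        lower = upper + 5
        labels = np.array([["mask", "mask", "resistor", "resistor"]])
        tm = thickness_map(upper, lower, 2.0, 1.5, labels=labels)
        path = tmp_path / "thick.csv"
        tm.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["b", "y", "thickness_um", "region"]
        assert set(df["region"]) == {"mask", "resistor"}


# --------------------------------------------------------------------------
# end-to-end segmentation behaviour on simulated data
# --------------------------------------------------------------------------

class TestOnSimulatedData:
    def test_injected_stripe_detected_and_cleaned(self, calib):
        from lfoct.forward_sim import (inject_saturation_artifact,
                                       simulate_background, simulate_frame)
        from lfoct.phantom import make_cornea_phantom
        from lfoct.recon import process_frame
        ph = make_cornea_phantom(seed=4, n_bscans=1, n_ascans=64)
        rng = np.random.default_rng(8)
        frame = simulate_frame(ph, 0, rng=rng)
        frame = inject_saturation_artifact(frame, y_center=32, width=3)
        background = simulate_background(64, rng=rng)
        bscan = process_frame(frame, background, calib, zero_pad_factor=2)
        flags = detect_vertical_artifacts(bscan)
        assert set(flags) == {31, 32, 33}
        cleaned = remove_artifacts(bscan, flags)
        col_means = cleaned.amplitude.mean(axis=1)
        spread = col_means.std()
        assert np.all(np.abs(col_means[31:34] - col_means.mean())
                      <= 2.0 * spread)

    def test_coarse_surface_tracks_cornea_apex_layer(self, cornea_run):
        """Per-column intensity argmax lands within 2 bins of the true
        anterior surface for >= 95% of A-scans."""
        volume = cornea_run.volume
        gt = cornea_run.ground_truth
        scale = volume.depth_scale_um_per_bin
        hits = 0
        total = 0
        for b in (0, 50, 99):
            cleaned = wiener_denoise(volume.bscans[b].amplitude)
            f = coarse_surface(cleaned)
            truth = gt.interface_depth_um[b, :, 0] / scale
            hits += int(np.sum(np.abs(f - truth) <= 2.0))
            total += f.size
        assert hits / total >= 0.95

    def test_refined_cornea_surface_within_one_bin_of_truth(self, cornea_run):
        """Curved, speckled cornea: mean |error| <= 1 depth bin after the
        constant detection bias shared by all interfaces is removed."""
        volume = cornea_run.volume
        gt = cornea_run.ground_truth
        scale = volume.depth_scale_um_per_bin
        surf = cornea_run.surfaces["surface"].depth_bin
        truth = gt.interface_depth_um[:, :, 0] / scale
        err = surf - truth
        bias = np.median(err)
        assert np.abs(err - bias).mean() <= 1.0

    def test_epithelium_interface_within_one_bin_mean_error(self, cornea_run):
        volume = cornea_run.volume
        gt = cornea_run.ground_truth
        scale = volume.depth_scale_um_per_bin
        inner = cornea_run.surfaces["epithelium_stroma"].depth_bin
        truth = gt.interface_depth_um[:, :, 1] / scale
        err = inner - truth
        assert np.abs(err - np.median(err)).mean() <= 1.0

    def test_pcb_surfaces_follow_resistor_topography(self, pcb_run):
        """The coating/substrate interface follows the fillet ramps; large
        errors are confined to a small fraction of columns."""
        gt = pcb_run.ground_truth
        scale = pcb_run.volume.depth_scale_um_per_bin
        lower = pcb_run.surfaces["coating_bottom"].depth_bin
        truth = gt.interface_depth_um[:, :, 1] / scale
        err = np.abs(lower - truth - np.median(lower - truth))
        assert (err > 5).mean() < 0.05
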