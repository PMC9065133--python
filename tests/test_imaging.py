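import numpy as np
import pytest
import scipy.spatial
from skimage.morphology import disk, opening

from smstoich import (
    DetectionParams,
    FieldConfig,
    ImageStack,
    SimulationConfig,
    denoise,
    detect_spots,
    extract_trace,
    simulate_field,
    subtract_background,
)
from smstoich.errors import InputError, ParameterError
from smstoich.imaging import process_stack
from smstoich.units import time_axis


def _stack(frames, **kw):
    return ImageStack(np.asarray(frames, dtype=float), **kw)


class TestDenoise:
    def test_strength_zero_is_identity(self):
        rng = np.random.default_rng(0)
        stack = _stack(rng.normal(size=(2, 16, 16)))
        out = denoise(stack, 0.0)
        np.testing.assert_array_equal(out.frames, stack.frames)

    def test_constant_image_unchanged(self):
        stack = _stack(np.full((1, 32, 32), 7.0))
        out = denoise(stack, 5.0)
        np.testing.assert_allclose(out.frames, 7.0, atol=1e-9)

    def test_impulse_response_is_normalized_gaussian(self):
        img = np.zeros((1, 41, 41))
        img[0, 20, 20] = 1.0
        out = denoise(_stack(img), 5.0)
        # Kernel sums to 1 (total intensity preserved) and peaks at center.
        assert out.frames.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(out.frames[0].argmax(), (41, 41)) == (20, 20)
        # sigma = strength/5 = 1 px: compare against the analytic Gaussian.
        expected = np.exp(-0.5 * (np.arange(41) - 20) ** 2)
        expected /= expected.sum()
        np.testing.assert_allclose(out.frames[0, 20, :], expected * expected[20], atol=1e-4)

    def test_negative_strength_rejected(self):
        with pytest.raises(ParameterError):
            denoise(_stack(np.zeros((1, 8, 8))), -1.0)


class TestBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(np.full((32, 32), 11.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_isolated_spike_preserved(self):
        img = np.zeros((33, 33))
        img[16, 16] = 50.0
        out = subtract_background(img)
        assert out[16, 16] == pytest.approx(50.0)

    def test_ramp_removed_spot_preserved(self):
        # Linear ramp + narrow Gaussian spot; cross-check against an
        # independent flat-opening implementation (skimage.morphology).
        yy, xx = np.mgrid[0:64, 0:64]
        ramp = 0.5 * xx
        spot = 40.0 * np.exp(-((xx - 32.0) ** 2 + (yy - 32.0) ** 2) / 2.0)
        img = ramp + spot
        out = subtract_background(img)
        oracle = img - opening(img, disk(3))
        np.testing.assert_allclose(out, oracle, atol=1e-9)
        far = out[(np.abs(xx - 32) > 8) | (np.abs(yy - 32) > 8)]
        assert np.abs(far).max() < 0.05 * np.ptp(ramp)
        assert out[32, 32] == pytest.approx(40.0, rel=0.1)

    def test_output_never_exceeds_input_background(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 10, (40, 40))
        out = subtract_background(img)
        assert out.min() >= -1e-9  # opening is anti-extensive

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ParameterError):
            subtract_background(np.zeros((16, 16)), ball_radius_um=0.1)


class TestDetect:
    def test_nan_pixels_rejected(self):
        img = np.zeros((32, 32))
        img[3, 3] = np.nan
        with pytest.raises(InputError):
            detect_spots(img)

    def test_blank_noise_has_no_detections(self):
        # Pure Gaussian noise at the printed contrast threshold: false
        # positives in well under 1% of seeded trials.
        fp_trials = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            if detect_spots(rng.normal(0, 1.0, (128, 128))):
                fp_trials += 1
        assert fp_trials <= 1

    def test_single_planted_spot_found_precisely(self):
        rng = np.random.default_rng(4)
        noise_sd = 1.0
        yy, xx = np.mgrid[0:64, 0:64]
        img = 50.0 * noise_sd * np.exp(
            -((xx - 30.3) ** 2 + (yy - 33.7) ** 2) / (2 * 1.3**2)
        ) + rng.normal(0, noise_sd, (64, 64))
        spots = detect_spots(img)
        assert len(spots) == 1
        assert abs(spots[0].x_px - 30.3) < 1.0
        assert abs(spots[0].y_px - 33.7) < 1.0

    def test_grid_of_spots_recall_and_precision(self):
        # Non-overlapping planted spots at simulation-like SNR.
        rng = np.random.default_rng(9)
        yy, xx = np.mgrid[0:256, 0:256]
        img = np.zeros((256, 256))
        truth = []
        for gy in range(16, 256, 32):
            for gx in range(16, 256, 32):
                x = gx + rng.uniform(-3, 3)
                y = gy + rng.uniform(-3, 3)
                flux = rng.normal(100, 25)
                sigma = 1.3
                img += flux / (2 * np.pi * sigma**2) * np.exp(
                    -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
                )
                truth.append((x, y))
        img += rng.normal(0, 0.2, img.shape)
        spots = detect_spots(img)
        det = np.array([[s.x_px, s.y_px] for s in spots])
        truth = np.array(truth)
        d, _ = scipy.spatial.cKDTree(det).query(truth)
        recall = np.mean(d < 4.875)
        d2, _ = scipy.spatial.cKDTree(truth).query(det)
        precision = np.mean(d2 < 4.875)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_empty_image_empty_list(self):
        assert detect_spots(np.zeros((0, 0))) == []


class TestEndToEnd:
    def test_field_recovery_at_default_presets(self):
        # simulate -> denoise -> background -> detect at the printed
        # settings recovers >= 95% of non-overlapping spots with >= 95%
        # precision.
        sim = SimulationConfig()
        fc = FieldConfig()
        params = DetectionParams()
        cy3, _, truth = simulate_field(sim, fc, seed=200, render_movie=False)
        img = process_stack(cy3, params).temporal_mean()
        spots = detect_spots(img, params, fc.pixel_size_um)
        det = np.array([[s.x_px, s.y_px] for s in spots])
        gt = truth[~truth.overlap_flag][["x_px", "y_px"]].to_numpy()
        d, _ = scipy.spatial.cKDTree(det).query(gt)
        recall = np.mean(d < 4.875)
        d2, _ = scipy.spatial.cKDTree(truth[["x_px", "y_px"]].to_numpy()).query(det)
        precision = np.mean(d2 < 4.875)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_photometric_linearity(self):
        # Scaling the movie by c scales every extracted trace by c and
        # leaves detection decisions unchanged.
        sim = SimulationConfig().with_(n_frames=40)
        fc = FieldConfig(width_px=96, height_px=96, n_spots_mean=6)
        params = DetectionParams()
        cy3, surf, _ = simulate_field(sim, fc, seed=77)
        c = 7.0
        base_img = process_stack(cy3, params).temporal_mean()
        spots = detect_spots(base_img, params, fc.pixel_size_um)
        scaled_cy3 = ImageStack(c * cy3.frames, fc.pixel_size_um, "Cy3", sim.frame_rate_hz)
        scaled_img = process_stack(scaled_cy3, params).temporal_mean()
        spots_scaled = detect_spots(scaled_img, params, fc.pixel_size_um)
        assert len(spots) == len(spots_scaled)
        surf_proc = process_stack(surf, params)
        cy3_proc = process_stack(cy3, params)
        scaled_surf = ImageStack(c * surf.frames, fc.pixel_size_um, "Surf649", sim.frame_rate_hz)
        surf_proc_scaled = process_stack(scaled_surf, params)
        cy3_proc_scaled = ImageStack(c * cy3_proc.frames, fc.pixel_size_um, "Cy3", sim.frame_rate_hz)
        for s in spots[:3]:
            tr = extract_trace(surf_proc, cy3_proc, s)
            tr_scaled = extract_trace(surf_proc_scaled, cy3_proc_scaled, s)
            # float32 frames: linearity holds to single-precision rounding
            np.testing.assert_allclose(tr_scaled.intensity, c * tr.intensity, rtol=1e-4, atol=1e-3)

    def test_extracted_trace_tracks_active_fluorophores(self):
        # Correlation between extracted intensity and the true
        # active-fluorophore time course at default noise.
        sim = SimulationConfig()
        fc = FieldConfig(width_px=160, height_px=160, n_spots_mean=20)
        params = DetectionParams()
        cy3, surf, truth = simulate_field(sim, fc, seed=42)
        cy3_proc = process_stack(cy3, params)
        surf_proc = process_stack(surf, params)
        spots = detect_spots(cy3_proc.temporal_mean(), params, fc.pixel_size_um)
        tree = scipy.spatial.cKDTree(truth[["x_px", "y_px"]].to_numpy())
        frames = np.arange(sim.n_frames)
        cors = []
        for s in spots:
            d, j = tree.query([s.x_px, s.y_px])
            if d > 2.0 or truth.overlap_flag[j]:
                continue
            trace = extract_trace(surf_proc, cy3_proc, s)
            if trace.edge_clipped:
                continue
            b = np.asarray(truth.bleach_frames[j])
            if b.size == 0:
                continue
            count_t = (frames[:, None] <= b[None, :]).sum(axis=1)
            if count_t.std() == 0:
                continue
            cors.append(np.corrcoef(trace.intensity, count_t)[0, 1])
        assert len(cors) >= 5
        assert np.median(cors) >= 0.95


class TestExtract:
    def _spot(self, x, y, r=4.875):
        from smstoich.imaging import SpotDetection

        return SpotDetection(0, x, y, r, 100.0)

    def test_zero_movie_zero_trace(self):
        surf = _stack(np.zeros((20, 64, 64)), channel_label="Surf649")
        cy3 = _stack(np.zeros((5, 64, 64)))
        trace = extract_trace(surf, cy3, self._spot(32.0, 32.0))
        np.testing.assert_allclose(trace.intensity, 0.0, atol=1e-12)
        assert trace.cy3_intensity == pytest.approx(0.0)
        assert not trace.edge_clipped

    def test_constant_spot_amplitude_recovered(self):
        # Noiseless spot of integrated amplitude A on flat background:
        # every frame's aperture-minus-annulus measure returns A within
        # PSF-truncation tolerance (Gaussian integral oracle).
        A, sigma = 200.0, 1.3
        yy, xx = np.mgrid[0:64, 0:64]
        frame = 10.0 + A / (2 * np.pi * sigma**2) * np.exp(
            -((xx - 31.6) ** 2 + (yy - 32.4) ** 2) / (2 * sigma**2)
        )
        surf = _stack(np.repeat(frame[None], 8, axis=0), channel_label="Surf649")
        cy3 = _stack(np.repeat(frame[None], 5, axis=0))
        trace = extract_trace(surf, cy3, self._spot(31.6, 32.4))
        np.testing.assert_allclose(trace.intensity, A, rtol=0.02)

    def test_edge_spot_flagged(self):
        surf = _stack(np.zeros((5, 64, 64)), channel_label="Surf649")
        cy3 = _stack(np.zeros((5, 64, 64)))
        trace = extract_trace(surf, cy3, self._spot(2.0, 30.0))
        assert trace.edge_clipped

    def test_mismatched_geometry_rejected(self):
        surf = _stack(np.zeros((5, 32, 32)))
        cy3 = _stack(np.zeros((5, 64, 64)))
        with pytest.raises(InputError):
            extract_trace(surf, cy3, self._spot(16, 16))

    def test_time_axis_from_frame_rate(self):
        surf = _stack(np.zeros((10, 64, 64)), frame_rate_hz=5.0)
        cy3 = _stack(np.zeros((5, 64, 64)), frame_rate_hz=5.0)
        trace = extract_trace(surf, cy3, self._spot(32, 32))
        np.testing.assert_allclose(trace.t, np.arange(10) / 5.0)
        assert time_axis(900, 5.0)[-1] == pytest.approx(179.8)
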