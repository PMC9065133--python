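import numpy as np
import pytest

from smstoich import (
    FieldConfig,
    SimulationConfig,
    condition_preset,
    simulate_cohort,
    simulate_field,
    simulate_occupancy,
    simulate_resolvable_trace,
    simulate_trace,
)
from smstoich.errors import ParameterError, UnknownPresetError
from smstoich.simulate import inject_jump, rng_for_complex


class TestOccupancy:
    def test_full_occupancy_gives_all_sites(self):
        cfg = SimulationConfig(occupancy_p=1.0)
        k = simulate_occupancy(cfg, 50, np.random.default_rng(0))
        assert np.all(k == 16)

    def test_zero_occupancy_gives_zero(self):
        cfg = SimulationConfig(occupancy_p=0.0)
        k = simulate_occupancy(cfg, 50, np.random.default_rng(0))
        assert np.all(k == 0)

    def test_binomial_mean_matches_analytic(self):
        # Binomial(16, 0.375) has mean 6; 1e5 draws put the sample mean
        # within 0.05 with large margin (3 SE ~ 0.018).
        cfg = SimulationConfig(occupancy_p=0.375)
        k = simulate_occupancy(cfg, 100_000, np.random.default_rng(7))
        assert abs(k.mean() - 6.0) < 0.05

    def test_labeling_efficiency_thins_occupancy(self):
        cfg = SimulationConfig(occupancy_p=0.5, labeling_efficiency=0.5)
        k = simulate_occupancy(cfg, 50_000, np.random.default_rng(3))
        assert abs(k.mean() - 16 * 0.25) < 0.1

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(occupancy_p=1.5)
        with pytest.raises(ParameterError):
            simulate_occupancy(SimulationConfig(), 0, np.random.default_rng(0))


class TestTrace:
    def test_zero_fluorophores_zero_trace(self):
        cfg = SimulationConfig(noise_sd=0.0)
        trace, bleach = simulate_trace(0, cfg, np.random.default_rng(0))
        assert np.all(trace.intensity == 0.0)
        assert bleach.size == 0

    def test_noiseless_equal_steps_piecewise_constant(self):
        # Three unit fluorophores, no noise: the trace starts at 3, only
        # visits levels {3, 2, 1, 0}, and ends fully bleached.
        cfg = SimulationConfig(
            unit_step_mean=1.0, unit_step_cv=0.0, noise_sd=0.0, bleach_rate=0.02
        )
        trace, _ = simulate_trace(3, cfg, np.random.default_rng(5))
        assert trace.intensity[0] == pytest.approx(3.0)
        assert set(np.round(trace.intensity, 9)) <= {0.0, 1.0, 2.0, 3.0}
        assert trace.intensity[-1] == pytest.approx(0.0)

    def test_geometric_mean_bleach_frame(self):
        # Mean of (geometric(q) - 1) is 1/q - 1.
        cfg = SimulationConfig(bleach_rate=0.01, n_frames=10)
        rng = np.random.default_rng(11)
        frames = np.concatenate(
            [simulate_trace(1, cfg, rng)[1] for _ in range(20_000)]
        )
        expected = 1 / 0.01 - 1
        se = np.sqrt((1 - 0.01) / 0.01**2 / frames.size)
        assert abs(frames.mean() - expected) < 3 * se

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            simulate_trace(17, SimulationConfig(), np.random.default_rng(0))
        with pytest.raises(ParameterError):
            simulate_trace(-1, SimulationConfig(), np.random.default_rng(0))

    def test_conservation_bleach_count_equals_labeled(self):
        cfg = condition_preset("salt_0.2M")
        _, truth = simulate_cohort(cfg, 40, seed=2)
        for _, row in truth.iterrows():
            assert len(row.bleach_frames) == row.n_labeled

    def test_determinism_per_complex_substream(self):
        cfg = condition_preset("salt_0.5M")
        t1, g1 = simulate_cohort(cfg, 10, seed=9)
        t2, g2 = simulate_cohort(cfg, 10, seed=9)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.intensity, b.intensity)
        assert g1.drop(columns="bleach_frames").equals(g2.drop(columns="bleach_frames"))
        # Substreams are keyed by (seed, index): trace i is identical
        # regardless of cohort size.
        t3, _ = simulate_cohort(cfg, 3, seed=9)
        np.testing.assert_array_equal(t1[2].intensity, t3[2].intensity)

    def test_resolvable_trace_plateau_separation(self):
        cfg = SimulationConfig(unit_step_cv=0.0, noise_sd=0.0)
        _, bleach = simulate_resolvable_trace(cfg, 8, np.random.default_rng(4), min_plateau_frames=5)
        b = np.sort(bleach)
        assert b[0] >= 4
        assert np.all(np.diff(b) >= 5)
        assert b[-1] < cfg.n_frames - 25

    def test_inject_jump_adds_upward_step(self):
        cfg = SimulationConfig(noise_sd=0.0, unit_step_cv=0.0)
        trace, _ = simulate_trace(2, cfg, np.random.default_rng(1))
        jumped = inject_jump(trace, 400, 75.0)
        assert jumped.intensity[400] - trace.intensity[400] == pytest.approx(75.0)
        assert np.all(jumped.intensity[:400] == trace.intensity[:400])
        with pytest.raises(ParameterError):
            inject_jump(trace, 900, 10.0)


class TestPresets:
    @pytest.mark.parametrize(
        "name,expected_p,molarity",
        [("salt_0.2M", 0.375, 0.2), ("salt_0.5M", 0.25, 0.5), ("salt_1.0M", 0.125, 1.0)],
    )
    def test_preset_occupancy_calibration(self, name, expected_p, molarity):
        cfg = condition_preset(name)
        assert cfg.occupancy_p == pytest.approx(expected_p)
        assert cfg.condition_m == molarity

    def test_unknown_preset_raises(self):
        with pytest.raises(UnknownPresetError):
            condition_preset("salt_0.9M")

    def test_preset_mean_occupancy_within_three_se(self):
        for name, mean in [("salt_0.2M", 6.0), ("salt_1.0M", 2.0)]:
            cfg = condition_preset(name)
            k = simulate_occupancy(cfg, 20_000, np.random.default_rng(13))
            se = np.sqrt(16 * cfg.occupancy_p * (1 - cfg.occupancy_p) / 20_000)
            assert abs(k.mean() - mean) < 3 * se

    def test_bleaching_completeness_exceeds_95_percent(self):
        # Closed form: 1 - (1 - q)^900 with q = 0.005 is ~0.989.
        cfg = SimulationConfig()
        closed_form = 1 - (1 - cfg.bleach_rate) ** cfg.n_frames
        assert closed_form > 0.95
        rng = np.random.default_rng(5)
        bleach = rng.geometric(cfg.bleach_rate, size=20_000) - 1
        frac = np.mean(bleach < cfg.n_frames)
        assert frac > 0.95
        assert abs(frac - closed_form) < 0.01


class TestField:
    def test_empty_field_background_only(self):
        sim = SimulationConfig()
        fc = FieldConfig(width_px=64, height_px=64, n_spots_mean=0, read_noise_sd=0.0)
        cy3, surf, truth = simulate_field(sim.with_(n_frames=10), fc, seed=0)
        assert truth.empty
        expected_max = fc.camera_offset + fc.background_level + fc.background_gradient
        assert cy3.frames.max() <= expected_max + 1e-4
        assert surf.frames.max() <= expected_max + 1e-4

    def test_single_spot_aperture_sum_matches_flux(self):
        # Gaussian integral oracle: with no noise/gradient, the Cy3 pixel
        # sum over a generous aperture recovers the true integrated flux.
        sim = SimulationConfig()
        fc = FieldConfig(
            width_px=64,
            height_px=64,
            n_spots_mean=1,
            read_noise_sd=0.0,
            background_level=0.0,
            background_gradient=0.0,
            camera_offset=0.0,
        )
        for seed in range(5):
            cy3, _, truth = simulate_field(sim, fc, seed=seed, render_movie=False)
            if len(truth) != 1:
                continue
            x, y, flux = truth.x_px[0], truth.y_px[0], truth.cy3_true[0]
            if not (10 < x < 54 and 10 < y < 54):
                continue
            yy, xx = np.mgrid[0:64, 0:64]
            mask = (xx - x) ** 2 + (yy - y) ** 2 <= 8**2
            measured = cy3.frames[0][mask].sum()
            assert measured == pytest.approx(flux, rel=0.02)

    def test_poisson_spot_count(self):
        sim = SimulationConfig().with_(n_frames=2)
        fc = FieldConfig(width_px=96, height_px=96, n_spots_mean=40, read_noise_sd=0.0)
        counts = [
            len(simulate_field(sim, fc, seed=s, render_movie=False)[2]) for s in range(40)
        ]
        se = np.sqrt(40 / len(counts))
        assert abs(np.mean(counts) - 40) < 3 * se

    def test_overlap_flags_mark_close_pairs(self):
        sim = SimulationConfig().with_(n_frames=2)
        fc = FieldConfig(width_px=48, height_px=48, n_spots_mean=25)
        _, _, truth = simulate_field(sim, fc, seed=3, render_movie=False, aperture_radius_px=4.875)
        pos = truth[["x_px", "y_px"]].to_numpy()
        d2 = ((pos[:, None] - pos[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        has_close = d2.min(axis=1) < 4.875**2
        assert list(truth.overlap_flag) == list(has_close)

    def test_field_determinism(self):
        sim = SimulationConfig().with_(n_frames=30)
        fc = FieldConfig(width_px=64, height_px=64, n_spots_mean=8)
        a = simulate_field(sim, fc, seed=21)
        b = simulate_field(sim, fc, seed=21)
        np.testing.assert_array_equal(a[0].frames, b[0].frames)
        np.testing.assert_array_equal(a[1].frames, b[1].frames)

    def test_rng_substream_stability(self):
        a = rng_for_complex(42, 3).normal()
        b = rng_for_complex(42, 3).normal()
        assert a == b
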