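import math

import numpy as np
import pytest

from alveo4d import simulate as sim
from alveo4d.morphometrics import ellipsoid_sphericity


class TestBuildScene:
    def test_zero_fraction_flags_no_cells(self):
        cfg = sim.SceneConfig(flatten_fraction=0.0, n_epithelial=50, n_frames=4)
        truth = sim.build_scene(cfg)
        assert sum(c.flattening for c in truth.epithelial()) == 0

    def test_ring_member_counts_in_default_band(self):
        cfg = sim.SceneConfig(
            field_size=(350.0, 220.0, 80.0), n_rings=10, n_epithelial=0,
            n_frames=2, seed=3,
        )
        truth = sim.build_scene(cfg)
        assert len(truth.rings) == 10
        assert all(len(r.members) in {3, 4, 5} for r in truth.rings)

    def test_flatten_flag_count_is_rounded_fraction(self):
        cfg = sim.SceneConfig.p14_preset(seed=1, n_frames=4)
        truth = sim.build_scene(cfg)
        assert sum(c.flattening for c in truth.epithelial()) == 48  # round(.24*200)

    def test_extrusion_distance_within_configured_range(self):
        cfg = sim.SceneConfig(n_epithelial=30, flatten_fraction=0.5, seed=2, n_frames=4)
        truth = sim.build_scene(cfg)
        deltas = [c.delta for c in truth.epithelial() if c.flattening]
        assert all(60.0 <= d <= 100.0 for d in deltas)

    def test_same_seed_bit_identical(self):
        cfg = sim.SceneConfig(seed=5, n_frames=3, n_epithelial=6)
        a, b = sim.build_scene(cfg), sim.build_scene(cfg)
        for ca, cb in zip(a.cells, b.cells):
            np.testing.assert_array_equal(ca.centroids, cb.centroids)
            np.testing.assert_array_equal(ca.axes, cb.axes)
        fa = sim.render_frame(a, 1)
        fb = sim.render_frame(b, 1)
        np.testing.assert_array_equal(fa, fb)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_frames"):
            sim.SceneConfig(n_frames=1)
        with pytest.raises(ValueError, match="4 voxels"):
            sim.SceneConfig(field_size=(3.0, 96.0, 48.0))
        with pytest.raises(ValueError, match="min <= max"):
            sim.SceneConfig(extrusion_range=(100.0, 60.0))
        with pytest.raises(ValueError, match="skew_angle"):
            sim.SceneConfig(skew_angle=95.0)

    def test_ring_diameter_schedule_linear_with_floor(self):
        cfg = sim.SceneConfig(contraction_rate=0.5, ring_diameter_0=20.0,
                              min_ring_diameter=16.0, n_frames=20, seed=0)
        truth = sim.build_scene(cfg)
        ring = truth.rings[0]
        expected = np.maximum(20.0 - 0.5 * cfg.times, 16.0)
        np.testing.assert_allclose(ring.diameter, expected)
        assert np.all(np.diff(ring.diameter) <= 0)

    def test_flattening_sphericity_monotone_non_increasing(self):
        cfg = sim.SceneConfig(n_epithelial=10, flatten_fraction=0.5,
                              n_frames=60, seed=4)
        truth = sim.build_scene(cfg)
        for c in truth.epithelial():
            if not c.flattening:
                continue
            psi = truth.sphericity_series(c)
            sel = (cfg.times >= c.onset) & (cfg.times <= c.onset + c.duration)
            assert np.all(np.diff(psi[sel]) <= 1e-9)


class TestRender:
    def test_single_ball_shell_encloses_analytic_volume(self):
        img = np.zeros((40, 40, 40), np.float32)
        r = 8.0
        sim._paint_ellipsoid(img, np.array([20.0, 20.0, 20.0]), (r, r, r),
                             np.eye(3), (1.0, 1.0, 1.0), shell=1.0, interior=0.2)
        from scipy import ndimage as ndi

        enclosed = ndi.binary_fill_holes(img > 0).sum()
        analytic = 4 / 3 * math.pi * (1.05 * r) ** 3  # shell outer radius
        assert abs(enclosed - analytic) / analytic < 0.05

    def test_empty_scene_noise_free_is_all_zero(self):
        cfg = sim.SceneConfig(n_rings=0, n_epithelial=0, n_vessel_nodes=0,
                              n_frames=2, seed=0)
        truth = sim.build_scene(cfg)
        assert sim.render_frame(truth, 0).max() == 0.0

    def test_render_deterministic_with_noise(self):
        cfg = sim.SceneConfig(seed=7, n_frames=3, n_epithelial=4,
                              noise=(0.05, 50.0))
        truth = sim.build_scene(cfg)
        np.testing.assert_array_equal(sim.render_frame(truth, 2),
                                      sim.render_frame(truth, 2))

    def test_intensities_non_negative(self):
        cfg = sim.SceneConfig(seed=7, n_frames=2, n_epithelial=4, noise=(0.2, 10.0))
        truth = sim.build_scene(cfg)
        assert sim.render_frame(truth, 0).min() >= 0.0

    def test_frame_index_out_of_range(self, small_scene):
        cfg, truth = small_scene
        with pytest.raises(IndexError):
            sim.render_channel(truth, cfg.n_frames, "nuclei")


class TestDegrade:
    def test_identity_when_no_artifacts(self, small_scene):
        cfg, truth = small_scene
        movie = sim.render_movie(truth)
        raw, geom, trace = sim.degrade_acquisition(movie, cfg)
        np.testing.assert_array_equal(raw.data, movie.data)
        assert np.all(trace.shifts == 0)
        assert geom.skew_angle == 0.0

    def test_drift_walk_reproducible(self, small_scene):
        cfg, truth = small_scene
        cfg2 = sim.SceneConfig(seed=cfg.seed, n_epithelial=4, n_frames=5, drift_sd=0.8)
        truth2 = sim.build_scene(cfg2)
        movie = sim.render_movie(truth2)
        _, _, t1 = sim.degrade_acquisition(movie, cfg2)
        _, _, t2 = sim.degrade_acquisition(movie, cfg2)
        np.testing.assert_array_equal(t1.shifts, t2.shifts)
        assert np.all(t1.shifts[0] == 0)


class TestSchedules:
    def test_sphericity_schedule_plateaus_and_linear_decline(self):
        times = np.arange(0, 100.0)
        psi = sim.sphericity_schedule(times, onset=20.0, duration=42.0)
        assert np.all(psi[:20] == 1.0)
        np.testing.assert_allclose(psi[-1], sim.PSI_FLAT)
        decline = psi[(times >= 20) & (times <= 62)]
        np.testing.assert_allclose(np.diff(decline), np.diff(decline)[0])

    def test_flat_aspect_sphericity_matches_analytic(self):
        np.testing.assert_allclose(sim.PSI_FLAT, ellipsoid_sphericity((3, 3, 0.25)))

    def test_aspect_path_conserves_volume(self):
        aspect = sim._aspect_for_psi(np.linspace(sim.PSI_FLAT, 1.0, 20))
        np.testing.assert_allclose(np.prod(aspect, axis=1), 1.0, atol=1e-9)
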