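import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alveo4d import morphometrics as mm
from alveo4d import simulate as sim


class TestSphericity:
    def test_exact_sphere_is_one(self):
        assert mm.sphericity(4 / 3 * math.pi, 4 * math.pi) == pytest.approx(1.0)

    def test_oblate_matches_closed_form_area(self):
        a, c = 10.0, 2.5
        # independent evaluation of the oblate spheroid area closed form
        e = math.sqrt(1 - (c / a) ** 2)
        area = 2 * math.pi * a**2 + math.pi * c**2 / e * math.log((1 + e) / (1 - e))
        volume = 4 / 3 * math.pi * a * a * c
        expected = math.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area
        assert mm.ellipsoid_sphericity((a, a, c)) == pytest.approx(expected, abs=1e-6)

    def test_triaxial_area_between_spheroid_bounds(self):
        # (10, 6, 3): area must lie between the enclosing spheroids'
        tri = mm.ellipsoid_surface_area((10, 6, 3))
        assert mm.ellipsoid_surface_area((6, 6, 3)) < tri < mm.ellipsoid_surface_area((10, 10, 3))

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm.sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            mm.sphericity(1.0, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0), st.floats(1.1, 5.0))
    def test_scale_invariance(self, v, a, k):
        # V scales k^3 and A scales k^2 under isotropic scaling by k
        assert mm.sphericity(v * k**3, a * k**2) == pytest.approx(mm.sphericity(v, a))


class TestDetectFlattening:
    def test_constant_high_sphericity_no_event(self):
        s = mm.ShapeSeries(0, np.arange(50.0), np.full(50, 0.95))
        assert mm.detect_flattening(s) is None

    def test_pre_flattened_cell_no_event(self):
        psi = np.full(50, 0.4)
        s = mm.ShapeSeries(0, np.arange(50.0), psi)
        assert mm.detect_flattening(s) is None

    def test_rising_sphericity_no_event(self):
        psi = np.linspace(0.4, 0.98, 60)
        s = mm.ShapeSeries(0, np.arange(60.0), psi)
        assert mm.detect_flattening(s) is None

    def test_planted_duration_recovered_within_ten_percent(self):
        durations = []
        for seed in range(1, 101):
            trace = sim.sphericity_trace(duration=42.0, noise_sd=0.03, seed=seed)
            ev = mm.detect_flattening(trace)
            assert ev is not None and ev.completed
            durations.append(ev.duration)
        within = np.abs(np.array(durations) - 42.0) / 42.0 <= 0.10
        assert within.mean() >= 0.95

    def test_incomplete_decline_not_completed(self):
        # movie ends mid-transition: event may be absent or not completed
        trace = sim.sphericity_trace(duration=42.0, onset=20.0, n_frames=40,
                                     noise_sd=0.0, seed=1)
        ev = mm.detect_flattening(trace)
        assert ev is None or not ev.completed

    def test_onset_estimate_near_planted(self):
        trace = sim.sphericity_trace(duration=42.0, onset=25.0, noise_sd=0.02, seed=3)
        ev = mm.detect_flattening(trace)
        assert ev is not None
        assert abs(ev.onset_time - 25.0) < 5.0


class TestFlatteningFraction:
    def test_no_events_zero_percent(self):
        assert mm.flattening_fraction([None] * 50, 50) == 0.0

    def test_noise_free_p14_scene_exact(self):
        cfg = sim.SceneConfig.p14_preset(seed=2)
        truth = sim.build_scene(cfg)
        events = [mm.detect_flattening(s) for s in truth.shape_series()]
        assert mm.flattening_fraction(events, cfg.n_epithelial) == 24.0

    def test_quarter_fraction_scene(self):
        cfg = sim.SceneConfig.p14_preset(seed=3, n_epithelial=100, flatten_fraction=0.25)
        truth = sim.build_scene(cfg)
        events = [mm.detect_flattening(s) for s in truth.shape_series()]
        assert mm.flattening_fraction(events, 100) == 25.0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            mm.flattening_fraction([], 0)

    def test_fraction_recovery_unbiased_over_seeds(self):
        errors = []
        for seed in range(1, 21):
            cfg = sim.SceneConfig.p14_preset(seed=seed)
            truth = sim.build_scene(cfg)
            series = truth.shape_series(noise_sd=0.03, seed=seed + 500)
            events = [mm.detect_flattening(s) for s in series]
            errors.append(mm.flattening_fraction(events, cfg.n_epithelial) - 24.0)
        assert abs(np.mean(errors)) < 1.0


def _event_scene(mode="control", seed=1):
    cfg = sim.SceneConfig(
        field_size=(260.0, 260.0, 110.0), n_rings=5, n_epithelial=30,
        flatten_fraction=1 / 3, extrusion_range=(70.0, 100.0),
        n_frames=100, seed=seed, motility_mode=mode,
    )
    truth = sim.build_scene(cfg)
    return cfg, truth


class TestScoreEvents:
    def test_five_planted_clusters_five_events(self):
        _cfg, truth = _event_scene()
        events, rate = mm.score_events(truth.tracks(), truth.shape_series())
        assert len(events) == 5
        assert rate > 0

    def test_wnt_inhibited_scene_no_events(self):
        _cfg, truth = _event_scene(mode="wnt_inhibited")
        events, _ = mm.score_events(truth.tracks(), truth.shape_series())
        assert events == []

    def test_single_cell_excursions_do_not_score(self):
        _cfg, truth = _event_scene()
        events, _ = mm.score_events(truth.tracks(), truth.shape_series(),
                                    min_cluster=2, cluster_radius=0.5)
        assert events == []  # shrink the radius: no co-localised pair remains

    def test_event_count_monotone_in_min_displacement(self):
        _cfg, truth = _event_scene()
        tracks, series = truth.tracks(), truth.shape_series()
        counts = [len(mm.score_events(tracks, series, min_displacement=d)[0])
                  for d in (40.0, 70.0, 101.0)]
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[2] == 0  # beyond the planted extrusion range
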