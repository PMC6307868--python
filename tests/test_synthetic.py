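"""Simulator tests: geometry, kinetics, rendering, contact planting, fixture I/O."""

import numpy as np
import pytest

import neurorg as ng
from neurorg.errors import GeometryError, PackingError, TrackPlacementError
from neurorg.kinetics import CLASS_NAMES, DEFAULT_CLASS_BOUNDS
from neurorg.render import NoiseParams, place_capsules, plant_contacts


class TestGeometry:
    def test_no_neurites_gives_soma_only(self, small_config):
        g = ng.make_geometry(small_config, 0, seed=0, soma_radius=6.0)
        assert g.neurite_paths == []

    def test_deterministic_for_seed(self, small_config):
        a = ng.make_geometry(small_config, 3, seed=7, soma_radius=6.0, min_length=25)
        b = ng.make_geometry(small_config, 3, seed=7, soma_radius=6.0, min_length=25)
        for pa, pb in zip(a.neurite_paths, b.neurite_paths):
            np.testing.assert_array_equal(pa, pb)

    def test_rasterized_soma_area_matches_disk(self):
        # 10 um soma at 0.08 um/px: pixel count x pixel area vs pi r^2 within 2%
        config = ng.ImagingConfig(frame_shape=(512, 512))
        g = ng.NeuronGeometry(soma_center=(256.0, 256.0), soma_radius=10.0,
                              pixel_size=0.08)
        area = g.soma_mask((512, 512)).sum() * 0.08**2
        assert area == pytest.approx(np.pi * 100.0, rel=0.02)

    def test_paths_start_on_soma_boundary_and_stay_outside(self, small_geometry):
        g = small_geometry
        r_px = g.soma_radius / g.pixel_size
        center = np.asarray(g.soma_center)
        for path in g.neurite_paths:
            start_dist = np.linalg.norm(path[0] - center)
            assert start_dist == pytest.approx(r_px, abs=2.0)
            assert np.all(np.linalg.norm(path - center, axis=1) > r_px)

    def test_min_length_honoured(self, small_geometry):
        for i in range(len(small_geometry.neurite_paths)):
            assert small_geometry.path_length_um(i) >= 25.0

    def test_infeasible_soma_raises(self):
        config = ng.ImagingConfig(frame_shape=(128, 128))
        with pytest.raises(GeometryError, match="soma"):
            ng.make_geometry(config, 1, seed=0, soma_radius=10.0)


class TestKinetics:
    def test_degenerate_mixture_all_static(self, small_config, small_geometry):
        preset = ng.MotilityPreset((1.0, 0.0, 0.0, 0.0), run_speed=0.1)
        tracks = ng.sample_tracks(small_geometry, preset, 10, small_config, seed=4)
        assert all(t.planted_total_distance < 1.0 for t in tracks)

    def test_class_fractions_match_mixture(self, small_config):
        # pure sampling check, large n: fractions within 3 multinomial SE
        config = ng.ImagingConfig(frame_shape=(1024, 1024), n_frames=97)
        g = ng.make_geometry(config, 8, seed=5)
        preset = ng.PRESETS["control-PO"]
        tracks = []
        for s in range(40):
            tracks += ng.sample_tracks(g, preset, 25, config, seed=100 + s)
        n = len(tracks)
        counts = {c: sum(t.planted_class == c for t in tracks) for c in CLASS_NAMES}
        for c, p in zip(CLASS_NAMES, preset.class_probs):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[c] / n - p) <= 3 * se + 1e-12

    def test_long_tracks_resum_and_max_speed(self, small_config, small_geometry):
        preset = ng.MotilityPreset((0.0, 0.0, 0.0, 1.0), run_speed=0.1)
        tracks = ng.sample_tracks(small_geometry, preset, 5, small_config, seed=6)
        for t in tracks:
            steps = np.abs(np.diff(t.path_pos_um))
            assert steps.sum() == pytest.approx(t.planted_total_distance, abs=1e-9)
            assert 10.0 <= steps.sum() < 15.0
            assert t.planted_max_speed == pytest.approx(0.1)

    def test_total_distance_in_class_bounds(self, small_tracks):
        for t in small_tracks:
            lo, hi = DEFAULT_CLASS_BOUNDS[t.planted_class]
            assert lo - 1e-9 <= t.planted_total_distance < hi

    def test_no_step_below_oscillation_floor(self, small_tracks):
        for t in small_tracks:
            steps = np.abs(np.diff(t.path_pos_um))
            nonzero = steps[steps > 1e-12]
            assert np.all(nonzero >= 0.15 - 1e-9)

    def test_unreachable_distance_raises(self, small_geometry):
        config = ng.ImagingConfig(frame_shape=(512, 512), n_frames=5)
        preset = ng.MotilityPreset((0.0, 0.0, 0.0, 1.0), run_speed=0.1)
        with pytest.raises(TrackPlacementError, match="unreachable"):
            ng.sample_tracks(small_geometry, preset, 3, config, seed=0)


class TestRendering:
    def test_bit_identical_for_seed(self, small_config, small_geometry, small_tracks):
        a, _ = ng.render_timelapse(small_geometry, small_tracks, None, small_config, seed=9)
        b, _ = ng.render_timelapse(small_geometry, small_tracks, None, small_config, seed=9)
        np.testing.assert_array_equal(a.channels["PO"], b.channels["PO"])

    def test_noiseless_spot_centroid(self, small_config, small_geometry):
        # one static spot, noise off: intensity-weighted centroid within 0.05 px
        preset = ng.MotilityPreset((1.0, 0.0, 0.0, 0.0), run_speed=0.1)
        tracks = ng.sample_tracks(small_geometry, preset, 1, small_config, seed=3)
        stack, truth = ng.render_timelapse(
            small_geometry, tracks, None, small_config,
            noise=NoiseParams(enabled=False), seed=0,
        )
        frame = stack.channels["PO"][0].astype(float)
        bg = ng.render_timelapse(
            small_geometry, [], None, small_config,
            noise=NoiseParams(enabled=False), seed=0,
        )[0].channels["PO"][0].astype(float)
        excess = frame - bg
        rr, cc = np.mgrid[: frame.shape[0], : frame.shape[1]]
        row = (excess * rr).sum() / excess.sum()
        col = (excess * cc).sum() / excess.sum()
        planted = truth.tracks[0].px[0]
        assert row == pytest.approx(planted[0], abs=0.05)
        assert col == pytest.approx(planted[1], abs=0.05)

    def test_zero_organelles_zero_detections(self, small_config, small_geometry):
        from neurorg import pipeline
        from neurorg.detection import detect_stack

        stack, _ = ng.render_timelapse(small_geometry, [], None, small_config, seed=1)
        masks = pipeline.segment_stack(stack)
        # the mask may be tiny or empty without organelle trails; detection must
        # then either find nothing or the mask is empty outright
        if masks.neurite_mask.any():
            det = detect_stack(stack, masks)
            assert sum(len(r) for r in det["PO"]) == 0


class TestFixedAndContacts:
    def test_fixed_counts_planted_exactly(self):
        config = ng.ImagingConfig(frame_shape=(1280, 1280), channels=("PO", "CYTO"))
        spec = ng.fixed_spec_from_preset("fixed-control", config, seed=5)
        stack, truth = ng.render_fixed_neuron(spec, config, seed=5)
        assert len(truth.fixed_spots["soma_px"]) == 174
        assert len(truth.fixed_spots["neurite_px"]) == 65
        assert truth.fixed_spots["planted_soma_area_um2"] == pytest.approx(22.0, rel=0.05)
        assert truth.fixed_spots["planted_neurite_area_um2"] == pytest.approx(6.0, rel=0.05)

    def test_fixed_zero_counts_blank_channel(self):
        config = ng.ImagingConfig(frame_shape=(512, 512), channels=("PO", "CYTO"))
        geometry = ng.make_geometry(config, 2, seed=1, soma_radius=6.0,
                                    min_length=12, max_length=14)
        spec = ng.FixedNeuronSpec(geometry, 0, 0, 0.0, 0.0)
        stack, truth = ng.render_fixed_neuron(
            spec, config, seed=1, noise=NoiseParams(enabled=False)
        )
        po = stack.channels["PO"][0].astype(float)
        assert po.max() - po.min() < 1.0  # flat background only

    def test_min_separation_respected(self):
        config = ng.ImagingConfig(frame_shape=(1280, 1280), channels=("PO", "CYTO"))
        spec = ng.fixed_spec_from_preset("fixed-control", config, seed=6)
        _, truth = ng.render_fixed_neuron(spec, config, seed=6)
        pts = np.asarray(truth.fixed_spots["soma_px"])
        r = truth.fixed_spots["soma_radius_um"]
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        min_center_um = d[:, 1].min() * 0.08
        assert min_center_um >= 0.5 + 2 * r - 1e-6

    def test_plant_contacts_extremes(self, small_config):
        config = ng.ImagingConfig(frame_shape=(1024, 1024), channels=("PO", "MITO"))
        g = ng.make_geometry(config, 6, seed=2)
        rng = np.random.default_rng(0)
        capsules = place_capsules(g, config, rng)
        seeds = [(int(i % 6), 5.0 + 3.0 * i / 6) for i in range(24)]
        pos, labels = plant_contacts(
            seeds, capsules, ng.ContactPreset(contact_fraction=1.0), g, config, seed=1
        )
        assert all(labels)
        for p in pos:
            dmin = min(c.surface_distance_um(p[None], 0.08)[0] for c in capsules)
            assert dmin <= 0.1
        pos, labels = plant_contacts(
            seeds, capsules, ng.ContactPreset(contact_fraction=0.0), g, config, seed=1
        )
        assert not any(labels)
        for p in pos:
            dmin = min(c.surface_distance_um(p[None], 0.08)[0] for c in capsules)
            assert dmin >= 1.0 - 1e-6

    def test_contact_fixture_records_binomial_draw(self):
        config = ng.ImagingConfig(frame_shape=(1280, 1280), channels=("PO", "MITO"))
        _, truth = ng.make_contact_fixture(config, n_po=60, seed=3)
        assert truth.meta["planted_fraction"] == pytest.approx(
            np.mean(truth.contact_labels)
        )
        assert len(truth.contact_labels) == 60


class TestFixtureIO:
    def test_round_trip(self, tmp_path, small_stack):
        stack, truth = small_stack
        ng.write_fixture(stack, truth, tmp_path / "fx")
        back, truth2 = ng.read_fixture(tmp_path / "fx")
        np.testing.assert_array_equal(back.channels["PO"], stack.channels["PO"])
        assert back.config.pixel_size == stack.config.pixel_size  # full precision
        assert back.config.frame_interval == stack.config.frame_interval
        assert truth2 is not None
        assert len(truth2.tracks) == len(truth.tracks)
        t0, t1 = truth.tracks[0], truth2.tracks[0]
        np.testing.assert_allclose(t0.px, t1.px)
        assert t0.planted_class == t1.planted_class

    def test_truth_json_reparses_equal(self, tmp_path, small_stack):
        _, truth = small_stack
        truth.to_json(tmp_path / "t.json")
        again = ng.GroundTruth.from_json(tmp_path / "t.json")
        assert again.to_dict() == truth.to_dict()
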