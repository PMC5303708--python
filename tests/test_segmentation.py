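import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from canopypheno.image_io import Label, RGBImage
from canopypheno.segmentation import (ClassPrototype, ColorThresholdModel,
                                      ConfigurationError, KMeansResult,
                                      SegmentationConfig, TrainingError,
                                      assign_classes, kmeans_cluster,
                                      learn_soil_threshold, remove_background,
                                      segment_plant, stretch_colors)
from canopypheno.synthetic_canopy import SceneSpec, generate_scene

SOIL = (110.0, 85.0, 65.0)
GREEN = (60.0, 120.0, 50.0)


class TestSoilThreshold:
    def test_point_masses_perfectly_separated(self):
        colors = np.array([[100, 80, 60]] * 20 + [[40, 120, 50]] * 20, float)
        is_soil = np.array([True] * 20 + [False] * 20)
        model = learn_soil_threshold(colors, is_soil)
        assert model.contains(np.array([[100, 80, 60]], float)).all()
        assert not model.contains(np.array([[40, 120, 50]], float)).any()

    def test_disjoint_boxes_classified_above_99_percent(self):
        # brute-force check of every training pixel against the learned bounds
        rng = np.random.default_rng(12)
        soil = rng.uniform((90, 70, 50), (130, 100, 80), (200, 3))
        plant = rng.uniform((40, 110, 30), (80, 160, 70), (200, 3))
        colors = np.vstack([soil, plant])
        is_soil = np.array([True] * 200 + [False] * 200)
        model = learn_soil_threshold(colors, is_soil)
        pred_soil = model.contains(colors)
        accuracy = (pred_soil == is_soil).mean()
        assert accuracy >= 0.99

    def test_single_class_training_set_rejected(self):
        colors = np.full((10, 3), 100.0)
        with pytest.raises(TrainingError):
            learn_soil_threshold(colors, np.ones(10, bool))
        with pytest.raises(TrainingError):
            learn_soil_threshold(colors, np.zeros(10, bool))

    def test_overlapping_classes_tightening_prefers_plant_exclusion(self):
        # plant pixels inside the raw soil envelope get excluded by tightening
        rng = np.random.default_rng(5)
        soil = rng.uniform((90, 70, 50), (130, 100, 80), (300, 3))
        plant = rng.uniform((120, 95, 75), (170, 150, 120), (300, 3))  # overlaps corner
        colors = np.vstack([soil, plant])
        is_soil = np.array([True] * 300 + [False] * 300)
        model = learn_soil_threshold(colors, is_soil, channel_space="rgb")
        # no plant pixel may remain inside unless the floor width was hit
        plant_inside = model.contains(plant).mean()
        assert plant_inside < 0.05


class TestRemoveBackground:
    def _rgb_box_model(self, lo, hi):
        return ColorThresholdModel(channel_space="rgb", lower=lo, upper=hi)

    def test_all_soil_image_is_all_background(self):
        img = RGBImage(np.full((8, 8, 3), 110, dtype=np.uint8))
        model = self._rgb_box_model((100, 75, 55), (120, 95, 75))
        img.pixels[:, :, 1] = 85
        img.pixels[:, :, 2] = 65
        assert not remove_background(img, model).any()

    def test_centered_square_matches_pixelwise_oracle(self, checker_image):
        model = self._rgb_box_model((100, 75, 55), (120, 95, 75))
        fg = remove_background(checker_image, model)
        # independent oracle: apply the bounds directly per pixel
        px = checker_image.pixels.astype(float)
        inside = ((px >= model.lower) & (px <= model.upper)).all(axis=2)
        np.testing.assert_array_equal(fg, ~inside)
        expected = np.zeros((6, 6), bool)
        expected[2:4, 2:4] = True
        np.testing.assert_array_equal(fg, expected)

    def test_zero_width_bounds_without_match_is_all_foreground(self):
        img = RGBImage(np.full((4, 4, 3), 200, dtype=np.uint8))
        model = self._rgb_box_model((10, 10, 10), (10, 10, 10))
        assert remove_background(img, model).all()


class TestStretchColors:
    def test_gray_ramp_triggers_percentile_fallback(self):
        ramp = np.repeat(np.arange(100, dtype=np.uint8).reshape(10, 10)[:, :, None],
                         3, axis=2)
        img = RGBImage(ramp.copy())
        fg = np.ones((10, 10), bool)
        out, params = stretch_colors(img, fg, method="decorrelation")
        assert params.fallback and params.method == "percentile"
        out_p, _ = stretch_colors(img, fg, method="percentile")
        np.testing.assert_array_equal(out.pixels, out_p.pixels)

    def test_channel_correlations_do_not_increase(self):
        rng = np.random.default_rng(8)
        base = rng.normal([100, 120, 90], [20, 25, 15], (40, 40, 3))
        # induce correlation by mixing a shared luminance term
        lum = rng.normal(0, 30, (40, 40, 1))
        px = np.clip(base + lum, 0, 255).astype(np.uint8)
        img = RGBImage(px)
        fg = np.ones((40, 40), bool)
        out, params = stretch_colors(img, fg, method="decorrelation")
        assert not params.fallback

        def max_abs_corr(p):
            c = np.corrcoef(p.reshape(-1, 3).astype(float), rowvar=False)
            return np.abs(c[np.triu_indices(3, 1)]).max()

        assert max_abs_corr(out.pixels) <= max_abs_corr(px) + 0.02

    def test_two_color_foreground_correlations_bounded_by_input(self):
        px = np.array([[60, 100, 40]] * 50 + [[80, 90, 50]] * 50,
                      np.uint8).reshape(10, 10, 3)
        img = RGBImage(px)
        out, params = stretch_colors(img, np.ones((10, 10), bool))

        def corrs(p):
            c = np.corrcoef(p.reshape(-1, 3).astype(float), rowvar=False)
            return np.abs(c[np.triu_indices(3, 1)])

        assert (corrs(out.pixels) <= corrs(px) + 1e-9).all()

    def test_constant_foreground_maps_to_midpoint(self):
        img = RGBImage(np.full((5, 5, 3), 77, np.uint8))
        out, _ = stretch_colors(img, np.ones((5, 5), bool), method="percentile")
        assert (out.pixels == 128).all()

    def test_background_passes_through_unmodified(self):
        rng = np.random.default_rng(1)
        px = rng.integers(0, 255, (12, 12, 3), dtype=np.uint8)
        img = RGBImage(px.copy())
        fg = np.zeros((12, 12), bool)
        fg[3:9, 3:9] = True
        out, _ = stretch_colors(img, fg)
        np.testing.assert_array_equal(out.pixels[~fg], px[~fg])

    def test_decorrelated_channels_span_full_range(self):
        rng = np.random.default_rng(2)
        px = rng.integers(0, 255, (30, 30, 3), dtype=np.uint8)
        img = RGBImage(px)
        out, params = stretch_colors(img, np.ones((30, 30), bool))
        assert not params.fallback
        flat = out.pixels.reshape(-1, 3)
        assert (flat.min(axis=0) == 0).all()
        assert (flat.max(axis=0) == 255).all()


class TestKMeans:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(100, 20, (50, 3))
        res = kmeans_cluster(X, k=1, seed=0)
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0))
        np.testing.assert_allclose(res.sse, ((X - X.mean(axis=0)) ** 2).sum())
        assert (res.assignment == 0).all()

    def test_k_equals_n_saturates(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 255, (8, 3))
        res = kmeans_cluster(X, k=8, seed=4)
        assert res.sse == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.assignment.tolist())) == 8

    def test_planted_three_clusters_recovered_and_locally_optimal(self):
        rng = np.random.default_rng(7)
        centers = np.array([[30, 30, 30], [120, 200, 90], [180, 160, 60]], float)
        X = np.vstack([c + rng.uniform(-2, 2, (10, 3)) for c in centers])
        truth = np.repeat([0, 1, 2], 10)
        res = kmeans_cluster(X, k=3, seed=5)
        matches_truth = any(
            (res.assignment == np.array([perm[t] for t in truth])).all()
            for perm in itertools.permutations(range(3)))
        assert matches_truth

        # oracle: no single-point relocation lowers the SSE
        def sse_of(assign):
            return sum(((X[assign == j] - X[assign == j].mean(axis=0)) ** 2).sum()
                       for j in range(3) if (assign == j).any())

        base = sse_of(res.assignment)
        for i in range(X.shape[0]):
            for j in range(3):
                if j != res.assignment[i]:
                    alt = res.assignment.copy()
                    alt[i] = j
                    assert sse_of(alt) >= base - 1e-9

    def test_sse_history_non_increasing(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 255, (500, 3))
        res = kmeans_cluster(X, k=5, seed=3)
        hist = np.array(res.sse_history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_same_seed_reproduces_bitwise(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 255, (200, 3))
        a = kmeans_cluster(X, k=4, seed=9)
        b = kmeans_cluster(X, k=4, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.sse == b.sse

    def test_every_point_assigned_to_nearest_centroid(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 255, (300, 3))
        res = kmeans_cluster(X, k=6, seed=1)
        d = cdist(X, res.centroids)
        np.testing.assert_array_equal(res.assignment, d.argmin(axis=1))

    def test_partition_agrees_with_independent_library_on_separated_data(self):
        # cross-check against scikit-learn's KMeans on well-separated clouds,
        # where both must find the unique global optimum partition
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(21)
        centers = np.array([[20, 20, 20], [130, 210, 80], [200, 150, 40]], float)
        X = np.vstack([c + rng.normal(0, 3, (40, 3)) for c in centers])
        ours = kmeans_cluster(X, k=3, seed=2)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        # compare partitions up to label permutation
        ours_parts = {frozenset(np.flatnonzero(ours.assignment == j).tolist())
                      for j in range(3)}
        ref_parts = {frozenset(np.flatnonzero(ref.labels_ == j).tolist())
                     for j in range(3)}
        assert ours_parts == ref_parts

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((2, 3)), k=3)
        with pytest.raises(ValueError):
            kmeans_cluster(np.array([[np.nan, 0, 0]]), k=1)
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((5, 3)), k=0)


def _protos():
    return (ClassPrototype(Label.GREEN, GREEN),
            ClassPrototype(Label.DEAD, (160.0, 140.0, 60.0)),
            ClassPrototype(Label.BACKGROUND, SOIL))


class TestAssignClasses:
    def _result(self, centroids, assignment):
        centroids = np.asarray(centroids, float)
        assignment = np.asarray(assignment)
        return KMeansResult(k=centroids.shape[0], centroids=centroids,
                            assignment=assignment, sse=0.0, sse_history=[0.0],
                            n_iter=1, seed=0, converged=True)

    def test_cluster_at_green_prototype_labels_green(self):
        fg = np.ones((2, 2), bool)
        res = self._result([GREEN], np.zeros(4, dtype=int))
        mask = assign_classes(res, _protos(), fg)
        assert (mask.labels == int(Label.GREEN)).all()

    def test_equidistant_tie_resolves_to_green(self):
        protos = (ClassPrototype(Label.GREEN, (0.0, 0.0, 0.0)),
                  ClassPrototype(Label.DEAD, (10.0, 0.0, 0.0)),
                  ClassPrototype(Label.BACKGROUND, (100.0, 100.0, 100.0)))
        fg = np.ones((1, 1), bool)
        res = self._result([(5.0, 0.0, 0.0)], np.zeros(1, dtype=int))
        mask = assign_classes(res, protos, fg)
        assert mask.labels[0, 0] == int(Label.GREEN)

    def test_four_clusters_match_hand_computed_distance_table(self):
        protos = _protos()
        centroids = np.array([
            [70, 110, 55],    # nearest GREEN
            [150, 150, 70],   # nearest DEAD
            [105, 90, 60],    # nearest BACKGROUND
            [200, 180, 90],   # nearest DEAD
        ], float)
        proto_mat = np.array([p.centroid for p in protos], float)
        hand = cdist(centroids, proto_mat).argmin(axis=1)
        expected_labels = np.array([int(protos[i].label) for i in hand])
        fg = np.ones((1, 4), bool)
        res = self._result(centroids, np.arange(4))
        mask = assign_classes(res, protos, fg)
        np.testing.assert_array_equal(mask.labels.ravel(), expected_labels)

    def test_outside_foreground_forced_background(self):
        fg = np.zeros((2, 2), bool)
        fg[0, 0] = True
        res = self._result([GREEN], np.zeros(1, dtype=int))
        mask = assign_classes(res, _protos(), fg)
        assert mask.labels[0, 0] == int(Label.GREEN)
        assert (mask.labels.ravel()[1:] == int(Label.BACKGROUND)).all()

    def test_missing_prototype_is_configuration_error(self):
        protos = (ClassPrototype(Label.GREEN, GREEN),
                  ClassPrototype(Label.DEAD, (160.0, 140.0, 60.0)))
        res = self._result([GREEN], np.zeros(1, dtype=int))
        with pytest.raises(ConfigurationError, match="BACKGROUND"):
            assign_classes(res, protos, np.ones((1, 1), bool))


class TestSegmentPlant:
    def test_recovers_known_composition_within_two_points(self, small_scene,
                                                          scene_config):
        res = segment_plant(small_scene.image, scene_config)
        truth = small_scene.counts
        total = truth.total_pixels
        assert res.percentages.of_image_green == pytest.approx(
            100 * truth.pixels_green / total, abs=2.0)
        assert res.percentages.of_image_dead == pytest.approx(
            100 * truth.pixels_dead / total, abs=2.0)

    def test_all_soil_image_yields_all_background_with_warning(self):
        scene = generate_scene(SceneSpec(width=64, height=64, n_green=0,
                                         n_dead=0, seed=1))
        model = ColorThresholdModel(channel_space="rgb",
                                    lower=(80, 55, 35), upper=(140, 115, 95))
        cfg = SegmentationConfig(threshold_model=model, seed=0)
        res = segment_plant(scene.image, cfg)
        assert res.counts.pixels_background == 64 * 64
        assert res.counts.pixels_green == 0 and res.counts.pixels_dead == 0
        assert any("zero-foreground" in w for w in res.warnings)

    def test_same_image_same_config_identical_mask(self, small_scene,
                                                   scene_config):
        a = segment_plant(small_scene.image, scene_config)
        b = segment_plant(small_scene.image, scene_config)
        np.testing.assert_array_equal(a.mask.labels, b.mask.labels)

    def test_label_counts_conserve_image_size(self, small_scene, scene_config):
        res = segment_plant(small_scene.image, scene_config)
        assert res.counts.total_pixels == 256 * 256

    def test_subsampled_fit_still_covers_every_pixel(self, small_scene):
        cfg = SegmentationConfig(
            threshold_model=scene_model(small_scene), seed=7, sample_cap=500)
        res = segment_plant(small_scene.image, cfg)
        assert res.counts.total_pixels == 256 * 256
        # composition still recovered despite fitting on 500 pixels
        truth = small_scene.counts
        assert res.percentages.of_image_green == pytest.approx(
            100 * truth.pixels_green / truth.total_pixels, abs=2.0)

    def test_min_region_cleanup_removes_speckle(self, small_scene):
        cfg_raw = SegmentationConfig(threshold_model=scene_model(small_scene),
                                     seed=7)
        cfg_clean = SegmentationConfig(threshold_model=scene_model(small_scene),
                                       seed=7, min_region_size=16)
        raw = segment_plant(small_scene.image, cfg_raw)
        clean = segment_plant(small_scene.image, cfg_clean)
        assert clean.counts.plant_pixels <= raw.counts.plant_pixels
        assert clean.counts.total_pixels == raw.counts.total_pixels


def scene_model(scene, n_train=2000, seed=0):
    from conftest import threshold_from_scene

    return threshold_from_scene(scene, n_train=n_train, seed=seed)
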