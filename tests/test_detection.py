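"""Candidate extraction, BoVW encoding and the cluster/non-cluster SVM."""

import numpy as np
import pytest
from scipy.ndimage import binary_opening
from skimage.morphology import disk

from vinecompact import colorseg, detection, fixtures, metrics
from vinecompact.detection import BoVWHistogram, Codebook


class TestGrapeMask:
    def test_mask_is_exactly_grape_labels(self, seg_model, scene):
        seg = colorseg.segment(seg_model, scene.image)
        mask = detection.grape_mask(seg)
        assert np.array_equal(mask, seg.labels == 0)

    def test_all_and_none(self, seg_model):
        seg = colorseg.segment(seg_model, np.zeros((8, 8, 3), np.uint8))
        seg.labels[:] = 0
        assert detection.grape_mask(seg).all()
        seg.labels[:] = 4
        assert not detection.grape_mask(seg).any()

    def test_recovers_truth_grape_with_high_iou(self, seg_model, scene):
        seg = colorseg.segment(seg_model, scene.image)
        mask = detection.grape_mask(seg)
        truth = scene.truth == 0
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9


class TestMorphOpen:
    def test_single_pixel_vanishes(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not detection.morph_open(mask, 3).any()

    def test_large_square_matches_oracle_and_keeps_body(self):
        """A 21-square under a radius-3 disk opening: equal to an
        independent morphology implementation, and only corner pixels (the
        disk cannot reach into right-angle corners) may be shaved."""
        mask = np.zeros((31, 31), bool)
        mask[5:26, 5:26] = True
        opened = detection.morph_open(mask, 3)
        oracle = binary_opening(mask, structure=disk(3))
        assert np.array_equal(opened, oracle)
        removed = mask & ~opened
        corners = np.array([[5, 5], [5, 25], [25, 5], [25, 25]])
        for r, c in np.argwhere(removed):
            assert np.min(np.hypot(corners[:, 0] - r, corners[:, 1] - c)) <= 3
        # the body (eroded square) is untouched
        assert opened[8:23, 8:23].all()

    def test_matches_reference_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = rng.random((40, 40)) < 0.45
            mask[:3] = mask[-3:] = False  # keep the border clear: the oracle
            mask[:, :3] = mask[:, -3:] = False  # pads differently at edges
            got = detection.morph_open(mask, 2)
            want = binary_opening(mask, structure=disk(2))
            assert np.array_equal(got, want)

    def test_idempotent_and_anti_extensive(self):
        rng = np.random.default_rng(1)
        mask = rng.random((50, 50)) < 0.55
        once = detection.morph_open(mask, 3)
        assert np.array_equal(once, detection.morph_open(once, 3))
        assert not np.any(once & ~mask)

    def test_radius_zero_rejected(self):
        with pytest.raises(ValueError):
            detection.morph_open(np.ones((4, 4), bool), 0)


class TestCandidateBoxes:
    def test_empty_mask(self):
        assert detection.candidate_boxes(np.zeros((10, 10), bool)) == []

    def test_two_disjoint_blobs(self):
        mask = np.zeros((40, 40), bool)
        mask[2:14, 2:14] = True
        mask[20:35, 20:35] = True
        boxes = detection.candidate_boxes(mask, min_area=1)
        assert len(boxes) == 2
        assert boxes[0].box == (2, 2, 13, 13)
        assert boxes[1].box == (20, 20, 34, 34)

    def test_box_minimality(self):
        mask = np.zeros((10, 12), bool)
        mask[2:6, 3:10] = True
        [cand] = detection.candidate_boxes(mask, min_area=1)
        assert cand.box == (2, 3, 5, 9)
        assert cand.sub_mask.shape == (4, 7)

    def test_min_area_drops_specks(self):
        mask = np.zeros((30, 30), bool)
        mask[1:3, 1:3] = True  # 4 px speck
        mask[10:25, 10:25] = True
        boxes = detection.candidate_boxes(mask, min_area=100)
        assert len(boxes) == 1

    def test_diagonal_touching_merges_with_8_connectivity(self):
        mask = np.zeros((6, 6), bool)
        mask[0:2, 0:2] = True
        mask[2:4, 2:4] = True  # touches only diagonally
        boxes = detection.candidate_boxes(mask, min_area=1)
        assert len(boxes) == 1


class TestLocalDescriptors:
    def test_uniform_image_has_no_descriptors(self):
        img = np.full((64, 64, 3), 120, np.uint8)
        assert detection.local_descriptors(img).shape == (0, 64)

    def test_berry_texture_yields_at_least_10(self):
        crop = fixtures.generate_cluster_crop(0.8, seed=3)
        desc = detection.local_descriptors(crop)
        assert desc.shape[0] >= 10
        assert desc.shape[1] == 64
        assert np.all(np.isfinite(desc))

    def test_deterministic(self):
        crop = fixtures.generate_cluster_crop(0.6, seed=5)
        a = detection.local_descriptors(crop)
        b = detection.local_descriptors(crop)
        assert np.array_equal(a, b)

    def test_too_small_image_returns_empty_not_error(self):
        assert detection.local_descriptors(np.zeros((8, 8, 3), np.uint8)).size == 0


class TestCodebook:
    def test_k_equals_points_centroids_coincide(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 64)) * 10
        cb = detection.build_codebook([pts], k=12, seed=0)
        dists = np.linalg.norm(cb.centroids[:, None] - pts[None], axis=2)
        assert np.all(dists.min(axis=1) < 1e-9)

    def test_k_one_is_mean(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 64))
        cb = detection.build_codebook([pts], k=1, seed=0)
        assert np.allclose(cb.centroids[0], pts.mean(axis=0))

    def test_fewer_descriptors_than_k_rejected(self):
        with pytest.raises(ValueError):
            detection.build_codebook([np.zeros((5, 64))], k=10, seed=0)


class TestEncodeBoVW:
    def test_empty_set_gives_zero_vector(self):
        cb = Codebook(centroids=np.zeros((7, 64)), training_seed=0)
        hist = detection.encode_bovw(np.empty((0, 64)), cb)
        assert hist.counts.shape == (7,)
        assert hist.total == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(4)
        cb = Codebook(centroids=rng.normal(size=(10, 64)), training_seed=0)
        desc = rng.normal(size=(57, 64))
        assert detection.encode_bovw(desc, cb).total == 57

    def test_matches_brute_force_nearest_neighbour_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 12))
            n = int(rng.integers(1, 40))
            cb = Codebook(centroids=rng.normal(size=(k, 64)), training_seed=0)
            desc = rng.normal(size=(n, 64))
            got = detection.encode_bovw(desc, cb).counts
            want = np.zeros(k, int)
            for d in desc:
                dists = [float(np.sum((d - c) ** 2)) for c in cb.centroids]
                want[int(np.argmin(dists))] += 1
            assert np.array_equal(got, want)


class TestClusterClassifier:
    def test_default_hyperparameters_are_the_tuned_operating_point(self):
        rng = np.random.default_rng(6)
        h0 = [BoVWHistogram(rng.poisson(3, size=5)) for _ in range(10)]
        h1 = [BoVWHistogram(rng.poisson(3, size=5) + 40) for _ in range(10)]
        clf = detection.train_cluster_classifier(
            h0 + h1, ["non-cluster"] * 10 + ["cluster"] * 10
        )
        assert clf.box_constraint == 1.4654
        assert clf.kernel_scale == 24.628

    def test_separable_sets_train_to_accuracy_one(self):
        rng = np.random.default_rng(7)
        h0 = [BoVWHistogram(rng.poisson(2, size=8)) for _ in range(20)]
        h1 = [BoVWHistogram(rng.poisson(2, size=8) + 30) for _ in range(20)]
        labels = ["non-cluster"] * 20 + ["cluster"] * 20
        clf = detection.train_cluster_classifier(h0 + h1, labels)
        pred = clf.predict(h0 + h1)
        assert np.array_equal(pred, [False] * 20 + [True] * 20)

    def test_one_class_rejected(self):
        h = [BoVWHistogram(np.ones(4, int))] * 5
        with pytest.raises(ValueError):
            detection.train_cluster_classifier(h, ["cluster"] * 5)

    def test_decision_invariant_to_training_order(self):
        rng = np.random.default_rng(8)
        hists = [BoVWHistogram(rng.poisson(4, size=6)) for _ in range(30)]
        labels = ["cluster" if i % 2 else "non-cluster" for i in range(30)]
        clf_a = detection.train_cluster_classifier(hists, labels)
        perm = rng.permutation(30)
        clf_b = detection.train_cluster_classifier(
            [hists[i] for i in perm], [labels[i] for i in perm]
        )
        probe = [BoVWHistogram(rng.poisson(4, size=6)) for _ in range(10)]
        assert np.allclose(
            clf_a.decision_scores(probe), clf_b.decision_scores(probe), atol=1e-8
        )

    def test_crop_classifier_auc(self):
        """Berry-textured vs berry-free crops separate with high AUC."""
        n_train, n_test = 60, 40
        dens = np.linspace(0.25, 0.95, n_train)
        train_c = [fixtures.generate_cluster_crop(d, seed=1000 + i)
                   for i, d in enumerate(dens)]
        train_n = [fixtures.generate_noncluster_crop(seed=2000 + i)
                   for i in range(n_train)]
        desc = [detection.local_descriptors(c) for c in train_c + train_n]
        cb = detection.build_codebook(desc, k=50, seed=0)
        hists = [detection.encode_bovw(d, cb) for d in desc]
        clf = detection.train_cluster_classifier(
            hists, ["cluster"] * n_train + ["non-cluster"] * n_train
        )
        test = ([fixtures.generate_cluster_crop(d, seed=3000 + i)
                 for i, d in enumerate(np.linspace(0.3, 0.9, n_test))]
                + [fixtures.generate_noncluster_crop(seed=4000 + i)
                   for i in range(n_test)])
        ht = [detection.encode_bovw(detection.local_descriptors(c), cb)
              for c in test]
        scores = clf.decision_scores(ht)
        labels = [1] * n_test + [0] * n_test
        assert metrics.auc(scores, labels) >= 0.95


class TestDetectClusters:
    def test_k_mismatch_rejected(self, trained_models, scene):
        seg = colorseg.segment(trained_models["seg"], scene.image)
        wrong = Codebook(centroids=np.zeros((3, 64)), training_seed=0)
        with pytest.raises(ValueError, match="k="):
            detection.detect_clusters(
                scene.image, seg, wrong, trained_models["classifier"]
            )

    def test_scene_without_clusters_yields_nothing(self, trained_models):
        empty = fixtures.generate_scene(256, 256, 0, seed=10)
        seg = colorseg.segment(trained_models["seg"], empty.image)
        kept, scores = detection.detect_clusters(
            empty.image, seg, trained_models["codebook"],
            trained_models["classifier"],
        )
        assert kept == [] and scores.size == 0

    def test_three_well_formed_clusters_give_three_detections(self, trained_models):
        dense = fixtures.generate_scene(480, 480, 3, (0.7, 0.95), seed=905)
        seg = colorseg.segment(trained_models["seg"], dense.image)
        kept, _ = detection.detect_clusters(
            dense.image, seg, trained_models["codebook"],
            trained_models["classifier"],
        )
        assert len(kept) == 3

    def test_deterministic(self, trained_models):
        dense = fixtures.generate_scene(320, 320, 2, (0.8, 0.9), seed=33)
        seg = colorseg.segment(trained_models["seg"], dense.image)
        args = (dense.image, seg, trained_models["codebook"],
                trained_models["classifier"])
        kept_a, scores_a = detection.detect_clusters(*args)
        kept_b, scores_b = detection.detect_clusters(*args)
        assert [c.box for c in kept_a] == [c.box for c in kept_b]
        assert np.array_equal(scores_a, scores_b)
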