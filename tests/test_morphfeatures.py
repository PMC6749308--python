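"""Mask refinement rules and the 14 compactness features."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.draw import disk as draw_disk
from skimage.measure import label as cc_label

from vinecompact import fixtures, morphfeatures as mf


def make_disk(radius, pad=10):
    side = 2 * radius + 2 * pad
    mask = np.zeros((side, side), bool)
    rr, cc = draw_disk((side // 2, side // 2), radius)
    mask[rr, cc] = True
    return mask


def make_rect(height, width, pad=10):
    mask = np.zeros((height + 2 * pad, width + 2 * pad), bool)
    mask[pad:pad + height, pad:pad + width] = True
    return mask


def make_triangle(base=40, height=40, pad=10):
    """Digitised isoceles triangle, apex up."""
    mask = np.zeros((height + 2 * pad, base + 2 * pad), bool)
    cx = pad + base // 2
    for i in range(height):
        half = (i / (height - 1)) * (base / 2)
        mask[pad + i, int(cx - half):int(cx + half) + 1] = True
    return mask


class TestRefineClusterMask:
    def test_single_blob_final_equals_opened_blob(self):
        from skimage.morphology import disk, opening

        grape = make_rect(30, 30)
        refined = mf.refine_cluster_mask(grape, np.zeros_like(grape))
        # final grape = the radius-2 opened blob (square corners rounded)
        assert np.array_equal(refined.grape, opening(grape, disk(2)))
        assert not refined.rachis.any()
        # its hull restores the convex blob
        assert refined.convex_hull.sum() >= refined.grape.sum()
        assert not np.any(refined.grape & ~refined.convex_hull)

    def test_rachis_bridge_outside_hulls_is_retained(self):
        grape = np.zeros((60, 100), bool)
        for cx in (25, 75):
            rr, cc = draw_disk((30, cx), 12)
            grape[rr, cc] = True
        rachis = np.zeros_like(grape)
        rachis[27:33, 35:66] = True
        refined = mf.refine_cluster_mask(grape, rachis)
        assert refined.rachis.sum() > 0
        assert cc_label(refined.foreground, connectivity=2).max() == 1

    def test_without_bridge_only_largest_component_survives(self):
        grape = np.zeros((60, 100), bool)
        rr, cc = draw_disk((30, 25), 12)
        grape[rr, cc] = True
        rr, cc = draw_disk((30, 75), 8)
        grape[rr, cc] = True
        refined = mf.refine_cluster_mask(grape, np.zeros_like(grape))
        assert cc_label(refined.grape, connectivity=2).max() == 1
        # the surviving blob is the larger one (centred at col 25)
        assert refined.grape[:, :50].sum() > 0
        assert refined.grape[:, 50:].sum() == 0

    def test_nonbridging_rachis_outside_hulls_is_dropped(self):
        grape = make_disk(12, pad=20)
        rachis = np.zeros_like(grape)
        rachis[2:9, 2:9] = True  # far corner, touches nothing
        refined = mf.refine_cluster_mask(grape, rachis)
        assert not refined.rachis.any()

    def test_radius_2_opening_removes_thin_structures(self):
        grape = make_rect(30, 30)
        thin = np.zeros_like(grape)
        thin[5, :] = True  # 1-px line of rachis
        refined = mf.refine_cluster_mask(grape, thin)
        assert not refined.rachis.any()
        # and a 3-px-wide grape whisker vanishes too
        whisker = grape.copy()
        whisker[2:5, :] = True
        refined2 = mf.refine_cluster_mask(whisker, np.zeros_like(whisker))
        assert not refined2.grape[2:5].any()

    def test_empty_grape_after_opening_raises(self):
        grape = np.zeros((20, 20), bool)
        grape[5, 5] = True
        with pytest.raises(mf.NoClusterContentError):
            mf.refine_cluster_mask(grape, np.zeros_like(grape))

    def test_grape_and_rachis_remain_disjoint(self):
        scene = fixtures.generate_scene(320, 320, 1, (0.5, 0.5), seed=21)
        rec = scene.clusters[0]
        r0, c0, r1, c1 = rec.box
        grape = scene.truth[r0:r1 + 1, c0:c1 + 1] == 0
        rachis = scene.truth[r0:r1 + 1, c0:c1 + 1] == 1
        refined = mf.refine_cluster_mask(grape, rachis)
        assert not np.any(refined.grape & refined.rachis)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mf.refine_cluster_mask(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestRotateMajorAxis:
    def test_vertical_rectangle_unchanged_extent(self):
        rot = mf.rotate_major_axis(make_rect(40, 10))
        rows = np.nonzero(rot.any(axis=1))[0]
        cols = np.nonzero(rot.any(axis=0))[0]
        assert rows.max() - rows.min() + 1 == 40
        assert cols.max() - cols.min() + 1 == 10

    def test_horizontal_rectangle_rotates_upright(self):
        rot = mf.rotate_major_axis(make_rect(10, 40))
        rows = np.nonzero(rot.any(axis=1))[0]
        cols = np.nonzero(rot.any(axis=0))[0]
        assert abs((rows.max() - rows.min() + 1) - 40) <= 1
        assert abs((cols.max() - cols.min() + 1) - 10) <= 1

    def test_disk_is_rotation_invariant(self):
        rot = mf.rotate_major_axis(make_disk(30))
        rows = np.nonzero(rot.any(axis=1))[0]
        cols = np.nonzero(rot.any(axis=0))[0]
        length = rows.max() - rows.min() + 1
        width = cols.max() - cols.min() + 1
        assert abs(length - width) / length < 0.02

    def test_collinear_foreground_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 2:8] = True
        with pytest.raises(ValueError):
            mf.rotate_major_axis(mask)


class TestBandWidth:
    def test_rectangle_any_fraction_gives_width(self):
        rect = make_rect(40, 10)
        for f in (0.25, 0.5, 0.75):
            assert mf.band_width(rect, f) == pytest.approx(10.0)

    def test_triangle_profile_matches_analytic_within_1px(self):
        tri = make_triangle()
        rot = mf.rotate_major_axis(tri)
        widths = {f: mf.band_width(rot, f) for f in (0.25, 0.5, 0.75)}
        assert widths[0.25] < widths[0.5] < widths[0.75]
        for f in (0.25, 0.5, 0.75):
            analytic = f * 40 + 1  # linear taper, +1 px digitisation
            assert abs(widths[f] - analytic) <= 1.0

    def test_single_pixel_rows_give_width_one(self):
        mask = np.zeros((20, 9), bool)
        mask[2:18, 4] = True
        mask[2, 3:6] = True  # break collinearity at the top
        assert mf.band_width(mask, 0.5) == pytest.approx(1.0)

    def test_empty_band_raises(self):
        mask = np.zeros((40, 10), bool)
        mask[0:2, 3:7] = True
        mask[30:39, 3:7] = True
        with pytest.raises(ValueError):
            mf.band_width(mask, 0.5, tol=0.01)


class TestCompactnessFeatures:
    def test_disk_analytics(self):
        disk_mask = make_disk(50)
        refined = mf.refine_cluster_mask(disk_mask, np.zeros_like(disk_mask))
        f = mf.compactness_features(refined, mean_cluster_area=refined.foreground.sum())
        assert 0.95 <= f.RDGrape <= 1.05
        assert 4 * np.pi * 0.95 <= f.CSFGrape <= 4 * np.pi * 1.05
        assert f.AH <= 0.02
        assert 0.95 <= f.AS <= 1.05
        assert f.AB == 1.0 and f.AR == 0.0 and f.RatioRG == 0.0
        assert f.RR_in == 0.0 and f.RR_out == 0.0
        assert f.R_AoM == pytest.approx(1.0)

    def test_rectangle_aspect_and_width_ratio(self):
        rect = make_rect(40, 10)
        refined = mf.refine_cluster_mask(rect, np.zeros_like(rect))
        f = mf.compactness_features(refined, mean_cluster_area=400)
        assert f.AS == pytest.approx(0.25, abs=0.03)
        assert f.RatioW75_W25 == pytest.approx(1.0)

    def test_interior_rachis_counts_as_inside(self):
        grape = make_disk(15)
        hole_r, hole_c = grape.shape[0] // 2, grape.shape[1] // 2
        grape[hole_r - 3:hole_r + 4, hole_c - 3:hole_c + 4] = False
        rachis = np.zeros_like(grape)
        rachis[hole_r - 3:hole_r + 4, hole_c - 3:hole_c + 4] = True
        refined = mf.refine_cluster_mask(grape, rachis)
        f = mf.compactness_features(refined, mean_cluster_area=500)
        assert f.RR_in == pytest.approx(1.0)
        assert f.RR_out == pytest.approx(0.0)

    def test_rr_in_plus_rr_out_is_one_with_rachis(self):
        scene = fixtures.generate_scene(320, 320, 1, (0.4, 0.4), seed=31)
        rec = scene.clusters[0]
        r0, c0, r1, c1 = rec.box
        refined = mf.refine_cluster_mask(
            scene.truth[r0:r1 + 1, c0:c1 + 1] == 0,
            scene.truth[r0:r1 + 1, c0:c1 + 1] == 1,
        )
        f = mf.compactness_features(refined, mean_cluster_area=1000)
        if f.AR > 0:
            assert f.RR_in + f.RR_out == pytest.approx(1.0)

    def test_feature_vector_layout(self):
        disk_mask = make_disk(20)
        refined = mf.refine_cluster_mask(disk_mask, np.zeros_like(disk_mask))
        f = mf.compactness_features(refined, mean_cluster_area=100)
        vec = f.as_array()
        assert vec.shape == (14,)
        assert np.all(np.isfinite(vec))
        assert vec[0] == f.AH and vec[13] == f.R_AoM

    def test_scale_free_features_stable_under_2x(self):
        """RDGrape, CSFGrape, AS, AH, RatioW75_W25 change < 3% at 2x scale."""
        small = make_disk(30)
        big = make_disk(60)
        out = []
        for mask in (small, big):
            refined = mf.refine_cluster_mask(mask, np.zeros_like(mask))
            out.append(mf.compactness_features(refined, mean_cluster_area=1.0))
        for name in ("RDGrape", "CSFGrape", "AS", "RatioW75_W25"):
            a, b = getattr(out[0], name), getattr(out[1], name)
            assert abs(a - b) / abs(a) < 0.03, name
        assert abs(out[0].AH - out[1].AH) < 0.03  # both are ~0

    def test_zero_grape_rejected(self):
        refined = mf.RefinedClusterMask(
            grape=np.zeros((5, 5), bool),
            rachis=np.ones((5, 5), bool),
            convex_hull=np.ones((5, 5), bool),
        )
        with pytest.raises(ValueError):
            mf.compactness_features(refined, mean_cluster_area=10)

    def test_ah_decreases_with_packing_density(self):
        """Over >= 30 truth clusters the hole fraction is strongly
        anticorrelated with the generator's packing density."""
        densities, ahs = [], []
        for s in range(12):
            scene = fixtures.generate_scene(480, 480, 3, (0.2, 0.95),
                                            seed=600 + s)
            for rec in scene.clusters:
                r0, c0, r1, c1 = rec.box
                grape = scene.truth[r0:r1 + 1, c0:c1 + 1] == 0
                rachis = scene.truth[r0:r1 + 1, c0:c1 + 1] == 1
                refined = mf.refine_cluster_mask(grape, rachis)
                f = mf.compactness_features(refined, mean_cluster_area=1000)
                densities.append(rec.packing_density)
                ahs.append(f.AH)
        assert len(densities) >= 30
        rho = spearmanr(ahs, densities).statistic
        assert rho <= -0.8


class TestBatchRAoM:
    def test_identical_areas_give_ones(self):
        assert np.allclose(mf.batch_r_aom([250, 250, 250]), 1.0)

    def test_two_areas(self):
        assert np.allclose(mf.batch_r_aom([100, 300]), [0.5, 1.5])

    def test_mean_is_one_for_any_list(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            areas = rng.uniform(10, 5000, size=int(rng.integers(1, 30)))
            assert np.mean(mf.batch_r_aom(areas)) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mf.batch_r_aom([])
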