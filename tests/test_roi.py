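"""Pixelwise group comparison, ROI features, node back-projection."""

import numpy as np
import pytest

from hypdisp import RoiParams, discriminant_nodes, pixelwise_ttest, resected_node_report
from hypdisp.raster import DiskRaster, pixel_grid
from hypdisp.roi import RoiMask, roi_median_feature

from conftest import connectome_from_edges
from test_raster import make_embedding

GRID = 20


def make_raster(values_fn, seed=None):
    centers, mask = pixel_grid(GRID)
    xx, yy = np.meshgrid(centers, centers, indexing="xy")
    vals = values_fn(xx[mask], yy[mask])
    return DiskRaster(GRID, centers, mask, np.asarray(vals, dtype=float))


def noise_raster(rng, offset=0.0, patch=None):
    def fn(x, y):
        v = rng.normal(0, 1, x.size) + offset
        if patch is not None:
            v = v + np.where((x > patch[0]) & (y > patch[1]), patch[2], 0.0)
        return v

    return make_raster(fn)


class TestPixelwiseTTest:
    def test_identical_groups_give_empty_mask(self):
        rng = np.random.default_rng(0)
        group = [noise_raster(rng) for _ in range(4)]
        roi = pixelwise_ttest(group, list(group))
        assert np.all(roi.t_stat == 0.0)
        assert roi.n_pixels == 0
        assert roi.n_components == 0

    def test_nominal_type_one_error_rate(self):
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(30):
            a = [noise_raster(rng) for _ in range(5)]
            b = [noise_raster(rng) for _ in range(5)]
            fracs.append(pixelwise_ttest(a, b).significant.mean())
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - 0.05) <= 2 * se + 0.01

    def test_planted_offset_patch_recovered(self):
        rng = np.random.default_rng(2)
        a = [noise_raster(rng) for _ in range(6)]
        b = [noise_raster(rng, patch=(0.2, 0.2, 8.0)) for _ in range(6)]
        roi = pixelwise_ttest(a, b)
        centers, mask = pixel_grid(GRID)
        xx, yy = np.meshgrid(centers, centers, indexing="xy")
        in_patch = (xx[mask] > 0.2) & (yy[mask] > 0.2)
        assert roi.significant[in_patch].mean() > 0.95
        assert roi.n_components >= 1

    def test_zero_variance_pixels_flagged_non_significant(self):
        rng = np.random.default_rng(3)
        a = [make_raster(lambda x, y: np.zeros(x.size)) for _ in range(3)]
        b = [make_raster(lambda x, y: np.zeros(x.size)) for _ in range(3)]
        roi = pixelwise_ttest(a, b)
        assert roi.zero_variance.all()
        assert roi.n_pixels == 0
        assert np.all(roi.p_value == 1.0)

    def test_group_order_within_groups_irrelevant(self):
        rng = np.random.default_rng(4)
        a = [noise_raster(rng) for _ in range(4)]
        b = [noise_raster(rng) for _ in range(4)]
        m1 = pixelwise_ttest(a, b)
        m2 = pixelwise_ttest(a[::-1], b[::-1])
        np.testing.assert_array_equal(m1.significant, m2.significant)

    def test_too_few_rasters_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="at least 2"):
            pixelwise_ttest([noise_raster(rng)], [noise_raster(rng), noise_raster(rng)])


def mask_from_pixels(pixels, values=None):
    """RoiMask covering the given (row, col) pixels of the GRID."""
    centers, in_disk = pixel_grid(GRID)
    n = int(in_disk.sum())
    sig = np.zeros(n, dtype=bool)
    iy, ix = np.nonzero(in_disk)
    for r, c in pixels:
        sig[np.flatnonzero((iy == r) & (ix == c))[0]] = True
    return RoiMask(
        GRID, in_disk, sig, np.zeros(n), np.ones(n),
        components=sig.astype(int), zero_variance=np.zeros(n, dtype=bool),
    )


class TestRoiMedianFeature:
    def test_odd_count_median(self):
        roi = mask_from_pixels([(9, 9), (9, 10), (10, 9)])
        centers, in_disk = pixel_grid(GRID)
        vals = np.zeros(int(in_disk.sum()))
        vals[roi.significant] = [1.0, 5.0, 9.0]
        raster = DiskRaster(GRID, centers, in_disk, vals)
        assert roi_median_feature(raster, roi) == 5.0

    def test_even_count_median_averages_middle_pair(self):
        roi = mask_from_pixels([(9, 9), (9, 10), (10, 9), (10, 10)])
        centers, in_disk = pixel_grid(GRID)
        vals = np.zeros(int(in_disk.sum()))
        vals[roi.significant] = [1.0, 2.0, 3.0, 10.0]
        raster = DiskRaster(GRID, centers, in_disk, vals)
        assert roi_median_feature(raster, roi) == 2.5

    def test_constant_raster_gives_constant(self):
        roi = mask_from_pixels([(9, 9), (10, 10)])
        centers, in_disk = pixel_grid(GRID)
        raster = DiskRaster(GRID, centers, in_disk, np.full(int(in_disk.sum()), 4.2))
        assert roi_median_feature(raster, roi) == 4.2

    def test_empty_roi_gives_nan(self):
        roi = mask_from_pixels([])
        centers, in_disk = pixel_grid(GRID)
        raster = DiskRaster(GRID, centers, in_disk, np.zeros(int(in_disk.sum())))
        assert np.isnan(roi_median_feature(raster, roi))


class TestDiscriminantNodes:
    def _embedding_at(self, x, y):
        r = np.hypot(x, y)
        th = np.mod(np.arctan2(y, x), 2 * np.pi)
        return make_embedding(r, th)

    def test_node_in_roi_for_all_patients_included(self):
        centers, _ = pixel_grid(GRID)
        # node exactly at the center of pixel (12, 12)
        emb = self._embedding_at(np.array([centers[12]]), np.array([centers[12]]))
        roi = mask_from_pixels([(12, 12)])
        df = discriminant_nodes([emb] * 5, roi)
        assert df["discriminant"].tolist() == [True]
        assert df["fraction_in_roi"].tolist() == [1.0]

    def test_seventy_percent_excluded_at_eighty_threshold(self):
        centers, _ = pixel_grid(GRID)
        inside = self._embedding_at(np.array([centers[12]]), np.array([centers[12]]))
        outside = self._embedding_at(np.array([centers[3]]), np.array([centers[12]]))
        roi = mask_from_pixels([(12, 12)])
        embs = [inside] * 7 + [outside] * 3
        df = discriminant_nodes(embs, roi)
        assert df["fraction_in_roi"].iloc[0] == pytest.approx(0.7)
        assert not df["discriminant"].iloc[0]


class TestResectedNodeReport:
    def test_display_threshold(self):
        nodes = [f"n{i}" for i in range(12)]
        hub_edges = [("n0", x) for x in nodes[1:11]]  # n0 degree 10
        pre = connectome_from_edges(hub_edges + [("n1", "n11")], nodes)
        # n0 drops 10 -> 5: displayed; others mostly drop by 1 edge
        post = connectome_from_edges(hub_edges[:5] + [("n1", "n11")], nodes)
        rep = resected_node_report(pre, post).set_index("node_id")
        assert bool(rep.loc["n0", "displayed"])
        # 10 -> 7 case: 30% removed, below the 40% display threshold
        post2 = connectome_from_edges(hub_edges[:7] + [("n1", "n11")], nodes)
        rep2 = resected_node_report(pre, post2).set_index("node_id")
        assert not bool(rep2.loc["n0", "displayed"])

    def test_degree_zero_pre_excluded_with_flag(self):
        pre = connectome_from_edges([("A", "B")], "ABC")
        post = connectome_from_edges([("A", "B")], "ABC")
        rep = resected_node_report(pre, post).set_index("node_id")
        assert np.isnan(rep.loc["C", "fraction_removed"])
        assert not bool(rep.loc["C", "displayed"])

    def test_full_resection_reports_planted_sector(self, small_cohort):
        from hypdisp import apply_resection

        patients = small_cohort["patients"]
        truths = small_cohort["truths"]
        p = patients[0]
        truth = truths[p.subject_id]
        full_post = apply_resection(p.pre, truth, 1.0, seed=3)
        rep = resected_node_report(p.pre, full_post)
        displayed = set(int(v) for v in np.flatnonzero(rep["displayed"].to_numpy()))
        # every fully-resected node lost 100% of its connections
        assert displayed >= set(truth.resected_nodes)
        # any extra displayed node is a sector neighbor that genuinely lost
        # >= 40% of its connections to the removed sector
        sector = list(truth.resected_nodes)
        for v in displayed - set(truth.resected_nodes):
            into_sector = p.pre.adjacency[v, sector].sum()
            assert into_sector / p.pre.degrees[v] >= 0.4
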