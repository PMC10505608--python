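"""Matched-filter vessel segmentation, skeleton topology, diameters,
vessel counts, total blood volume, and the size histogram."""

import numpy as np
import pytest
from scipy import ndimage

from rsomskin import layers, vessels
from rsomskin.volio import VolumeGrid


def bar_image(width_px, shape=(80, 100), value=1.0, background=0.0):
    """Vertical bar of given width centered in the image, with half-pixel
    antialiasing (subpixel coverage)."""
    img = np.full(shape, background, dtype=float)
    cols = np.arange(shape[1])
    cov = np.clip(width_px / 2 - np.abs(cols - shape[1] // 2) + 0.5, 0, 1)
    img += (value - background) * cov[None, :]
    return img


class TestMatchedFilter:
    def test_flat_image_zero_response(self):
        resp = vessels.matched_filter_response(np.full((40, 40), 3.0))
        np.testing.assert_allclose(resp, 0.0, atol=1e-9)

    def test_response_equals_dense_correlation_oracle(self, rng):
        """Response at sampled pixels equals a direct sliding-window dot
        product with the winning kernel (brute-force correlation)."""
        img = rng.random((40, 40))
        scales = (15.0, 30.0, 45.0)
        n_th = 4
        resp = vessels.matched_filter_response(img, scales_um=scales,
                                               n_orientations=n_th)
        pad = 40
        padded = np.pad(img, pad, mode="edge")
        for _ in range(5):
            r, c = rng.integers(8, 32, size=2)
            best = -np.inf
            for s in scales:
                for theta in np.arange(n_th) * np.pi / n_th:
                    k = vessels.line_kernel(s, theta, 12.0)
                    h = k.shape[0] // 2
                    win = padded[pad + r - h: pad + r + h + 1,
                                 pad + c - h: pad + c + h + 1]
                    best = max(best, float((win * k).sum()))
            assert resp[r, c] == pytest.approx(best, rel=1e-9, abs=1e-12)

    def test_argmax_scale_tracks_bar_width(self):
        """On a three-scale bank the best-responding scale is the one nearest
        the bar width (noiseless)."""
        scales = (24.0, 48.0, 96.0)
        for w_um, expect in ((24, 24.0), (48, 48.0), (96, 96.0)):
            img = bar_image(w_um / 12)
            per_scale = [vessels.matched_filter_response(
                img, scales_um=(s,), n_orientations=4).max() for s in scales]
            assert scales[int(np.argmax(per_scale))] == expect

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            vessels.matched_filter_response(np.zeros((5, 5)), scales_um=(90.0,))


class TestSegmentVessels:
    def test_empty_response_empty_mask(self):
        assert vessels.segment_vessels(np.zeros((20, 20))).sum() == 0

    def test_two_tubes_two_components(self):
        img = bar_image(3, shape=(60, 120))
        img += np.roll(bar_image(3, shape=(60, 120)), 40, axis=1)
        resp = vessels.matched_filter_response(img)
        mask = vessels.segment_vessels(resp, image=img)
        _, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 2

    def test_raising_threshold_shrinks_mask(self):
        img = bar_image(4)
        resp = vessels.matched_filter_response(img)
        lo = vessels.segment_vessels(resp, absolute_threshold=0.2,
                                     refine_fraction=None)
        hi = vessels.segment_vessels(resp, absolute_threshold=0.6,
                                     refine_fraction=None)
        assert hi.sum() <= lo.sum()
        assert np.all(lo[hi])  # nesting

    def test_non_finite_response_rejected(self):
        bad = np.zeros((10, 10))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            vessels.segment_vessels(bad)


class TestSkeleton:
    def test_isolated_short_blob_removed(self):
        mask = np.zeros((30, 30), bool)
        mask[5, 5:8] = True  # 3-pixel isolated piece
        skel = vessels.skeletonize_and_prune(mask)
        assert skel.sum() == 0

    def test_long_line_kept(self):
        mask = np.zeros((30, 60), bool)
        mask[15, 10:50] = True
        skel = vessels.skeletonize_and_prune(mask)
        assert skel.sum() >= 38  # 40-pixel line survives (ends may trim)

    def test_attached_spur_kept(self):
        """A 3-pixel spur hanging off a long line is not isolated, so the
        <5-pixel rule leaves the component intact."""
        mask = np.zeros((30, 60), bool)
        mask[15, 5:55] = True
        mask[12:15, 30] = True  # spur touching the line
        skel = vessels.skeletonize_and_prune(mask)
        assert skel.sum() >= 50

    def test_skeleton_subset_of_mask(self):
        rng = np.random.default_rng(0)
        mask = ndimage.binary_dilation(rng.random((50, 50)) > 0.95,
                                       iterations=3)
        skel = vessels.skeletonize_and_prune(mask)
        assert np.all(mask[skel])


class TestJunctions:
    def test_straight_line_no_junctions(self):
        skel = np.zeros((20, 40), bool)
        skel[10, 5:35] = True
        assert vessels.find_junctions(skel) == []

    def test_y_single_junction(self):
        skel = np.zeros((40, 40), bool)
        skel[20, 5:20] = True          # stem
        for i in range(1, 15):          # two diagonal arms
            skel[20 - i, 19 + i] = True
            skel[20 + i, 19 + i] = True
        junctions = vessels.find_junctions(skel)
        assert len(junctions) == 1

    def test_x_crossing_merges_to_one_junction(self):
        """Two crossing diagonals: the 8-connected cluster of ≥3-neighbour
        pixels counts once.  Oracle: neighbour counts on the rasterized X."""
        n = 21
        skel = np.zeros((n, n), bool)
        for i in range(n):
            skel[i, i] = True
            skel[i, n - 1 - i] = True
        nbrs = ndimage.convolve(skel.astype(int),
                                np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
                                mode="constant")
        assert ((skel) & (nbrs >= 3)).sum() >= 1  # oracle: a junction exists
        junctions = vessels.find_junctions(skel)
        assert len(junctions) == 1
        assert np.allclose(junctions[0].centroid, (n // 2, n // 2), atol=1.5)


class TestDiameters:
    def test_disk_center_diameter(self):
        """Rasterized disk of radius 5 px: center diameter 10 px ± 1 px."""
        mask = np.zeros((30, 30), bool)
        yy, xx = np.mgrid[:30, :30]
        mask[(yy - 15) ** 2 + (xx - 15) ** 2 <= 25] = True
        d = vessels.centerline_diameters(mask, np.array([[15, 15]]), pixel_um=1.0)
        assert d[0] == pytest.approx(10.0, abs=1.0)

    def test_four_pixel_bar(self):
        mask = np.zeros((40, 40), bool)
        mask[:, 18:22] = True
        center = np.array([[20, 19], [20, 20]])
        d = vessels.centerline_diameters(mask, center, pixel_um=12.0)
        assert np.all(np.abs(d - 48.0) <= 12.0)

    def test_spacing_linearity(self):
        mask = np.zeros((40, 40), bool)
        mask[:, 18:22] = True
        pix = np.array([[20, 19]])
        d12 = vessels.centerline_diameters(mask, pix, pixel_um=12.0)
        d24 = vessels.centerline_diameters(mask, pix, pixel_um=24.0)
        assert d24 == pytest.approx(2 * d12)


def _y_network(width_px):
    """Build a network from a rasterized Y of bars ``width_px`` wide."""
    yy, xx = np.mgrid[:90, :90]
    img = np.zeros((90, 90))
    img[(np.abs(yy - 45) <= width_px / 2) & (xx <= 45)] = 1.0  # stem
    arm1 = np.abs((yy - 45) - (xx - 45)) <= width_px / 2 * 1.41
    arm2 = np.abs((yy - 45) + (xx - 45)) <= width_px / 2 * 1.41
    img[(arm1 | arm2) & (xx >= 45)] = 1.0
    return vessels.build_network(img, pixel_um=12.0)


class TestCountVessels:
    def test_small_y(self):
        net = _y_network(2)  # 24 µm arms
        svn, lvn, tvn = vessels.count_vessels(net)
        assert (svn, lvn, tvn) == (1, 0, 1)

    def test_large_y(self):
        net = _y_network(5)  # 60 µm arms
        svn, lvn, tvn = vessels.count_vessels(net)
        assert (svn, lvn, tvn) == (0, 1, 1)

    def test_empty_network_zero_counts(self):
        net = vessels.build_network(np.zeros((40, 40)))
        assert vessels.count_vessels(net) == (0, 0, 0)

    def test_partition_invariant(self, rng):
        """svn + lvn = tvn on arbitrary blob networks."""
        img = ndimage.gaussian_filter(rng.random((80, 80)), 2)
        net = vessels.build_network(img)
        svn, lvn, tvn = vessels.count_vessels(net)
        assert svn + lvn == tvn == net.n_junctions


class TestTotalBloodVolume:
    def _slab(self, shape):
        nf, ns = shape[1], shape[2]
        return layers.DermisSlab(start_index=np.zeros((nf, ns), int),
                                 stop_index=np.full((nf, ns), shape[0]),
                                 spacing_um=(3.0, 12.0, 12.0))

    def test_exact_fraction(self):
        vals = np.zeros((20, 10, 10), dtype=np.float32)
        flat = vals.reshape(-1)
        flat[:100] = 1.0  # 5 % of 2000 voxels
        grid = VolumeGrid(vals)
        assert vessels.total_blood_volume(grid, self._slab(vals.shape)) == \
            pytest.approx(5.0)

    def test_uniform_slab_is_100pct(self):
        vals = np.full((10, 5, 5), 0.7, dtype=np.float32)
        assert vessels.total_blood_volume(VolumeGrid(vals),
                                          self._slab(vals.shape)) == 100.0

    def test_scaling_invariance(self, rng):
        vals = rng.random((15, 8, 8)).astype(np.float32)
        grid = VolumeGrid(vals)
        scaled = VolumeGrid(7.3 * vals)
        slab = self._slab(vals.shape)
        assert vessels.total_blood_volume(grid, slab) == \
            vessels.total_blood_volume(scaled, slab)

    def test_all_zero_slab_warns_zero(self):
        vals = np.zeros((10, 5, 5), dtype=np.float32)
        with pytest.warns(UserWarning):
            tbv = vessels.total_blood_volume(VolumeGrid(vals),
                                             self._slab(vals.shape))
        assert tbv == 0.0


class TestDiameterHistogram:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=500.0), max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_conservation_property(self, diameters):
        """Bins always partition the ≥10 µm diameters, whatever the input."""
        counts = vessels.diameter_histogram(diameters)
        assert counts.sum() == sum(d >= 10.0 for d in diameters)
        assert counts.shape == (10,) and (counts >= 0).all()

    def test_binning_arithmetic(self):
        counts = vessels.diameter_histogram([15, 25, 105])
        np.testing.assert_array_equal(counts, [1, 1, 0, 0, 0, 0, 0, 0, 0, 1])

    def test_empty_input(self):
        np.testing.assert_array_equal(vessels.diameter_histogram([]),
                                      np.zeros(10, int))

    def test_conservation_and_sub10_exclusion(self, rng):
        d = rng.uniform(0, 150, size=200)
        counts = vessels.diameter_histogram(d)
        assert counts.sum() == (d >= 10).sum()


class TestDermisMip:
    def test_tube_footprint_and_slab_locality(self):
        vals = np.zeros((40, 20, 20), dtype=np.float32)
        vals[10, 5:15, 8] = 2.0      # inside slab
        vals[35, :, :] = 9.0         # below slab: must not leak in
        grid = VolumeGrid(vals)
        slab = layers.DermisSlab(start_index=np.full((20, 20), 5),
                                 stop_index=np.full((20, 20), 30),
                                 spacing_um=(3.0, 12.0, 12.0))
        mip = vessels.dermis_mip(grid, slab)
        assert mip[5:15, 8].tolist() == [2.0] * 10
        assert mip.max() == 2.0
        np.testing.assert_array_equal(
            mip, vessels.dermis_mip(grid, slab))  # deterministic
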