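import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.measure import label as cc_label

from hallerseg.binarize import restrict_to_choroid
from hallerseg.io import BoundaryCurve, BoundaryKind, ValidationError
from hallerseg.vessels import (
    VesselLabelMap,
    classify_large,
    distance_transform,
    extended_minima,
    morphological_close,
    morphological_open,
    watershed_separate,
)

from .oracles import (
    close_loops,
    distance_exhaustive,
    flood_watershed,
    hminima_reconstruction,
    open_loops,
)


def _disk_mask(shape, centers, radius):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    mask = np.zeros(shape, dtype=bool)
    for r0, c0 in centers:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return mask


def _bcl(mask):
    h, w = mask.shape
    cib = BoundaryCurve(np.zeros(w), BoundaryKind.CIB)
    cob = BoundaryCurve(np.full(w, float(h - 1)), BoundaryKind.COB)
    return restrict_to_choroid(mask, cib, cob)


class TestClosing:
    def test_solid_rectangle_is_fixed_point(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:12, 4:15] = True
        np.testing.assert_array_equal(morphological_close(mask, 5), mask)

    def test_merges_two_squares_across_small_gap(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[10:20, 5:15] = True
        mask[10:20, 17:27] = True  # 2-px gap
        closed = morphological_close(mask, 5)
        # oracle: explicit dilation/erosion loops
        np.testing.assert_array_equal(closed, close_loops(mask, 5))
        assert cc_label(closed, connectivity=2).max() == 1

    def test_single_pixel_survives(self):
        mask = np.zeros((15, 15), dtype=bool)
        mask[7, 7] = True
        assert morphological_close(mask, 5)[7, 7]

    @given(st.integers(0, 10**6))
    def test_extensive_and_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.3
        closed = morphological_close(mask, 3)
        assert (closed | mask).sum() == closed.sum()  # output ⊇ input
        np.testing.assert_array_equal(closed, close_loops(mask, 3))


class TestOpening:
    def test_removes_speckle_keeps_blobs_and_matches_oracle(self, rng):
        mask = rng.random((24, 24)) < 0.05
        mask[4:14, 4:14] = True
        opened = morphological_open(mask, 5)
        np.testing.assert_array_equal(opened, open_loops(mask, 5))
        assert opened[5:13, 5:13].all()
        assert (opened & ~mask).sum() == 0  # anti-extensive


class TestDistanceTransform:
    def test_single_pixel_unit_distance(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert distance_transform(mask)[4, 4] == 1.0

    def test_square_center_depth(self):
        mask = np.zeros((11, 11), dtype=bool)
        mask[3:8, 3:8] = True
        dist = distance_transform(mask)
        assert dist[5, 5] == 3.0  # oracle: nearest outside pixel 3 away
        np.testing.assert_allclose(dist, distance_exhaustive(mask))

    def test_disk_maximum_close_to_radius(self):
        mask = _disk_mask((31, 31), [(15, 15)], 10)
        dist = distance_transform(mask)
        assert abs(dist.max() - 10) <= 0.8
        np.testing.assert_allclose(dist, distance_exhaustive(mask))

    def test_all_foreground_rejected(self):
        with pytest.raises(ValidationError):
            distance_transform(np.ones((5, 5), dtype=bool))


class TestExtendedMinima:
    @staticmethod
    def _two_basin_surface():
        # plateau at 5, two depth-5 basins separated by a ridge at height 2
        profile = np.full(40, 5.0)
        profile[8:14] = 0.0
        profile[26:32] = 0.0
        profile[19:21] = 2.0
        profile[14:19] = 2.0
        profile[21:26] = 2.0
        return np.tile(profile, (7, 1))

    def test_deep_h_merges_basins(self):
        surface = self._two_basin_surface()
        markers = extended_minima(surface, 3.0)
        assert cc_label(markers, connectivity=2).max() == 1
        oracle = hminima_reconstruction(surface, 3.0)
        assert cc_label(oracle, connectivity=2).max() == 1

    def test_shallow_h_keeps_basins_separate(self):
        surface = self._two_basin_surface()
        markers = extended_minima(surface, 1.0)
        assert cc_label(markers, connectivity=2).max() == 2
        oracle = hminima_reconstruction(surface, 1.0)
        assert cc_label(oracle, connectivity=2).max() == 2
        np.testing.assert_array_equal(markers, oracle)

    def test_constant_surface_single_marker(self):
        markers = extended_minima(np.zeros((8, 8)), 1.0)
        assert markers.all()

    @pytest.mark.parametrize("h_pair", [(0.5, 1.5), (1.0, 3.0), (2.0, 4.0)])
    def test_marker_count_non_increasing_in_h(self, h_pair, rng):
        surface = rng.random((24, 24)) * 5
        lo, hi = h_pair
        n_lo = cc_label(extended_minima(surface, lo), connectivity=2).max()
        n_hi = cc_label(extended_minima(surface, hi), connectivity=2).max()
        assert n_hi <= n_lo

    def test_invalid_h(self):
        with pytest.raises(ValidationError):
            extended_minima(np.zeros((5, 5)), 0.0)


class TestWatershedSeparate:
    def test_disjoint_disks_keep_their_areas(self):
        mask = _disk_mask((40, 60), [(20, 15), (20, 45)], 8)
        vm = watershed_separate(_bcl(mask), h=2.0)
        assert vm.n_vessels == 2
        areas = sorted(vm.area_px.values())
        disk_area = int(_disk_mask((40, 60), [(20, 15)], 8).sum())
        assert areas == [disk_area, disk_area]

    def test_overlapping_disks_split_near_neck(self):
        mask = _disk_mask((40, 60), [(20, 24), (20, 36)], 8)
        assert cc_label(mask, connectivity=2).max() == 1  # truly touching
        vm = watershed_separate(_bcl(mask), h=2.0)
        assert vm.n_vessels == 2
        # each disk centre keeps its own label
        assert vm.labels[20, 24] != vm.labels[20, 36]
        assert vm.labels[20, 24] > 0 and vm.labels[20, 36] > 0
        # oracle: brute-force priority-flood watershed on the same relief
        from scipy import ndimage

        relief = -ndimage.distance_transform_edt(mask)
        markers = cc_label(extended_minima(relief, 2.0) & mask, connectivity=2)
        oracle = flood_watershed(relief, markers)
        assert oracle[20, 24] != oracle[20, 36]
        agree = (vm.labels > 0) & (oracle > 0) & mask
        # partitions agree up to label permutation away from the ridge
        left = agree & (np.arange(60)[None, :] < 30)
        right = agree & (np.arange(60)[None, :] >= 30)
        assert np.all(vm.labels[left] == vm.labels[20, 24])
        assert np.all(oracle[left] == oracle[20, 24])
        assert np.all(vm.labels[right] == vm.labels[20, 36])
        assert np.all(oracle[right] == oracle[20, 36])

    def test_large_h_prevents_spurious_split(self):
        mask = _disk_mask((30, 30), [(15, 15)], 8)
        vm = watershed_separate(_bcl(mask), h=10.0)
        assert vm.n_vessels == 1
        assert vm.area_px[1] == int(mask.sum())

    def test_empty_mask(self):
        vm = watershed_separate(_bcl(np.zeros((20, 20), dtype=bool)), h=2.0)
        assert vm.n_vessels == 0

    def test_labels_subset_of_mask(self, phantom, config):
        from hallerseg.pipeline import segment_bscan

        res = segment_bscan(phantom.image, phantom.cib, phantom.cob, config)
        assert not ((res.vessels.labels > 0) & ~res.bcl.mask).any()

    def test_min_size_filter(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2, 2] = True  # 1-px speck
        mask[10:16, 10:16] = True
        vm = watershed_separate(_bcl(mask), h=2.0, min_vessel_px=5)
        assert vm.n_vessels == 1
        assert vm.area_px[1] == 36


def _label_map(areas_positions):
    """Build a VesselLabelMap from {id: (top_row, col, area)} on a toy grid."""
    labels = np.zeros((200, 200), dtype=int)
    area_px, innermost, min_dist = {}, {}, {}
    cob = BoundaryCurve(np.full(200, 180.0), BoundaryKind.COB)
    for k, (top, col, area, dist) in areas_positions.items():
        area_px[k] = area
        innermost[k] = (top, col)
        min_dist[k] = dist
    return (
        VesselLabelMap(labels, len(area_px), area_px, innermost, min_dist),
        cob,
    )


class TestClassifyLarge:
    def test_worked_example_median_rule(self):
        vm, cob = _label_map({
            1: (100, 10, 10, 2.0),
            2: (100, 50, 20, 0.0),
            3: (100, 90, 30, 4.0),
            4: (60, 120, 25, 30.0),
            5: (60, 160, 15, 30.0),
        })
        out = classify_large(vm, cob, proximity_px=5)
        assert out.csi_adjacent_ids == frozenset({1, 2, 3})
        assert out.median_area_px == 20
        assert out.area_selected_ids == frozenset({4})
        assert out.label_ids == frozenset({1, 2, 3, 4})

    def test_all_adjacent_area_rule_vacuous(self):
        vm, cob = _label_map({k: (100, 20 * k, 10 * k, 1.0) for k in (1, 2, 3)})
        out = classify_large(vm, cob, proximity_px=5)
        assert out.label_ids == frozenset({1, 2, 3})
        assert not out.area_selected_ids

    def test_even_count_median_and_strict_inequality(self):
        vm, cob = _label_map({
            1: (100, 10, 8, 0.0),
            2: (100, 50, 12, 3.0),
            3: (60, 100, 10, 40.0),
        })
        out = classify_large(vm, cob, proximity_px=5)
        assert out.median_area_px == 10.0  # mean of middle pair (8, 12)
        assert 3 not in out.label_ids  # area 10 is NOT > 10

    def test_no_adjacent_vessels_empty_result(self):
        vm, cob = _label_map({1: (60, 10, 50, 30.0)})
        out = classify_large(vm, cob, proximity_px=5)
        assert not out.label_ids
        assert np.isnan(out.median_area_px)

    def test_invariant_to_label_renumbering(self):
        spec = {
            1: (100, 10, 10, 2.0), 2: (100, 50, 20, 0.0),
            3: (100, 90, 30, 4.0), 4: (60, 120, 25, 30.0),
        }
        vm, cob = _label_map(spec)
        permuted = {5 - k: v for k, v in spec.items()}
        vm2, _ = _label_map(permuted)
        out = classify_large(vm, cob)
        out2 = classify_large(vm2, cob)
        assert {vm.area_px[k] for k in out.label_ids} == \
               {vm2.area_px[k] for k in out2.label_ids}

    def test_phantom_strata_classification(self, phantom, config):
        """Planted Haller vessels are recovered; choriocapillaris never is."""
        from hallerseg.pipeline import segment_bscan

        res = segment_bscan(phantom.image, phantom.cib, phantom.cob, config)
        large_mask = np.isin(res.vessels.labels, sorted(res.large.label_ids))
        rr = np.arange(phantom.image.n_rows, dtype=float)[:, None]
        cc = np.arange(phantom.image.width, dtype=float)[None, :]
        for v in phantom.vessels:
            inside = (((rr - v.center_row) / v.radius_row) ** 2
                      + ((cc - v.center_col) / v.radius_col) ** 2) <= 0.5
            frac = large_mask[inside].mean()
            if v.stratum == "large":
                assert frac > 0.5, f"planted large vessel at {v.center_col} missed"
            elif v.stratum == "small":
                assert frac < 0.5, f"choriocapillaris vessel at {v.center_col} classified large"
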