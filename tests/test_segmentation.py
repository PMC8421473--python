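"""Threshold segmentation, CT-window regions, sphere VOIs, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpdquant import (RegionMask, VolumeGrid, detect_suvmax, quantify_uptake,
                      region_mean, resample_mask, segment_hu, smat, sphere_voi,
                      threshold_segment)


def suv_of(values, spacing=(4.0, 4.0, 4.0)):
    arr = np.asarray(values, dtype=float)
    return VolumeGrid(arr, spacing, units="g/ml")


def two_voxel_volume(a, b):
    data = np.zeros((4, 4, 4))
    data[0, 0, 0], data[0, 0, 1] = a, b
    mask = np.zeros((4, 4, 4), bool)
    mask[0, 0, 0] = mask[0, 0, 1] = True
    return suv_of(data), RegionMask("master", mask, (4.0, 4.0, 4.0))


class TestDetectSuvmax:
    def test_two_voxel_master(self):
        suv, master = two_voxel_volume(10.0, 3.0)
        value, loc = detect_suvmax(suv, master)
        assert value == 10.0 and loc == (0, 0, 0)

    def test_tie_broken_to_first_scan_order_voxel(self):
        suv, master = two_voxel_volume(5.0, 5.0)
        value, loc = detect_suvmax(suv, master)
        assert value == 5.0 and loc == (0, 0, 0)

    def test_empty_master_is_error(self):
        suv, _ = two_voxel_volume(1.0, 2.0)
        empty = RegionMask("m", np.zeros(suv.shape, bool), suv.spacing)
        with pytest.raises(ValueError, match="empty"):
            detect_suvmax(suv, empty)

    def test_noiseless_phantom_recovers_target(self, clean_phantom_grade2):
        from dpdquant import to_suv
        ph = clean_phantom_grade2
        suv = to_suv(ph.spect, ph.meta)
        value, loc = detect_suvmax(suv, ph.truth_masks["master_voi"])
        assert value == pytest.approx(14.05, rel=1e-9)
        assert ph.truth_masks["lv_wall"].voxels[loc]


class TestThresholdSegment:
    @pytest.mark.parametrize("f,expected_count", [(0.2, 2), (0.4, 1)])
    def test_two_voxel_enumeration(self, f, expected_count):
        # values {10, 3}: threshold 2.0 keeps both; threshold 4.0 keeps one
        suv, master = two_voxel_volume(10.0, 3.0)
        assert threshold_segment(suv, master, f).count == expected_count

    def test_f_one_keeps_exactly_the_argmax_voxels(self):
        suv, master = two_voxel_volume(10.0, 3.0)
        seg = threshold_segment(suv, master, 1.0)
        assert seg.count == 1 and seg.voxels[0, 0, 0]

    def test_zero_uptake_is_error(self):
        suv, master = two_voxel_volume(0.0, 0.0)
        with pytest.raises(ValueError, match="no uptake"):
            threshold_segment(suv, master, 0.4)

    def test_segmented_volume_non_increasing_in_f(self, noisy_phantom_grade2):
        from dpdquant import to_suv
        ph = noisy_phantom_grade2
        suv = to_suv(ph.spect, ph.meta)
        vols = [threshold_segment(suv, ph.truth_masks["master_voi"], f).count
                for f in (0.1, 0.2, 0.4, 0.6, 0.8)]
        assert vols == sorted(vols, reverse=True)

    @given(st.floats(0.1, 50.0), st.sampled_from([0.2, 0.4, 0.6]))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k, f):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.1, 10.0, (6, 6, 6))
        suv = suv_of(data)
        master = RegionMask("m", np.ones(data.shape, bool), suv.spacing)
        seg1 = threshold_segment(suv, master, f)
        seg2 = threshold_segment(suv_of(data * k), master, f)
        assert np.array_equal(seg1.voxels, seg2.voxels)
        assert smat(suv_of(data * k), seg2) == pytest.approx(
            k * smat(suv, seg1), rel=1e-9)

    def test_lowest_threshold_excludes_cold_lumen(self, clean_phantom_grade2):
        # the stated purpose of SMaT: drop blood-pool voxels in the master VOI
        from dpdquant import to_suv
        ph = clean_phantom_grade2
        assert ph.scenario.lumen_suv < 0.2 * ph.scenario.myocardial_suv
        suv = to_suv(ph.spect, ph.meta)
        seg = threshold_segment(suv, ph.truth_masks["master_voi"], 0.2)
        assert not np.any(seg.voxels & ph.truth_masks["lumen"].voxels)


class TestSmat:
    def test_hand_mean(self):
        suv, master = two_voxel_volume(10.0, 3.0)
        assert smat(suv, master) == pytest.approx(6.5)

    def test_uniform_region_any_threshold(self):
        suv, master = two_voxel_volume(4.0, 4.0)
        for f in (0.2, 0.4, 0.6):
            seg = threshold_segment(suv, master, f)
            assert smat(suv, seg) == pytest.approx(4.0)

    def test_grade1_patient_values_average_to_reported_mean(self):
        # two mild-uptake patients' 40%-threshold means: 1.27 and 1.71
        assert np.mean([1.27, 1.71]) == pytest.approx(1.49)

    def test_smat_ordering_and_lower_bound(self, noisy_phantom_grade2):
        from dpdquant import to_suv
        ph = noisy_phantom_grade2
        suv = to_suv(ph.spect, ph.meta)
        m = quantify_uptake(suv, ph.truth_masks["master_voi"])
        assert m.smat[0.2] <= m.smat[0.4] <= m.smat[0.6] <= m.suv_max
        for f in (0.2, 0.4, 0.6):
            assert m.smat[f] >= f * m.suv_max


class TestSegmentHU:
    def test_phantom_bone_mask_is_exact(self, clean_phantom_grade2):
        ph = clean_phantom_grade2
        bone = segment_hu(ph.ct, "bone")
        assert np.array_equal(bone.voxels, ph.truth_masks["bone"].voxels)

    def test_phantom_lung_mask_matches_truth(self, clean_phantom_grade2):
        ph = clean_phantom_grade2
        lung = segment_hu(ph.ct, "lung")
        assert np.array_equal(lung.voxels, ph.truth_masks["lungs"].voxels)

    def test_all_soft_tissue_ct_gives_empty_bone_mask(self):
        ct = VolumeGrid(np.full((8, 8, 8), 40.0), (4.0,) * 3, units="HU")
        with pytest.warns(UserWarning, match="empty"):
            assert segment_hu(ct, "bone").count == 0


class TestSphereVoi:
    def test_closed_form_radius(self):
        assert (3.0 * 25_000.0 / (4.0 * np.pi)) ** (1 / 3) == \
            pytest.approx(18.139, abs=1e-3)

    def test_realized_volume_close_to_nominal_on_fine_grid(self):
        grid = VolumeGrid(np.zeros((60, 60, 60)), (1.0, 1.0, 1.0))
        sphere = sphere_voi(grid, (30.0, 30.0, 30.0), 25.0)
        assert sphere.volume_ml == pytest.approx(25.0, rel=0.02)

    def test_subvoxel_sphere_degenerates_to_nearest_voxel(self):
        grid = VolumeGrid(np.zeros((10, 10, 10)), (10.0, 10.0, 10.0))
        with pytest.warns(UserWarning, match="nearest voxel"):
            sphere = sphere_voi(grid, (51.0, 52.0, 53.0), 0.01)
        assert sphere.count == 1

    def test_sphere_beyond_grid_is_error(self):
        grid = VolumeGrid(np.zeros((10, 10, 10)), (4.0, 4.0, 4.0))
        with pytest.raises(ValueError, match="beyond"):
            sphere_voi(grid, (2.0, 20.0, 20.0), 25.0)


class TestRegionMean:
    def test_two_voxel_mean(self):
        suv, master = two_voxel_volume(2.0, 4.0)
        assert region_mean(suv, master) == pytest.approx(3.0)

    def test_empty_mask_is_error(self):
        suv, _ = two_voxel_volume(1.0, 1.0)
        empty = RegionMask("e", np.zeros(suv.shape, bool), suv.spacing)
        with pytest.raises(ValueError, match="empty"):
            region_mean(suv, empty)


class TestResampleMask:
    def test_identity_on_same_grid(self, clean_phantom_grade2):
        ph = clean_phantom_grade2
        master = ph.truth_masks["master_voi"]
        out = resample_mask(master, ph.spect)
        assert np.array_equal(out.voxels, master.voxels)

    def test_fine_ct_cube_onto_coarse_spect_preserves_volume(self):
        # 20 mm cube drawn on a 2 mm CT grid, projected to a 4 mm SPECT grid
        ct_mask = np.zeros((40, 40, 40), bool)
        ct_mask[10:20, 10:20, 10:20] = True  # 20 mm cube => 8 ml
        mask = RegionMask("cube", ct_mask, (2.0, 2.0, 2.0))
        spect = VolumeGrid(np.zeros((20, 20, 20)), (4.0, 4.0, 4.0))
        out = resample_mask(mask, spect)
        # within one surface-voxel layer of the analytic volume
        n_surface = 6 * (20.0 / 4.0) ** 2
        assert abs(out.volume_ml - 8.0) <= n_surface * spect.voxel_volume_ml

    def test_empty_mask_stays_empty(self):
        mask = RegionMask("e", np.zeros((40, 40, 40), bool), (2.0, 2.0, 2.0))
        spect = VolumeGrid(np.zeros((20, 20, 20)), (4.0, 4.0, 4.0))
        assert resample_mask(mask, spect).count == 0

    def test_disjoint_fields_of_view_error(self):
        mask = RegionMask("m", np.ones((10, 10, 10), bool), (2.0, 2.0, 2.0),
                          origin=(1000.0, 1000.0, 1000.0))
        spect = VolumeGrid(np.zeros((10, 10, 10)), (4.0, 4.0, 4.0))
        with pytest.raises(ValueError, match="overlap"):
            resample_mask(mask, spect)
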