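import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infarctvol.brainextract import BrainMask
from infarctvol.iic import IICResult
from infarctvol.io_nifti import CTVolume
from infarctvol.volumetry import (
    DifferenceMap,
    difference_map,
    estimate_infarct_volume,
    masked_volume_cc,
    split_hemispheres,
    threshold_map,
)


def _toy(shape=(8, 6, 4), spacing=(1.0, 1.0, 1.0)):
    data = np.full(shape, 30.0, np.float32)
    vol = CTVolume(data, spacing)
    mask = BrainMask(np.ones(shape, bool), spacing)
    return vol, mask


def _iic_from_restored(vol, restored_data, mask):
    restored = CTVolume(restored_data.astype(np.float32), vol.spacing)
    field = np.where(mask.mask, vol.data - restored.data, 0.0).astype(np.float32)
    return IICResult(restored, field, 1, True, "manual")


class TestDifferenceMap:
    def test_identity_restored_gives_zero_map(self):
        vol, mask = _toy()
        res = _iic_from_restored(vol, vol.data.copy(), mask)
        dmap = difference_map(vol, res, mask)
        assert np.all(dmap.values == 0)

    def test_constant_offset(self):
        vol, mask = _toy()
        res = _iic_from_restored(vol, vol.data + 2.0, mask)
        dmap = difference_map(vol, res, mask)
        assert np.all(dmap.values[mask.mask] == -2.0)

    def test_off_mask_always_zero(self):
        vol, _ = _toy()
        half = np.zeros(vol.shape, bool)
        half[:4] = True
        mask = BrainMask(half, vol.spacing)
        res = _iic_from_restored(vol, vol.data + 5.0, mask)
        dmap = difference_map(vol, res, mask)
        assert np.all(dmap.values[~half] == 0)

    def test_shape_mismatch_rejected(self):
        vol, mask = _toy()
        other = CTVolume(np.zeros((4, 4, 4), np.float32), vol.spacing)
        res = _iic_from_restored(other, other.data, BrainMask(np.ones((4, 4, 4), bool), vol.spacing))
        with pytest.raises(ValueError):
            difference_map(vol, res, mask)


class TestThreshold:
    def test_boundary_semantics_closed_at_threshold(self):
        """-1.5 is selected; -1.4 is not."""
        vol, mask = _toy(shape=(5, 1, 1))
        values = np.array([-3.0, -1.6, -1.5, -1.4, 0.0]).reshape(5, 1, 1)
        dmap = DifferenceMap(values, mask)
        sel = threshold_map(dmap, -1.5)
        assert sel.ravel().tolist() == [True, True, True, False, False]

    def test_all_zero_map_selects_nothing(self):
        vol, mask = _toy()
        dmap = DifferenceMap(np.zeros(vol.shape), mask)
        assert not threshold_map(dmap).any()

    def test_nonnegative_threshold_rejected(self):
        vol, mask = _toy()
        dmap = DifferenceMap(np.zeros(vol.shape), mask)
        with pytest.raises(ValueError):
            threshold_map(dmap, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_more_negative_threshold_never_selects_more(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 2, size=(6, 6, 3))
        mask = BrainMask(rng.random((6, 6, 3)) > 0.3, (1, 1, 1))
        dmap = DifferenceMap(np.where(mask.mask, values, 0.0), mask)
        s1 = threshold_map(dmap, -1.0)
        s2 = threshold_map(dmap, -2.0)
        assert np.all(s1[s2])  # s2 subset of s1


class TestVolumeArithmetic:
    @pytest.mark.parametrize(
        "count, spacing, expected_cc",
        [
            (2000, (1.875, 1.875, 5.0), 35.15625),
            (0, (1.875, 1.875, 5.0), 0.0),
            (1, (1.0, 1.0, 1.0), 0.001),
        ],
    )
    def test_volume_from_count(self, count, spacing, expected_cc):
        sel = np.zeros(4000, bool)
        sel[:count] = True
        assert masked_volume_cc(sel, spacing) == pytest.approx(expected_cc)

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            masked_volume_cc(np.ones(5, bool), (1.0, -1.0, 1.0))


class TestHemisphereSplit:
    def test_partition_is_disjoint_and_covers(self, brain_mask, cupping_phantom):
        split = split_hemispheres(brain_mask, cupping_phantom.image, "right")
        assert not np.any(split.ipsi_mask & split.contra_mask)
        union = split.ipsi_mask | split.contra_mask
        # all mask voxels off the midline plane are covered
        uncovered = brain_mask.mask & ~union
        if uncovered.any():
            planes = np.unique(np.nonzero(uncovered)[0])
            assert len(planes) == 1  # only a single midline plane may be excluded

    def test_symmetric_mask_splits_evenly(self, brain_mask):
        vol = _toy(brain_mask.mask.shape, brain_mask.spacing)[0]
        split = split_hemispheres(brain_mask, vol, "right")
        total = brain_mask.voxel_count
        assert abs(int(split.ipsi_mask.sum()) - int(split.contra_mask.sum())) / total < 0.02

    def test_centered_mask_midline_at_grid_center(self):
        vol, mask = _toy(shape=(8, 6, 4))
        split = split_hemispheres(mask, vol, "right")
        assert split.midline_index == pytest.approx(3.5)

    def test_auto_side_deferred(self, brain_mask, cupping_phantom):
        with pytest.raises(ValueError, match="auto"):
            split_hemispheres(brain_mask, cupping_phantom.image, "auto")


class TestEstimateInfarctVolume:
    def test_subtraction_contract(self):
        """ipsi 30 cc and contra 14 cc yield 16 cc."""
        shape, spacing = (20, 10, 10), (1.0, 10.0, 10.0)  # 0.1 cc per voxel
        vol = CTVolume(np.full(shape, 30.0, np.float32), spacing)
        mask = BrainMask(np.ones(shape, bool), spacing)
        restored = vol.data.copy().astype(np.float64)
        # right half-grid: 300 voxels at -2 HU; left: 140 voxels
        restored[10:, :3, :] += 2.0
        restored[:10, :2, :7] += 2.0
        res = _iic_from_restored(vol, restored, mask)
        rep = estimate_infarct_volume(vol, mask, res, side_ipsi="right")
        assert rep.vol_ipsi_cc == pytest.approx(30.0)
        assert rep.vol_contra_cc == pytest.approx(14.0)
        assert rep.infarct_cc == pytest.approx(16.0)

    def test_null_phantom_near_zero(self, cupping_phantom, brain_mask, em_result):
        rep = estimate_infarct_volume(
            cupping_phantom.image, brain_mask, em_result, side_ipsi="right"
        )
        assert abs(rep.infarct_cc) < 2.0

    def test_auto_side_finds_right_lesion(self, lesioned45, lesioned45_fit):
        rep = estimate_infarct_volume(
            lesioned45.image,
            lesioned45_fit.brain_mask,
            lesioned45_fit.iic_result,
            side_ipsi="auto",
        )
        assert rep.side_ipsi == "right"
        assert rep.infarct_cc > 0

    def test_forced_wrong_side_is_negative_with_warning(self, lesioned45, lesioned45_fit):
        rep = estimate_infarct_volume(
            lesioned45.image,
            lesioned45_fit.brain_mask,
            lesioned45_fit.iic_result,
            side_ipsi="left",
        )
        assert rep.infarct_cc < 0
        assert rep.warnings

    def test_decomposition_oracle_equivalence(self, lesioned45, lesioned45_fit):
        """infarct_cc equals the independently recomposed hemisphere volumes."""
        mask = lesioned45_fit.brain_mask
        res = lesioned45_fit.iic_result
        rep = estimate_infarct_volume(lesioned45.image, mask, res, side_ipsi="right")
        dmap = difference_map(lesioned45.image, res, mask)
        sel = threshold_map(dmap, rep.threshold_hu)
        split = split_hemispheres(mask, lesioned45.image, "right")
        v_i = masked_volume_cc(sel & split.ipsi_mask, lesioned45.image.spacing)
        v_c = masked_volume_cc(sel & split.contra_mask, lesioned45.image.spacing)
        assert rep.infarct_cc == pytest.approx(v_i - v_c, abs=1e-9)

    def test_threshold_monotonicity(self, lesioned45, lesioned45_fit):
        mask = lesioned45_fit.brain_mask
        res = lesioned45_fit.iic_result
        prev_i, prev_c = np.inf, np.inf
        for thr in (-1.5, -2.5, -3.5):
            rep = estimate_infarct_volume(
                lesioned45.image, mask, res, side_ipsi="right", upper_hu=thr
            )
            assert rep.vol_ipsi_cc <= prev_i
            assert rep.vol_contra_cc <= prev_c
            prev_i, prev_c = rep.vol_ipsi_cc, rep.vol_contra_cc

    def test_split_and_threshold_commute(self, lesioned45, lesioned45_fit):
        """Thresholding then splitting equals splitting then thresholding."""
        mask = lesioned45_fit.brain_mask
        res = lesioned45_fit.iic_result
        dmap = difference_map(lesioned45.image, res, mask)
        split = split_hemispheres(mask, lesioned45.image, "right")
        sel_then_split = threshold_map(dmap) & split.ipsi_mask
        hemi_dmap = DifferenceMap(
            np.where(split.ipsi_mask, dmap.values, 0.0),
            BrainMask(split.ipsi_mask, mask.spacing),
        )
        split_then_sel = threshold_map(hemi_dmap)
        assert np.array_equal(sel_then_split, split_then_sel)
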