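"""NAWM/CST masks, lateralization indices, slice profiles, lesion maps."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemiacm.phantom import ValidationError, hemisphere_labels
from hemiacm.roi import (
    RoiMask,
    lateralization_index,
    lesion_frequency_map,
    make_cst_mask,
    make_nawm_mask,
    roi_means,
    slice_li_profile,
    split_nawm,
)

SHAPE = (10, 10, 10)


class TestMakeNawmMask:
    def _grids(self):
        wm = np.zeros(SHAPE, bool)
        wm[2:8, 2:8, 2:8] = True
        lesion = np.zeros(SHAPE, bool)
        fa = np.full(SHAPE, 0.5)
        return wm, lesion, fa

    def test_fa_just_below_floor_excluded_at_floor_kept(self):
        wm, lesion, fa = self._grids()
        fa[3, 3, 3] = 0.29
        fa[4, 4, 4] = 0.30
        nawm = make_nawm_mask(wm, lesion, fa)
        assert not nawm.mask[3, 3, 3]
        assert nawm.mask[4, 4, 4]

    def test_lesioned_voxel_excluded_despite_high_fa(self):
        wm, lesion, fa = self._grids()
        lesion[5, 5, 5] = True
        fa[5, 5, 5] = 0.9
        nawm = make_nawm_mask(wm, lesion, fa)
        assert not nawm.mask[5, 5, 5]

    def test_misaligned_grids_rejected(self):
        wm, lesion, fa = self._grids()
        with pytest.raises(ValidationError, match="misaligned"):
            make_nawm_mask(wm, lesion, fa[:5])


class TestMakeCstMask:
    def test_probability_boundary_is_strict(self):
        p = np.zeros(SHAPE)
        p[2, 5, 5] = 0.11
        p[3, 5, 5] = 0.10
        left, right = make_cst_mask(p)
        assert left.mask[2, 5, 5]
        assert not left.mask[3, 5, 5]

    def test_empty_atlas_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            make_cst_mask(np.zeros(SHAPE))

    def test_probabilities_outside_unit_interval_rejected(self):
        p = np.zeros(SHAPE)
        p[0, 0, 0] = 1.2
        with pytest.raises(ValidationError, match="probabilities"):
            make_cst_mask(p)

    def test_hemisphere_split_excludes_midline(self):
        p = np.full(SHAPE, 0.5)
        left, right = make_cst_mask(p)
        mid = SHAPE[0] // 2
        assert not left.mask[mid].any() and not right.mask[mid].any()
        left.validate()
        right.validate()


class TestRoiMeans:
    def test_constant_map_and_two_voxel_mean(self):
        const = np.full(SHAPE, 4.2)
        mask = np.zeros(SHAPE, bool)
        mask[1, 1, 1] = True
        roi = RoiMask(mask, "tiny", "both")
        assert roi_means(const, {"tiny": roi})["tiny"] == pytest.approx(4.2)
        m2 = np.zeros(SHAPE, bool)
        m2[0, 0, 0] = m2[0, 0, 1] = True
        vals = np.zeros(SHAPE)
        vals[0, 0, 0], vals[0, 0, 1] = 1.0, 3.0
        assert roi_means(vals, {"pair": RoiMask(m2, "pair", "both")})["pair"] == 2.0

    def test_matches_naive_summation_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=SHAPE)
        mask = rng.random(SHAPE) < 0.3
        roi = RoiMask(mask, "rand", "both")
        got = roi_means(vals, {"rand": roi})["rand"]
        total, n = 0.0, 0
        for idx in np.ndindex(SHAPE):
            if mask[idx]:
                total += vals[idx]
                n += 1
        assert abs(got - total / n) < 1e-12

    def test_empty_mask_error_names_the_mask(self):
        with pytest.raises(ValidationError, match="empty-roi"):
            roi_means(np.zeros(SHAPE), {"empty-roi": RoiMask(np.zeros(SHAPE, bool), "e", "both")})


class TestLateralizationIndex:
    def test_symmetry_extremes_and_errors(self):
        assert lateralization_index(5.0, 5.0) == 0.0
        assert lateralization_index(2.0, 0.0) == 100.0
        assert lateralization_index(0.0, 2.0) == -100.0
        with pytest.raises(ValidationError):
            lateralization_index(0.0, 0.0)
        with pytest.raises(ValidationError):
            lateralization_index(-1.0, 2.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
        b=st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        li = lateralization_index(a, b)
        assert -100.0 <= li <= 100.0
        assert li == pytest.approx(-lateralization_index(b, a), abs=1e-9)
        assert (li > 0) == (a > b) or li == 0


class TestSliceLiProfile:
    def _setup(self):
        labels = hemisphere_labels(SHAPE)
        cst_l = RoiMask((labels == 1) & (np.arange(SHAPE[0])[:, None, None] == 2), "CST", "left")
        cst_r = RoiMask((labels == 2) & (np.arange(SHAPE[0])[:, None, None] == 7), "CST", "right")
        left = np.full(SHAPE, 10.0)
        right = np.full(SHAPE, 10.0)
        return left, right, cst_l, cst_r

    def test_doubling_one_slice_changes_only_that_slice(self):
        left, right, cst_l, cst_r = self._setup()
        base = slice_li_profile(left, right, cst_l, cst_r)
        left2 = left.copy()
        left2[:, :, 4] *= 2.0
        bumped = slice_li_profile(left2, right, cst_l, cst_r)
        changed = np.flatnonzero(
            np.nan_to_num(bumped.li) != np.nan_to_num(base.li)
        )
        assert list(changed) == [4]
        assert bumped.li[4] == pytest.approx(lateralization_index(20.0, 10.0))

    def test_undefined_slices_are_excluded(self):
        left, right, cst_l, cst_r = self._setup()
        mask = cst_l.mask.copy()
        mask[:, :, 0] = False  # no left CST on slice 0
        profile = slice_li_profile(left, right, RoiMask(mask, "CST", "left"), cst_r)
        assert not profile.defined[0]
        assert np.isnan(profile.li[0])
        assert 0 not in profile.defined_slices()

    def test_whole_roi_li_recovered_from_slice_means(self):
        # voxel-count-weighted combination of slice means reproduces the
        # whole-ROI lateralization index
        rng = np.random.default_rng(8)
        left = rng.uniform(1, 10, SHAPE)
        right = rng.uniform(1, 10, SHAPE)
        labels = hemisphere_labels(SHAPE)
        cst_l = RoiMask((labels == 1) & (rng.random(SHAPE) < 0.4), "CST", "left")
        cst_r = RoiMask((labels == 2) & (rng.random(SHAPE) < 0.4), "CST", "right")
        profile = slice_li_profile(left, right, cst_l, cst_r)
        nl = cst_l.mask.sum(axis=(0, 1)).astype(float)
        nr = cst_r.mask.sum(axis=(0, 1)).astype(float)
        z = profile.defined
        mean_l = np.array([left[:, :, i][cst_l.mask[:, :, i]].mean() for i in range(SHAPE[2])])
        lw = np.sum(nl[z] * mean_l[z]) / nl[z].sum()
        mean_r = np.array([right[:, :, i][cst_r.mask[:, :, i]].mean() for i in range(SHAPE[2])])
        rw = np.sum(nr[z] * mean_r[z]) / nr[z].sum()
        whole_l = left[cst_l.mask].mean()
        whole_r = right[cst_r.mask].mean()
        assert lw == pytest.approx(whole_l)
        assert rw == pytest.approx(whole_r)
        assert lateralization_index(lw, rw) == pytest.approx(
            lateralization_index(whole_l, whole_r)
        )


class TestSymmetricPhantomProfiles:
    def test_mirror_symmetric_phantom_has_near_zero_group_li_profile(self, small_build):
        """Tracking both hemispheres of an undamaged, mirror-symmetric phantom
        across a 20-subject group leaves every slice's mean ACM-LI near zero."""
        from hemiacm.phantom import cst_probability_map
        from hemiacm.tracking import TrackingParams, track_and_count

        atlas = cst_probability_map(small_build.spec)
        cst_l, cst_r = make_cst_mask(atlas)
        roi_l = RoiMask(cst_l.mask & small_build.wm_mask, "CST-WM", "left")
        roi_r = RoiMask(cst_r.mask & small_build.wm_mask, "CST-WM", "right")
        profiles = []
        for subject in range(20):
            acm = {}
            for i, hemi in enumerate(("left", "right")):
                acm[hemi] = track_and_count(
                    small_build.field, small_build.wm_mask, hemi,
                    TrackingParams(seeds_per_voxel=6, rng_seed=700 + 2 * subject + i),
                ).counts.astype(float)
            profiles.append(slice_li_profile(acm["left"], acm["right"], roi_l, roi_r).li)
        profiles = np.asarray(profiles)
        defined = np.all(np.isfinite(profiles), axis=0)
        assert defined.any()
        group_mean = profiles[:, defined].mean(axis=0)
        assert np.all(np.abs(group_mean) < 2.0)


class TestPartition:
    def test_cst_and_noncst_nawm_partition_nawm_per_side(self, small_build):
        rng = np.random.default_rng(1)
        fa = rng.uniform(0.2, 0.8, small_build.wm_mask.shape)
        nawm = make_nawm_mask(small_build.wm_mask, small_build.lesion_mask, fa)
        from hemiacm.phantom import cst_probability_map

        atlas = cst_probability_map(small_build.spec)
        cst_l, cst_r = make_cst_mask(atlas)
        rois = split_nawm(nawm, cst_l, cst_r)
        labels = hemisphere_labels(nawm.mask.shape)
        for hemi, code in (("left", 1), ("right", 2)):
            a = rois[("CST-NAWM", hemi)].mask
            b = rois[("non-CST-NAWM", hemi)].mask
            assert not (a & b).any()
            assert np.array_equal(a | b, nawm.mask & (labels == code))


class TestLesionFrequencyMap:
    def test_disjoint_identical_and_oracle(self):
        rng = np.random.default_rng(5)
        a = np.zeros(SHAPE, bool)
        b = np.zeros(SHAPE, bool)
        c = np.zeros(SHAPE, bool)
        a[0, 0, 0] = b[1, 1, 1] = c[2, 2, 2] = True
        out = lesion_frequency_map([a, b, c])
        assert set(np.unique(out)) == {0, 1}
        same = rng.random(SHAPE) < 0.2
        out2 = lesion_frequency_map([same] * 4)
        assert np.all(out2[same] == 4)
        cohort = [rng.random(SHAPE) < 0.15 for _ in range(6)]
        out3 = lesion_frequency_map(cohort)
        naive = np.zeros(SHAPE, int)
        for m in cohort:
            for idx in np.ndindex(SHAPE):
                naive[idx] += int(m[idx])
        assert np.array_equal(out3, naive)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValidationError, match="binary"):
            lesion_frequency_map([np.full(SHAPE, 0.5)])
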