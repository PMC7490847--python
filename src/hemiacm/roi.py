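"""Region-of-interest masks, lateralization indices, and lesion maps.

Masks follow the clinical convention for normal-appearing white matter
(NAWM): the white-matter segmentation minus delineated lesions, with
low-anisotropy voxels (FA < 0.3) removed to suppress partial-volume
contamination at tissue boundaries.  The corticospinal-tract (CST) mask
keeps atlas voxels with a tract probability strictly above 10%.  The
lateralization index LI = 100 * (left - right) / (left + right) is
positive when the left-hemisphere value dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import HEMI_CODE, ValidationError, hemisphere_labels

__all__ = [
    "RoiMask",
    "SliceLiProfile",
    "make_nawm_mask",
    "make_cst_mask",
    "split_nawm",
    "roi_means",
    "lateralization_index",
    "slice_li_profile",
    "lesion_frequency_map",
]

FA_FLOOR = 0.3
CST_PROBABILITY_FLOOR = 0.10


@dataclass
class RoiMask:
    mask: np.ndarray
    name: str
    hemisphere: str  # left / right / both

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def validate(self) -> None:
        if self.mask.dtype != bool:
            raise ValidationError(f"mask {self.name!r} must be boolean")
        if self.hemisphere in ("left", "right"):
            labels = hemisphere_labels(self.mask.shape)
            if np.any(self.mask & (labels != HEMI_CODE[self.hemisphere])):
                raise ValidationError(
                    f"mask {self.name!r} contains voxels outside the {self.hemisphere} hemisphere"
                )


def _check_aligned(*grids: np.ndarray) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValidationError(f"misaligned grids: {sorted(shapes)}")


def make_nawm_mask(
    wm_mask: np.ndarray,
    lesion_mask: np.ndarray,
    fa_map: np.ndarray,
    fa_floor: float = FA_FLOOR,
) -> RoiMask:
    """Normal-appearing white matter: WM minus lesions minus low-FA voxels.

    Voxels with FA strictly below ``fa_floor`` are removed; a voxel at
    exactly the floor is kept.
    """
    _check_aligned(wm_mask, lesion_mask, fa_map)
    mask = wm_mask.astype(bool) & ~lesion_mask.astype(bool) & ~(fa_map < fa_floor)
    return RoiMask(mask=mask, name="NAWM", hemisphere="both")


def make_cst_mask(
    atlas_probability_map: np.ndarray,
    prob_floor: float = CST_PROBABILITY_FLOOR,
) -> tuple[RoiMask, RoiMask]:
    """Left/right CST masks from a tract-probability atlas.

    Voxels with probability strictly greater than ``prob_floor`` are
    included (a voxel at exactly the floor is excluded).
    """
    p = np.asarray(atlas_probability_map, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("atlas probabilities must lie in [0, 1]")
    supra = p > prob_floor
    labels = hemisphere_labels(p.shape)
    left = RoiMask(supra & (labels == HEMI_CODE["left"]), "CST", "left")
    right = RoiMask(supra & (labels == HEMI_CODE["right"]), "CST", "right")
    for m in (left, right):
        if m.n_voxels == 0:
            warnings.warn(f"CST mask for the {m.hemisphere} hemisphere is empty", stacklevel=2)
    return left, right


def split_nawm(nawm: RoiMask, cst_left: RoiMask, cst_right: RoiMask) -> dict:
    """Partition NAWM per hemisphere into CST-NAWM and non-CST-NAWM."""
    labels = hemisphere_labels(nawm.mask.shape)
    out = {}
    for hemi, cst in (("left", cst_left), ("right", cst_right)):
        hemi_nawm = nawm.mask & (labels == HEMI_CODE[hemi])
        out[("CST-NAWM", hemi)] = RoiMask(hemi_nawm & cst.mask, "CST-NAWM", hemi)
        out[("non-CST-NAWM", hemi)] = RoiMask(hemi_nawm & ~cst.mask, "non-CST-NAWM", hemi)
    return out


def roi_means(metric_map: np.ndarray, masks) -> dict:
    """Arithmetic mean of the metric over each mask's voxels."""
    out = {}
    items = masks.items() if hasattr(masks, "items") else [(m.name, m) for m in masks]
    for key, roi in items:
        _check_aligned(metric_map, roi.mask)
        if roi.n_voxels == 0:
            raise ValidationError(f"ROI mask {key!r} is empty")
        out[key] = float(metric_map[roi.mask].mean())
    return out


def lateralization_index(left_value: float, right_value: float) -> float:
    """LI = 100 * (left - right) / (left + right); in [-100, 100] for
    non-negative inputs, positive when left dominates."""
    if left_value < 0 or right_value < 0:
        raise ValidationError("lateralization index requires non-negative inputs")
    total = left_value + right_value
    if total == 0:
        raise ValidationError("lateralization index undefined: left + right = 0")
    # ratio first, then scale: keeps |LI| <= 100 against float rounding
    li = 100.0 * ((left_value - right_value) / total)
    return float(np.clip(li, -100.0, 100.0))


@dataclass
class SliceLiProfile:
    """Per-axial-slice lateralization of a metric within paired ROIs."""

    slice_index: np.ndarray  # z indices, full axis
    li: np.ndarray  # LI per slice (nan where undefined)
    defined: np.ndarray  # both sides non-empty with positive total

    def defined_slices(self) -> np.ndarray:
        return self.slice_index[self.defined]


def slice_li_profile(
    metric_left: np.ndarray,
    metric_right: np.ndarray,
    roi_left: RoiMask,
    roi_right: RoiMask,
) -> SliceLiProfile:
    """Slice-wise LI along z of per-slice ROI means.

    Slices where either side's ROI is empty (or the two means sum to zero)
    are marked undefined and excluded from the profile.
    """
    _check_aligned(metric_left, metric_right, roi_left.mask, roi_right.mask)
    nz = metric_left.shape[2]
    li = np.full(nz, np.nan)
    defined = np.zeros(nz, dtype=bool)
    for z in range(nz):
        lm = roi_left.mask[:, :, z]
        rm = roi_right.mask[:, :, z]
        if not (lm.any() and rm.any()):
            continue
        left_mean = float(metric_left[:, :, z][lm].mean())
        right_mean = float(metric_right[:, :, z][rm].mean())
        if left_mean < 0 or right_mean < 0 or left_mean + right_mean == 0:
            continue
        li[z] = lateralization_index(left_mean, right_mean)
        defined[z] = True
    return SliceLiProfile(slice_index=np.arange(nz), li=li, defined=defined)


def lesion_frequency_map(lesion_masks) -> np.ndarray:
    """Voxel-wise count of subjects with a lesion in each voxel."""
    masks = list(lesion_masks)
    if not masks:
        raise ValidationError("at least one lesion mask required")
    _check_aligned(*masks)
    total = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        arr = np.asarray(m)
        if not np.all(np.isin(arr, [0, 1])):
            raise ValidationError("lesion masks must be binary")
        total += arr.astype(np.int32)
    return total
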