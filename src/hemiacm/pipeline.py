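"""End-to-end orchestration: phantom -> signals -> tracking -> ROI -> stats.

These functions wire the stages together for whole-cohort experiments:
every subject's phantom is forward-simulated, shell-calibrated and
tensor-fitted; hemisphere-restricted tracking produces left and right
anatomical connectivity maps; ROI means and lateralization indices are
collected into a tidy per-subject table ready for the group statistics.

Seeds for every randomized stage are derived deterministically from one
global seed via ``numpy.random.SeedSequence`` spawning, so a single integer
reproduces the full experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dwi import calibrate_shells, extract_peaks, fit_tensor
from .phantom import (
    AcquisitionScheme,
    CohortSpec,
    PhantomBuild,
    PhantomSpec,
    build_phantom,
    cst_probability_map,
    default_phantom_spec,
    default_scheme,
    make_cohort,
    simulate_dwi,
)
from .roi import (
    RoiMask,
    lateralization_index,
    make_cst_mask,
    make_nawm_mask,
    roi_means,
    slice_li_profile,
    split_nawm,
)
from .tracking import AcmMap, TrackingParams, track_and_count

__all__ = [
    "SubjectMaps",
    "CohortResult",
    "derive_seed",
    "subject_maps",
    "run_cohort",
]

DEFAULT_S0 = 1000.0
DEFAULT_NOISE_SD = 20.0  # Rician sigma at SNR 50 relative to s0


def derive_seed(root_seed: int, *path: int) -> int:
    """Deterministic child seed below 2**31 from a root seed and a path."""
    ss = np.random.SeedSequence([int(root_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class SubjectMaps:
    """All per-subject volumes produced by the imaging stages."""

    build: PhantomBuild
    fa: np.ndarray
    md: np.ndarray
    acm_left: AcmMap
    acm_right: AcmMap
    nawm: RoiMask


def subject_maps(
    spec: PhantomSpec,
    scheme: AcquisitionScheme | None = None,
    tracking: TrackingParams | None = None,
    s0: float = DEFAULT_S0,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed: int = 0,
    use_ground_truth_field: bool = True,
) -> SubjectMaps:
    """Run the imaging chain for one subject phantom.

    The tensor fit always runs (it supplies the FA map gating the NAWM
    mask); tracking consumes the phantom's ground-truth multi-peak field by
    default, or the fitted single-peak field when
    ``use_ground_truth_field=False``.
    """
    scheme = scheme or default_scheme()
    tracking = tracking or TrackingParams()
    build = build_phantom(spec)
    dwi = simulate_dwi(
        build.field,
        scheme,
        s0=s0,
        noise_sd=noise_sd,
        rng_seed=derive_seed(rng_seed, 1),
        csf_mask=build.csf_mask,
    )
    calibrated = calibrate_shells(dwi)
    from scipy.ndimage import binary_dilation

    # Fit where FA can matter for masks/tracking: WM plus a 1-voxel margin.
    fit = fit_tensor(calibrated, mask=binary_dilation(build.wm_mask))
    field = build.field if use_ground_truth_field else extract_peaks(fit)
    wm = build.wm_mask if use_ground_truth_field else field.wm_mask
    acm_left = track_and_count(
        field, wm, "left", replace(tracking, rng_seed=derive_seed(rng_seed, 2))
    )
    acm_right = track_and_count(
        field, wm, "right", replace(tracking, rng_seed=derive_seed(rng_seed, 3))
    )
    nawm = make_nawm_mask(build.wm_mask, build.lesion_mask, fit.fa)
    return SubjectMaps(
        build=build,
        fa=fit.fa,
        md=fit.md,
        acm_left=acm_left,
        acm_right=acm_right,
        nawm=nawm,
    )


@dataclass
class CohortResult:
    table: pd.DataFrame
    slice_profiles: np.ndarray  # (n_subjects, n_slices) ACM-LI, NaN undefined
    cst_left: RoiMask
    cst_right: RoiMask
    atlas: np.ndarray
    subjects: list


def run_cohort(
    cohort: CohortSpec,
    phantom: PhantomSpec | None = None,
    tracking: TrackingParams | None = None,
    scheme: AcquisitionScheme | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed: int = 0,
    keep_maps: bool = False,
) -> CohortResult:
    """Simulate and analyze a full cohort.

    Returns a tidy table with one row per subject holding covariates, ROI
    means for ACM/FA/MD in CST-NAWM and non-CST-NAWM per side,
    lateralization indices, lesion volumes, and the whole-brain streamline
    count used as head-size covariate.
    """
    phantom = phantom or default_phantom_spec()
    tracking = tracking or TrackingParams()
    scheme = scheme or default_scheme()
    subjects = make_cohort(cohort, phantom)

    atlas = cst_probability_map(phantom)
    cst_left, cst_right = make_cst_mask(atlas)
    voxel_ml = float(np.prod(phantom.voxel_size)) / 1000.0
    from .phantom import HEMI_CODE, hemisphere_labels

    labels = hemisphere_labels(phantom.grid_shape)
    left_hemi = labels == HEMI_CODE["left"]
    right_hemi = labels == HEMI_CODE["right"]

    rows = []
    profiles = []
    kept = []
    for i, subj in enumerate(subjects):
        maps = subject_maps(
            subj.spec,
            scheme=scheme,
            tracking=tracking,
            noise_sd=noise_sd,
            rng_seed=derive_seed(rng_seed, 10, i),
        )
        rois = split_nawm(maps.nawm, cst_left, cst_right)
        acm = {
            "left": maps.acm_left.counts.astype(float),
            "right": maps.acm_right.counts.astype(float),
        }
        record = subj.record
        row = {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "age": record.age,
            "sex": record.sex,
            "fsmc_motor": record.fsmc_motor,
            "fsmc_cognitive": record.fsmc_cognitive,
            "fsmc_total": record.fsmc_total,
            "bdi": record.bdi,
            "edss": record.edss,
            "crossing_severity_left": subj.crossing_severity[0],
            "crossing_severity_right": subj.crossing_severity[1],
        }

        total_acm = float(acm["left"].sum() + acm["right"].sum())
        row["total_acm"] = total_acm
        record.total_acm = total_acm

        metric_maps = {"acm": acm, "fa": maps.fa, "md": maps.md}
        for metric, vol in metric_maps.items():
            for roi_name, short in (("CST-NAWM", "cst"), ("non-CST-NAWM", "noncst")):
                sides = {}
                for side in ("left", "right"):
                    m = vol[side] if isinstance(vol, dict) else vol
                    sides[side] = roi_means(m, {roi_name: rois[(roi_name, side)]})[roi_name]
                row[f"{metric}_{short}_left"] = sides["left"]
                row[f"{metric}_{short}_right"] = sides["right"]
                row[f"{metric}_{short}_li"] = lateralization_index(
                    sides["left"], sides["right"]
                )

        # Whole-NAWM ACM lateralization (hemisphere means over the full NAWM).
        nawm_left = RoiMask(maps.nawm.mask & left_hemi, "NAWM", "left")
        nawm_right = RoiMask(maps.nawm.mask & right_hemi, "NAWM", "right")
        row["acm_nawm_left"] = float(acm["left"][nawm_left.mask].mean())
        row["acm_nawm_right"] = float(acm["right"][nawm_right.mask].mean())
        row["acm_nawm_li"] = lateralization_index(
            row["acm_nawm_left"], row["acm_nawm_right"]
        )

        vol_left = float(maps.build.lesion_mask[left_hemi].sum()) * voxel_ml
        vol_right = float(maps.build.lesion_mask[right_hemi].sum()) * voxel_ml
        row["lesion_volume_left"] = vol_left
        row["lesion_volume_right"] = vol_right
        record.lesion_volume_left = vol_left
        record.lesion_volume_right = vol_right
        row["lesion_li"] = (
            lateralization_index(vol_left, vol_right)
            if vol_left + vol_right > 0
            else np.nan
        )

        profile = slice_li_profile(
            acm["left"], acm["right"], rois[("CST-NAWM", "left")], rois[("CST-NAWM", "right")]
        )
        profiles.append(profile.li)
        rows.append(row)
        if keep_maps:
            kept.append(maps)

    return CohortResult(
        table=pd.DataFrame(rows),
        slice_profiles=np.asarray(profiles),
        cst_left=cst_left,
        cst_right=cst_right,
        atlas=atlas,
        subjects=kept if keep_maps else subjects,
    )
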