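"""Synthetic two-hemisphere white-matter phantoms.

Builds voxelized fiber-orientation fields containing a vertical
corticospinal-tract-like bundle and an oblique crossing bundle per
hemisphere, focal lesions with configurable severity and lateralization,
a multi-tensor forward model for multi-shell diffusion-weighted signals,
and synthetic cohorts whose groups differ in the lateralization of
crossing-bundle damage.

Conventions
-----------
* The grid is split by a single mid-sagittal voxel plane at x index
  ``grid_shape[0] // 2``.  Voxels with a smaller x index belong to the
  *left* hemisphere, larger to the *right*.  No bundle population is ever
  placed in a midline voxel.
* World coordinates are millimetres; the affine maps voxel indices to
  world coordinates with the grid centred on the origin.
* Each voxel carries up to ``MAX_POPULATIONS`` fiber populations, each a
  unit direction with a non-negative amplitude (the volume fraction of
  that population, reduced by lesion severity).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "BundleSpec",
    "LesionSpec",
    "PhantomSpec",
    "OrientationField",
    "AcquisitionScheme",
    "CohortSpec",
    "CohortSubject",
    "PhantomBuild",
    "grid_affine",
    "hemisphere_labels",
    "default_phantom_spec",
    "build_phantom",
    "cst_probability_map",
    "default_scheme",
    "simulate_dwi",
    "make_cohort",
]

LEFT, RIGHT, MIDLINE = "left", "right", "midline"
HEMI_CODE = {MIDLINE: 0, LEFT: 1, RIGHT: 2}
MAX_POPULATIONS = 3
UNIT_NORM_TOL = 1e-9

# Diffusivities in mm^2/s typical of healthy white matter / free water.
DEFAULT_AXIAL_DIFFUSIVITY = 1.7e-3
DEFAULT_RADIAL_DIFFUSIVITY = 0.3e-3
DEFAULT_BACKGROUND_DIFFUSIVITY = 0.9e-3
CSF_DIFFUSIVITY = 3.0e-3


class ValidationError(ValueError):
    """Raised when a specification violates its invariants."""


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

def grid_affine(grid_shape: Sequence[int], voxel_size: Sequence[float]) -> np.ndarray:
    """Voxel-to-world affine with the grid centred on the world origin."""
    shape = np.asarray(grid_shape, dtype=float)
    vox = np.asarray(voxel_size, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vox)
    affine[:3, 3] = -(shape - 1.0) / 2.0 * vox
    return affine


def hemisphere_labels(grid_shape: Sequence[int]) -> np.ndarray:
    """Label every voxel ``left``/``right``/``midline`` by its x index.

    Exactly one sagittal voxel plane (x == grid_shape[0] // 2) is midline.
    """
    nx = int(grid_shape[0])
    labels = np.zeros(tuple(grid_shape), dtype=np.int8)
    mid = nx // 2
    labels[:mid] = HEMI_CODE[LEFT]
    labels[mid] = HEMI_CODE[MIDLINE]
    labels[mid + 1:] = HEMI_CODE[RIGHT]
    return labels


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(voxels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return np.asarray(voxels, dtype=float) @ affine[:3, :3].T + affine[:3, 3]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BundleSpec:
    """A tubular fiber bundle following a polyline centerline.

    ``volume_fraction`` is the intra-voxel signal fraction this population
    occupies; overlapping bundles may not sum above 1.
    """

    name: str
    hemisphere: str
    centerline: tuple  # ordered world-mm points, shape (K, 3)
    radius: float
    axial_diffusivity: float = DEFAULT_AXIAL_DIFFUSIVITY
    radial_diffusivity: float = DEFAULT_RADIAL_DIFFUSIVITY
    volume_fraction: float = 0.5

    def points(self) -> np.ndarray:
        return np.asarray(self.centerline, dtype=float).reshape(-1, 3)

    def validate(self) -> None:
        if self.hemisphere not in (LEFT, RIGHT):
            raise ValidationError(f"bundle {self.name!r}: hemisphere must be left or right")
        pts = self.points()
        if pts.shape[0] < 2:
            raise ValidationError(f"bundle {self.name!r}: centerline needs >= 2 points")
        if not (self.radius > 0):
            raise ValidationError(f"bundle {self.name!r}: radius must be positive")
        if not (self.axial_diffusivity >= self.radial_diffusivity > 0):
            raise ValidationError(
                f"bundle {self.name!r}: need axial_diffusivity >= radial_diffusivity > 0"
            )
        if not (0 < self.volume_fraction <= 1):
            raise ValidationError(f"bundle {self.name!r}: volume_fraction must be in (0, 1]")


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal lesion.

    ``severity`` is the fraction of local fiber amplitude removed (replaced
    by isotropic compartment).  ``bundle`` restricts the damage to one named
    bundle's population (None damages every population in the voxel).
    ``visible`` distinguishes delineable lesions (entered into the lesion
    mask, hence removed from normal-appearing white matter) from diffuse
    axonal degeneration, which reduces amplitudes without appearing in the
    lesion mask.
    """

    center: tuple
    radius: float
    severity: float
    bundle: str | None = None
    visible: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValidationError("lesion severity must be in [0, 1]")
        if not (self.radius > 0):
            raise ValidationError("lesion radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (40, 40, 40)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    bundles: tuple = ()
    lesions: tuple = ()
    background_isotropic_diffusivity: float = DEFAULT_BACKGROUND_DIFFUSIVITY
    rng_seed: int = 0

    @property
    def midline_index(self) -> int:
        return int(self.grid_shape[0]) // 2

    @property
    def affine(self) -> np.ndarray:
        return grid_affine(self.grid_shape, self.voxel_size)

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValidationError("grid_shape must be three axes, all >= 8 voxels")
        if any(not (v > 0) for v in self.voxel_size):
            raise ValidationError("voxel_size must be positive")
        if not (self.background_isotropic_diffusivity > 0):
            raise ValidationError("background_isotropic_diffusivity must be positive")
        mid = self.midline_index
        affine = self.affine
        for bundle in self.bundles:
            bundle.validate()
            vox_x = world_to_voxel(bundle.points(), affine)[:, 0]
            if bundle.hemisphere == LEFT and not np.all(vox_x < mid - 0.5):
                raise ValidationError(
                    f"bundle {bundle.name!r}: centerline not strictly in the left hemisphere"
                )
            if bundle.hemisphere == RIGHT and not np.all(vox_x > mid + 0.5):
                raise ValidationError(
                    f"bundle {bundle.name!r}: centerline not strictly in the right hemisphere"
                )
        for lesion in self.lesions:
            lesion.validate()


# ---------------------------------------------------------------------------
# Orientation field
# ---------------------------------------------------------------------------

@dataclass
class OrientationField:
    """Per-voxel fiber populations on a labeled two-hemisphere grid.

    ``directions``/``amplitudes`` have shape ``grid_shape + (MAX_POPULATIONS,
    3)`` and ``grid_shape + (MAX_POPULATIONS,)``; unused slots have zero
    amplitude.  ``axial_diffusivity``/``radial_diffusivity`` (same shape as
    amplitudes) are carried for the forward signal model and may be absent
    on fields derived from fitted data.
    """

    directions: np.ndarray
    amplitudes: np.ndarray
    wm_mask: np.ndarray
    hemisphere_labels: np.ndarray
    voxel_size: np.ndarray
    affine: np.ndarray
    axial_diffusivity: np.ndarray | None = None
    radial_diffusivity: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple:
        return tuple(self.amplitudes.shape[:3])

    def validate(self) -> None:
        if self.amplitudes.shape != self.grid_shape + (MAX_POPULATIONS,):
            raise ValidationError("amplitudes must have one slot per population")
        if self.directions.shape != self.amplitudes.shape + (3,):
            raise ValidationError("directions shape inconsistent with amplitudes")
        if np.any(self.amplitudes < 0):
            raise ValidationError("amplitudes must be non-negative")
        active = self.amplitudes > 0
        norms = np.linalg.norm(self.directions[active], axis=-1)
        if norms.size and np.max(np.abs(norms - 1.0)) >= UNIT_NORM_TOL:
            raise ValidationError("active population directions must be unit vectors")
        labels = np.unique(self.hemisphere_labels)
        if not np.all(np.isin(labels, list(HEMI_CODE.values()))):
            raise ValidationError("hemisphere labels must partition the grid")

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemisphere_labels == HEMI_CODE[hemisphere]


@dataclass
class PhantomBuild:
    """Output of :func:`build_phantom`."""

    field: OrientationField
    wm_mask: np.ndarray
    gm_mask: np.ndarray
    csf_mask: np.ndarray
    lesion_mask: np.ndarray
    bundle_masks: Mapping[str, np.ndarray]
    spec: PhantomSpec


def _polyline_distance(points: np.ndarray, line: np.ndarray):
    """Distance of each point to a polyline and the local tangent there."""
    seg_start = line[:-1]
    seg_vec = line[1:] - seg_start
    seg_len2 = np.einsum("kj,kj->k", seg_vec, seg_vec)
    # (n_points, n_segments) projections, clipped to the segment.
    diff = points[:, None, :] - seg_start[None, :, :]
    t = np.einsum("nkj,kj->nk", diff, seg_vec) / np.maximum(seg_len2, 1e-30)
    t = np.clip(t, 0.0, 1.0)
    closest = seg_start[None, :, :] + t[..., None] * seg_vec[None, :, :]
    d2 = np.einsum("nkj->nk", (points[:, None, :] - closest) ** 2)
    k = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(points)), k])
    tangents = seg_vec[k]
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    return dist, tangents


def build_phantom(spec: PhantomSpec) -> PhantomBuild:
    """Voxelize bundles, apply lesions, and label tissue compartments.

    Voxels within a bundle's radius of its centerline carry that bundle's
    direction population; overlapping bundles stack populations whose
    summed volume fractions may not exceed 1.  Populations are restricted
    to the bundle's own hemisphere so no population ever crosses the
    mid-sagittal plane.
    """
    spec.validate()
    shape = tuple(int(n) for n in spec.grid_shape)
    affine = spec.affine
    labels = hemisphere_labels(shape)

    idx = np.indices(shape).reshape(3, -1).T
    centers = voxel_to_world(idx, affine)

    n_vox = centers.shape[0]
    directions = np.zeros(shape + (MAX_POPULATIONS, 3))
    amplitudes = np.zeros(shape + (MAX_POPULATIONS,))
    axial = np.zeros_like(amplitudes)
    radial = np.zeros_like(amplitudes)
    n_pops = np.zeros(n_vox, dtype=np.int64)
    vf_sum = np.zeros(n_vox)

    flat_dirs = directions.reshape(n_vox, MAX_POPULATIONS, 3)
    flat_amps = amplitudes.reshape(n_vox, MAX_POPULATIONS)
    flat_ax = axial.reshape(n_vox, MAX_POPULATIONS)
    flat_rad = radial.reshape(n_vox, MAX_POPULATIONS)
    flat_labels = labels.reshape(-1)

    bundle_masks: dict[str, np.ndarray] = {}
    for bundle in spec.bundles:
        dist, tangents = _polyline_distance(centers, bundle.points())
        inside = (dist <= bundle.radius) & (flat_labels == HEMI_CODE[bundle.hemisphere])
        if np.any(n_pops[inside] >= MAX_POPULATIONS):
            raise ValidationError(
                f"bundle {bundle.name!r}: more than {MAX_POPULATIONS} populations in a voxel"
            )
        vf_sum[inside] += bundle.volume_fraction
        if np.any(vf_sum > 1.0 + 1e-12):
            raise ValidationError(
                f"bundle {bundle.name!r}: summed volume fractions exceed 1 in overlap"
            )
        where = np.flatnonzero(inside)
        slot = n_pops[where]
        flat_dirs[where, slot] = tangents[where]
        flat_amps[where, slot] = bundle.volume_fraction
        flat_ax[where, slot] = bundle.axial_diffusivity
        flat_rad[where, slot] = bundle.radial_diffusivity
        n_pops[where] += 1
        bundle_masks[bundle.name] = inside.reshape(shape)

    wm_mask = (n_pops > 0).reshape(shape)

    lesion_mask = np.zeros(shape, dtype=bool)
    slot_of = _bundle_slots(spec, bundle_masks, shape) if spec.lesions else {}
    for lesion in spec.lesions:
        center = np.asarray(lesion.center, dtype=float)
        inside = np.linalg.norm(centers - center, axis=1) <= lesion.radius
        inside &= wm_mask.reshape(-1)  # lesion voxels are a subset of WM
        if lesion.bundle is None:
            flat_amps[inside] *= 1.0 - lesion.severity
        else:
            if lesion.bundle not in bundle_masks:
                raise ValidationError(f"lesion targets unknown bundle {lesion.bundle!r}")
            # Damage only the population slot that belongs to the targeted bundle.
            sel = np.flatnonzero(inside & bundle_masks[lesion.bundle].reshape(-1))
            flat_amps[sel, slot_of[lesion.bundle].reshape(-1)[sel]] *= 1.0 - lesion.severity
        if lesion.visible:
            lesion_mask |= inside.reshape(shape)

    field_obj = OrientationField(
        directions=directions,
        amplitudes=amplitudes,
        wm_mask=wm_mask,
        hemisphere_labels=labels,
        voxel_size=np.asarray(spec.voxel_size, dtype=float),
        affine=affine,
        axial_diffusivity=axial,
        radial_diffusivity=radial,
    )
    field_obj.validate()

    from scipy.ndimage import binary_dilation

    gm_mask = binary_dilation(wm_mask) & ~wm_mask
    csf_mask = ~(wm_mask | gm_mask)
    return PhantomBuild(
        field=field_obj,
        wm_mask=wm_mask,
        gm_mask=gm_mask,
        csf_mask=csf_mask,
        lesion_mask=lesion_mask,
        bundle_masks=bundle_masks,
        spec=spec,
    )


def _bundle_slots(spec: PhantomSpec, bundle_masks, shape) -> dict[str, np.ndarray]:
    """Population slot index of each bundle in every voxel it occupies."""
    counts = np.zeros(shape, dtype=np.int64)
    slots: dict[str, np.ndarray] = {}
    for bundle in spec.bundles:
        mask = bundle_masks[bundle.name]
        slot = np.where(mask, counts, 0)
        slots[bundle.name] = slot
        counts = counts + mask.astype(np.int64)
    return slots


# ---------------------------------------------------------------------------
# Default two-hemisphere geometry
# ---------------------------------------------------------------------------

def default_phantom_spec(
    grid_shape: Sequence[int] = (40, 40, 40),
    voxel_size: float = 2.0,
    crossing_angle_deg: float = 40.0,
    vertical_radius: float = 5.0,
    crossing_radius: float = 4.0,
    volume_fraction: float = 0.5,
    lesions: Sequence[LesionSpec] = (),
    rng_seed: int = 0,
) -> PhantomSpec:
    """Two bundles per hemisphere: a vertical CST-like tract and an oblique
    crossing tract intersecting it at ``crossing_angle_deg`` from vertical.

    The crossing angle is kept below typical tracker curvature limits so
    that streamlines can trade bundles at the intersection; a strictly
    perpendicular crossing cannot exchange streamlines under a sub-90-degree
    per-step turn limit.
    """
    shape = tuple(int(n) for n in grid_shape)
    vox = (float(voxel_size),) * 3
    affine = grid_affine(shape, vox)
    half_extent = (np.asarray(shape) - 1) / 2.0 * voxel_size

    theta = math.radians(crossing_angle_deg)
    bundles = []
    for hemi, sign in ((LEFT, -1.0), (RIGHT, 1.0)):
        # Hemisphere centre in x, clear of the midline plane.
        x0 = sign * half_extent[0] / 2.0
        z_top = half_extent[2]
        vertical = BundleSpec(
            name=f"cst_{hemi}",
            hemisphere=hemi,
            centerline=((x0, 0.0, -z_top), (x0, 0.0, z_top)),
            radius=vertical_radius,
            volume_fraction=volume_fraction,
        )
        # Oblique bundle in the y-z plane through the vertical bundle centre.
        direction = np.array([0.0, math.sin(theta), math.cos(theta)])
        t_max = min(half_extent[1] / direction[1], half_extent[2] / direction[2])
        p0 = np.array([x0, 0.0, 0.0]) - t_max * direction
        p1 = np.array([x0, 0.0, 0.0]) + t_max * direction
        crossing = BundleSpec(
            name=f"crossing_{hemi}",
            hemisphere=hemi,
            centerline=(tuple(p0), tuple(p1)),
            radius=crossing_radius,
            volume_fraction=volume_fraction,
        )
        bundles += [vertical, crossing]
    return PhantomSpec(
        grid_shape=shape,
        voxel_size=vox,
        bundles=tuple(bundles),
        lesions=tuple(lesions),
        rng_seed=rng_seed,
    )


def crossing_center(spec: PhantomSpec, hemisphere: str) -> np.ndarray:
    """World-mm centre of the bundle intersection in one hemisphere."""
    vertical = next(b for b in spec.bundles if b.name == f"cst_{hemisphere}")
    pts = vertical.points()
    return pts.mean(axis=0)


def cst_probability_map(spec: PhantomSpec, fwhm_mm: float = 6.0) -> np.ndarray:
    """Synthetic tract-probability atlas for the CST-like bundles.

    Gaussian-blurred indicator of the (lesion-free) vertical bundles,
    normalized to peak probability 1; a stand-in for a population atlas.
    """
    clean = replace(spec, lesions=())
    build = build_phantom(clean)
    indicator = np.zeros(clean.grid_shape)
    for name, mask in build.bundle_masks.items():
        if name.startswith("cst_"):
            indicator[mask] = 1.0
    from scipy.ndimage import gaussian_filter

    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / np.asarray(spec.voxel_size)
    blurred = gaussian_filter(indicator, sigma=sigma_vox)
    peak = blurred.max()
    return blurred / peak if peak > 0 else blurred


# ---------------------------------------------------------------------------
# Acquisition scheme and forward signal model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionScheme:
    """Gradient table with shell bookkeeping.

    ``shell_scales`` emulate TE/TR-driven intensity offsets between shells
    (one multiplicative factor per shell, applied to every volume of the
    shell including its b0).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray
    shell_scales: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bvals", np.asarray(self.bvals, dtype=float))
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, dtype=float))
        object.__setattr__(self, "shell_ids", np.asarray(self.shell_ids, dtype=int))
        object.__setattr__(self, "shell_scales", np.asarray(self.shell_scales, dtype=float))

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.shell_ids)

    def shell_bvalue(self, shell_id: int) -> float:
        vals = self.bvals[(self.shell_ids == shell_id) & (self.bvals > 0)]
        return float(vals[0]) if vals.size else 0.0

    def validate(self) -> None:
        if self.bvecs.shape != (self.n_volumes, 3):
            raise ValidationError("bvecs must be (n_volumes, 3)")
        if self.shell_ids.shape != (self.n_volumes,):
            raise ValidationError("one shell id per volume required")
        if np.any(self.shell_scales <= 0):
            raise ValidationError("shell scale factors must be positive")
        if self.shell_scales.shape != (len(self.shells),):
            raise ValidationError("one scale factor per shell required")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.max(np.abs(norms - 1.0)) > 1e-8:
            raise ValidationError("diffusion-weighted bvecs must be unit vectors")
        for shell in self.shells:
            sel = self.shell_ids == shell
            if not np.any(self.bvals[sel] == 0):
                raise ValidationError(f"shell {shell} has no b0 volume")


def fibonacci_hemisphere(n: int, seed_rotation: float = 0.0) -> np.ndarray:
    """n roughly uniform unit directions on the upper hemisphere."""
    i = np.arange(n) + 0.5
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = i / n  # in (0, 1): strictly upper hemisphere, non-collinear
    phi = golden * i + seed_rotation
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_scheme(
    b_values: Sequence[float] = (300.0, 1000.0, 2000.0),
    n_directions: Sequence[int] = (6, 62, 62),
    shell_scales: Sequence[float] = (1.0, 1.0, 1.0),
) -> AcquisitionScheme:
    """Multi-shell scheme: one b0 per shell plus the shell's directions."""
    bvals, bvecs, ids = [], [], []
    for shell, (b, n) in enumerate(zip(b_values, n_directions)):
        bvals.append(0.0)
        bvecs.append((0.0, 0.0, 0.0))
        ids.append(shell)
        for d in fibonacci_hemisphere(int(n), seed_rotation=0.37 * shell):
            bvals.append(float(b))
            bvecs.append(tuple(d))
            ids.append(shell)
    scheme = AcquisitionScheme(
        bvals=np.array(bvals),
        bvecs=np.array(bvecs),
        shell_ids=np.array(ids),
        shell_scales=np.asarray(shell_scales, dtype=float),
    )
    scheme.validate()
    return scheme


def simulate_dwi(
    field: OrientationField,
    scheme: AcquisitionScheme,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    csf_mask: np.ndarray | None = None,
    background_diffusivity: float = DEFAULT_BACKGROUND_DIFFUSIVITY,
):
    """Forward-simulate multi-shell signals with a multi-tensor mixture.

    Per voxel ``S = scale_shell * s0 * (sum_k f_k exp(-b g'D_k g) + f_iso
    exp(-b d_iso))`` where ``D_k`` is an axially symmetric tensor along the
    population direction and ``f_iso = 1 - sum_k f_k``.  Optional Rician
    noise is the magnitude of the complex Gaussian-corrupted signal, so
    ``noise_sd = 0`` yields the exact closed form.
    """
    scheme.validate()
    if not (s0 > 0):
        raise ValidationError("s0 must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if field.axial_diffusivity is None or field.radial_diffusivity is None:
        raise ValidationError("field lacks per-population diffusivities")

    shape = field.grid_shape
    amps = field.amplitudes  # (X,Y,Z,P)
    dirs = field.directions  # (X,Y,Z,P,3)
    ad = field.axial_diffusivity
    rd = field.radial_diffusivity
    iso_frac = np.clip(1.0 - amps.sum(axis=-1), 0.0, 1.0)
    iso_diff = np.full(shape, float(background_diffusivity))
    if csf_mask is not None:
        iso_diff[csf_mask] = CSF_DIFFUSIVITY

    data = np.empty(shape + (scheme.n_volumes,))
    active = amps > 0
    for j in range(scheme.n_volumes):
        b = scheme.bvals[j]
        scale = scheme.shell_scales[list(scheme.shells).index(scheme.shell_ids[j])]
        if b == 0:
            signal = np.ones(shape)
        else:
            g = scheme.bvecs[j]
            cos2 = np.einsum("...pj,j->...p", dirs, g) ** 2
            adc = rd + (ad - rd) * cos2
            per_pop = np.where(active, amps * np.exp(-b * adc), 0.0)
            signal = per_pop.sum(axis=-1) + iso_frac * np.exp(-b * iso_diff)
        data[..., j] = scale * s0 * signal

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        re = data + rng.normal(0.0, noise_sd, size=data.shape)
        im = rng.normal(0.0, noise_sd, size=data.shape)
        data = np.sqrt(re**2 + im**2)

    from .dwi import DwiVolumeSet

    return DwiVolumeSet(data=data, scheme=scheme, affine=field.affine.copy())


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

GROUPS = ("HC", "FMS", "NFMS")
FSMC_MOTOR_MIN, FSMC_MOTOR_MAX = 10, 50
FSMC_CUTOFF = 27


@dataclass(frozen=True)
class CohortSpec:
    """Group structure of a synthetic cohort.

    ``crossing_damage_mean`` gives per-group mean severity of diffuse
    crossing-bundle degeneration as ``(left, right)``; between-subject
    spread is ``crossing_damage_sd`` (draws clipped to [0, 1]).  Patients
    additionally receive ``Poisson(lesion_rate)`` visible focal lesions
    with per-subject random lateralization.
    """

    n_per_group: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"HC": 10, "FMS": 10, "NFMS": 10}
    )
    crossing_damage_mean: Mapping[str, tuple] = dataclasses.field(
        default_factory=lambda: {"HC": (0.0, 0.0), "FMS": (0.75, 0.1), "NFMS": (0.1, 0.75)}
    )
    crossing_damage_sd: float = 0.1
    lesion_rate: float = 5.0
    lesion_radius_range: tuple = (2.0, 4.0)
    lesion_severity_range: tuple = (0.6, 0.9)
    rng_seed: int = 0

    def validate(self) -> None:
        for group, n in self.n_per_group.items():
            if group not in GROUPS:
                raise ValidationError(f"unknown group {group!r}")
            if int(n) < 2:
                raise ValidationError("each group needs n >= 2")
        for group, (lo, hi) in self.crossing_damage_mean.items():
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise ValidationError("crossing damage severities must be in [0, 1]")
        if self.crossing_damage_sd < 0:
            raise ValidationError("crossing_damage_sd must be non-negative")


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    spec: PhantomSpec
    record: "object"  # stats.SubjectRecord
    crossing_severity: tuple = (0.0, 0.0)


def _subject_lesions(
    rng: np.random.Generator,
    cspec: CohortSpec,
    pspec: PhantomSpec,
    severities: tuple,
) -> list[LesionSpec]:
    lesions: list[LesionSpec] = []
    for hemi, severity in zip((LEFT, RIGHT), severities):
        if severity > 1e-3:
            lesions.append(
                LesionSpec(
                    center=tuple(crossing_center(pspec, hemi)),
                    radius=2.0 * max(pspec.voxel_size) + 4.0,
                    severity=float(severity),
                    bundle=f"crossing_{hemi}",
                    visible=False,  # diffuse degeneration, not a delineable lesion
                )
            )
    n_focal = int(rng.poisson(cspec.lesion_rate))
    left_share = float(rng.beta(2.0, 2.0))
    bundles_by_hemi = {
        LEFT: [b for b in pspec.bundles if b.hemisphere == LEFT],
        RIGHT: [b for b in pspec.bundles if b.hemisphere == RIGHT],
    }
    for _ in range(n_focal):
        hemi = LEFT if rng.random() < left_share else RIGHT
        bundle = bundles_by_hemi[hemi][int(rng.integers(len(bundles_by_hemi[hemi])))]
        pts = bundle.points()
        t = float(rng.uniform(0.15, 0.85))
        center = pts[0] + t * (pts[-1] - pts[0])
        jitter = rng.normal(0.0, bundle.radius / 3.0, size=3)
        lesions.append(
            LesionSpec(
                center=tuple(center + jitter),
                radius=float(rng.uniform(*cspec.lesion_radius_range)),
                severity=float(rng.uniform(*cspec.lesion_severity_range)),
                bundle=None,
                visible=True,
            )
        )
    return lesions


def _fsmc_motor(rng: np.random.Generator, group: str, left_severity: float) -> int:
    """Motor-fatigue score increasing with left crossing-bundle damage.

    FMS subjects score at or above the clinical cutoff (27), NFMS and HC
    below it, mirroring the grouping rule the score is classified by.
    """
    base = 12.0 + 35.0 * left_severity + rng.normal(0.0, 3.0)
    score = int(round(base))
    if group == "FMS":
        score = max(FSMC_CUTOFF, score)
    else:
        score = min(FSMC_CUTOFF - 1, score)
    return int(np.clip(score, FSMC_MOTOR_MIN, FSMC_MOTOR_MAX))


def make_cohort(cspec: CohortSpec, pspec: PhantomSpec | None = None) -> list[CohortSubject]:
    """Per-subject phantom specs and covariate skeletons.

    Deterministic given ``cspec.rng_seed``; crossing-bundle severities are
    drawn from the group's distribution and clipped to [0, 1].
    """
    from .stats import SubjectRecord

    cspec.validate()
    if pspec is None:
        pspec = default_phantom_spec()
    pspec.validate()

    rng = np.random.default_rng(cspec.rng_seed)
    subjects: list[CohortSubject] = []
    counter = 0
    for group in GROUPS:
        n = int(cspec.n_per_group.get(group, 0))
        mean_l, mean_r = cspec.crossing_damage_mean.get(group, (0.0, 0.0))
        for _ in range(n):
            counter += 1
            sid = f"sub-{counter:03d}"
            sev_l = float(np.clip(rng.normal(mean_l, cspec.crossing_damage_sd), 0.0, 1.0))
            sev_r = float(np.clip(rng.normal(mean_r, cspec.crossing_damage_sd), 0.0, 1.0))
            if group == "HC":
                lesions: list[LesionSpec] = []
                if max(sev_l, sev_r) > 1e-3:
                    lesions = _subject_lesions(rng, replace(cspec, lesion_rate=0.0), pspec, (sev_l, sev_r))
            else:
                lesions = _subject_lesions(rng, cspec, pspec, (sev_l, sev_r))
            subject_spec = replace(
                pspec,
                lesions=tuple(lesions),
                rng_seed=int(rng.integers(2**31 - 1)),
            )
            fsmc_motor = _fsmc_motor(rng, group, sev_l)
            fsmc_cog = int(np.clip(round(12 + 20 * max(sev_l, sev_r) + rng.normal(0, 4)), 10, 50))
            record = SubjectRecord(
                subject_id=sid,
                group=group,
                fsmc_motor=fsmc_motor,
                fsmc_cognitive=fsmc_cog,
                fsmc_total=fsmc_motor + fsmc_cog,
                bdi=float(np.clip(rng.normal(5 + 8 * sev_l, 3), 0, 28)),
                edss=float(np.clip(round(rng.normal(1.5, 1.0) * 2) / 2, 0, 3.5)) if group != "HC" else 0.0,
                age=float(np.clip(round(rng.normal(36.0, 9.0)), 18, 60)),
                sex="F" if rng.random() < 0.7 else "M",
            )
            subjects.append(
                CohortSubject(
                    subject_id=sid,
                    group=group,
                    spec=subject_spec,
                    record=record,
                    crossing_severity=(sev_l, sev_r),
                )
            )
    return subjects
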