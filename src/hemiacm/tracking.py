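"""Probabilistic streamline tractography and anatomical connectivity maps.

Anatomical connectivity mapping (ACM) seeds a fixed number of streamlines
in every white-matter voxel of one hemisphere, propagates them through the
per-voxel fiber-orientation field, discards any streamline that touches
the mid-sagittal plane or the contralateral hemisphere, and counts how
many retained streamlines pass through each voxel.

Propagation is bidirectional from the seed.  At every step the candidate
fiber populations of the current voxel are restricted to those within the
curvature cone of the incoming direction; one population is drawn with
probability proportional to ``amplitude * |cos(angle to incoming)|`` and
the step direction is sampled from a von Mises-Fisher distribution around
that population's (sign-aligned) peak.  With ``deterministic=True`` the
highest-weight population is followed exactly (ties broken by lowest
population index), which gives a reproducible limit used by enumeration
oracles.  A streamline ends on low amplitude, excessive turning, leaving
the tracking mask, or exceeding the maximum length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import HEMI_CODE, OrientationField, ValidationError, world_to_voxel

__all__ = [
    "TrackingParams",
    "Streamline",
    "TrackingResult",
    "AcmMap",
    "track_unilateral",
    "compute_acm",
    "track_and_count",
    "smooth_map",
    "sample_von_mises_fisher",
]

TERM_AMPLITUDE = "amplitude"
TERM_CURVATURE = "curvature"
TERM_MASK_EXIT = "mask_exit"
TERM_MAX_LENGTH = "max_length"
TERM_MIDLINE = "midline_excluded"

_CHUNK_SEEDS = 8192


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters.

    ``step_size=None`` resolves to half the smallest voxel size.  With
    ``deterministic=True`` (or ``dispersion_kappa=inf``) direction sampling
    collapses to the population peak.
    """

    seeds_per_voxel: int = 300
    step_size: float | None = None
    max_turn_angle: float = 45.0
    amplitude_threshold: float = 0.1
    dispersion_kappa: float = 30.0
    max_length: float = 250.0
    min_length: float = 4.0
    rng_seed: int = 0
    deterministic: bool = False

    def resolve_step(self, voxel_size: np.ndarray) -> float:
        step = self.step_size if self.step_size is not None else 0.5 * float(np.min(voxel_size))
        if not (0 < step <= float(np.min(voxel_size))):
            raise ValidationError("step_size must be in (0, min(voxel_size)]")
        return step

    def validate(self) -> None:
        if self.seeds_per_voxel < 1:
            raise ValidationError("seeds_per_voxel must be >= 1")
        if not (0 < self.max_turn_angle < 90):
            raise ValidationError("max_turn_angle must be in (0, 90) degrees")
        if self.amplitude_threshold < 0:
            raise ValidationError("amplitude_threshold must be non-negative")
        if not self.deterministic and not (self.dispersion_kappa > 0):
            raise ValidationError("dispersion_kappa must be positive")
        if not (self.max_length > 0 and self.min_length >= 0):
            raise ValidationError("lengths must be positive (min_length may be 0)")


@dataclass
class Streamline:
    """An ordered polyline in world mm with per-end termination reasons."""

    points: np.ndarray  # (n_points, 3)
    seed_voxel: tuple
    termination: tuple  # (backward end, forward end)
    excluded: bool = False

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TrackingResult:
    streamlines: list  # retained streamlines only
    n_launched: int
    n_retained: int
    n_discarded: dict
    hemisphere: str
    params: TrackingParams
    grid_shape: tuple
    affine: np.ndarray
    step_size: float


@dataclass
class AcmMap:
    """Voxel-wise count of distinct retained streamlines per voxel."""

    counts: np.ndarray
    hemisphere: str
    n_launched: int
    n_retained: int
    params: TrackingParams | None
    affine: np.ndarray


def sample_von_mises_fisher(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Draw one unit vector per row of ``mu`` from vMF(mu, kappa)."""
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(kappa):
        return mu.copy()
    n = mu.shape[0]
    u = rng.random(n)
    # Inverse-CDF sampling of the cosine w relative to mu.
    w = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.random(n) * 2.0 * math.pi

    # Orthonormal basis perpendicular to mu.
    helper = np.zeros_like(mu)
    helper[np.arange(n), np.argmin(np.abs(mu), axis=1)] = 1.0
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(mu, e1)

    sin_theta = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    out = (
        sin_theta[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        + w[:, None] * mu
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _categorical(rng: np.random.Generator, weights: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw proportional to non-negative weights."""
    cum = np.cumsum(weights, axis=1)
    total = cum[:, -1]
    r = rng.random(weights.shape[0]) * total
    return np.minimum((r[:, None] > cum).sum(axis=1), weights.shape[1] - 1)


class _HalfTracker:
    """Vectorized propagation of one batch of streamline halves."""

    def __init__(self, field: OrientationField, wm_mask, hemi_code, params, step, rng):
        self.field = field
        self.wm = wm_mask
        self.hemi_code = hemi_code
        self.params = params
        self.step = step
        self.rng = rng
        self.inv = np.linalg.inv(field.affine)
        self.shape = np.asarray(field.grid_shape)
        self.cos_turn = math.cos(math.radians(params.max_turn_angle))
        self.max_steps = int(math.floor(params.max_length / step + 1e-9))

    def voxels_of(self, pts: np.ndarray) -> np.ndarray:
        return np.rint(pts @ self.inv[:3, :3].T + self.inv[:3, 3]).astype(np.int64)

    def run(self, seeds: np.ndarray, init_dirs: np.ndarray, dead: np.ndarray,
            budget: np.ndarray | None = None):
        """Propagate halves; returns (points buffer, n points, termination, excluded).

        ``budget`` caps the number of steps per row so the length limit
        applies to the full bidirectional streamline, not per half.
        """
        n = seeds.shape[0]
        if budget is None:
            budget = np.full(n, self.max_steps, dtype=np.int64)
        buf = np.zeros((n, self.max_steps, 3))
        npts = np.zeros(n, dtype=np.int64)
        term = np.array([""] * n, dtype=object)
        excluded = np.zeros(n, dtype=bool)

        pos = seeds.copy()
        dirn = init_dirs.copy()
        active = ~dead
        term[dead] = TERM_AMPLITUDE
        steps_taken = np.zeros(n, dtype=np.int64)
        deterministic = self.params.deterministic or not np.isfinite(self.params.dispersion_kappa)

        amps_grid = self.field.amplitudes
        dirs_grid = self.field.directions
        labels = self.field.hemisphere_labels

        while np.any(active):
            rows = np.flatnonzero(active)
            vox = self.voxels_of(pos[rows])
            vx, vy, vz = vox[:, 0], vox[:, 1], vox[:, 2]
            amps = amps_grid[vx, vy, vz]  # (m, P)
            dirs = dirs_grid[vx, vy, vz]  # (m, P, 3)

            stop_amp = amps.max(axis=1) < self.params.amplitude_threshold
            cosines = np.abs(np.einsum("mpj,mj->mp", dirs, dirn[rows]))
            feasible = (amps > 0) & (cosines >= self.cos_turn)
            weights = np.where(feasible, amps * cosines, 0.0)
            stop_curv = ~stop_amp & (weights.sum(axis=1) <= 0)

            alive = ~(stop_amp | stop_curv)
            term[rows[stop_amp]] = TERM_AMPLITUDE
            term[rows[stop_curv]] = TERM_CURVATURE

            sub = np.flatnonzero(alive)
            if sub.size:
                w = weights[sub]
                if deterministic:
                    k = np.argmax(w, axis=1)
                else:
                    k = _categorical(self.rng, w)
                mu = dirs[sub, k]
                align = np.einsum("mj,mj->m", mu, dirn[rows[sub]])
                mu = mu * np.where(align >= 0, 1.0, -1.0)[:, None]
                if deterministic:
                    new_dir = mu
                else:
                    new_dir = sample_von_mises_fisher(self.rng, mu, self.params.dispersion_kappa)
                turn_ok = np.einsum("mj,mj->m", new_dir, dirn[rows[sub]]) >= self.cos_turn
                len_ok = steps_taken[rows[sub]] < budget[rows[sub]]
                term[rows[sub[~turn_ok]]] = TERM_CURVATURE
                term[rows[sub[turn_ok & ~len_ok]]] = TERM_MAX_LENGTH

                go = turn_ok & len_ok
                gidx = sub[go]
                cand = pos[rows[gidx]] + self.step * new_dir[go]
                cvox = self.voxels_of(cand)
                inside = np.all((cvox >= 0) & (cvox < self.shape), axis=1)
                in_wm = np.zeros(gidx.shape[0], dtype=bool)
                in_wm[inside] = self.wm[
                    cvox[inside, 0], cvox[inside, 1], cvox[inside, 2]
                ]
                term[rows[gidx[~in_wm]]] = TERM_MASK_EXIT

                ok = gidx[in_wm]
                if ok.size:
                    r_ok = rows[ok]
                    buf[r_ok, steps_taken[r_ok]] = cand[in_wm]
                    npts[r_ok] += 1
                    steps_taken[r_ok] += 1
                    pos[r_ok] = cand[in_wm]
                    dirn[r_ok] = new_dir[go][in_wm]
                    # Exclusion: a point on the midline plane or in the
                    # contralateral hemisphere discards the whole streamline.
                    lab = labels[
                        cvox[in_wm, 0], cvox[in_wm, 1], cvox[in_wm, 2]
                    ]
                    out_hemi = lab != self.hemi_code
                    bad = r_ok[out_hemi]
                    term[bad] = TERM_MIDLINE
                    excluded[bad] = True
                    survivors = np.zeros(n, dtype=bool)
                    survivors[r_ok[~out_hemi]] = True
                    active = survivors
                else:
                    active = np.zeros(n, dtype=bool)
            else:
                active = np.zeros(n, dtype=bool)
        return buf, npts, term, excluded


def track_unilateral(
    field: OrientationField,
    wm_mask: np.ndarray,
    hemisphere: str,
    params: TrackingParams | None = None,
) -> TrackingResult:
    """Seed ``seeds_per_voxel`` streamlines in every WM voxel of one
    hemisphere and propagate them bidirectionally.

    Streamlines containing any point on the mid-sagittal plane or in the
    contralateral hemisphere are discarded in full (``midline_excluded``),
    as are streamlines shorter than ``min_length``.
    """
    params = params or TrackingParams()
    params.validate()
    if hemisphere not in ("left", "right"):
        raise ValidationError("hemisphere must be 'left' or 'right'")
    field.validate()
    step = params.resolve_step(field.voxel_size)
    hemi_code = HEMI_CODE[hemisphere]

    seed_mask = wm_mask & (field.hemisphere_labels == hemi_code)
    seed_voxels = np.argwhere(seed_mask)
    if seed_voxels.shape[0] == 0:
        raise ValidationError(f"no white-matter voxels in the {hemisphere} hemisphere mask")

    rng = np.random.default_rng(params.rng_seed)
    deterministic = params.deterministic or not np.isfinite(params.dispersion_kappa)
    n_launched = seed_voxels.shape[0] * params.seeds_per_voxel

    streamlines: list[Streamline] = []
    n_excluded = 0
    n_short = 0

    amps_grid = field.amplitudes
    dirs_grid = field.directions

    for start in range(0, seed_voxels.shape[0], _CHUNK_SEEDS // max(1, params.seeds_per_voxel) + 1):
        chunk_vox = seed_voxels[start : start + _CHUNK_SEEDS // max(1, params.seeds_per_voxel) + 1]
        reps = np.repeat(chunk_vox, params.seeds_per_voxel, axis=0)
        n = reps.shape[0]
        jitter = rng.random((n, 3)) - 0.5  # uniform within the voxel
        seeds = (reps + jitter) @ field.affine[:3, :3].T + field.affine[:3, 3]

        amps = amps_grid[reps[:, 0], reps[:, 1], reps[:, 2]]
        dirs = dirs_grid[reps[:, 0], reps[:, 1], reps[:, 2]]
        dead = amps.max(axis=1) < params.amplitude_threshold
        if deterministic:
            k = np.argmax(amps, axis=1)
        else:
            safe = np.where(dead[:, None], np.ones_like(amps), amps)
            k = _categorical(rng, np.where(safe.sum(axis=1)[:, None] > 0, safe, 1.0))
        peak = dirs[np.arange(n), k]
        peak[dead] = np.array([0.0, 0.0, 1.0])  # placeholder, never used
        if deterministic:
            init = peak
        else:
            init = sample_von_mises_fisher(rng, peak, params.dispersion_kappa)

        tracker = _HalfTracker(field, wm_mask, hemi_code, params, step, rng)
        buf_f, np_f, term_f, exc_f = tracker.run(seeds, init, dead)
        # The backward half gets whatever step budget the forward half left.
        buf_b, np_b, term_b, exc_b = tracker.run(
            seeds, -init, dead, budget=tracker.max_steps - np_f
        )

        for i in range(n):
            backward = buf_b[i, : np_b[i]][::-1]
            forward = buf_f[i, : np_f[i]]
            points = np.vstack([backward, seeds[i][None, :], forward])
            excluded = bool(exc_f[i] or exc_b[i])
            length = (np_f[i] + np_b[i]) * step
            sl = Streamline(
                points=points,
                seed_voxel=tuple(int(v) for v in reps[i]),
                termination=(str(term_b[i]), str(term_f[i])),
                excluded=excluded,
            )
            if excluded:
                n_excluded += 1
            elif length < params.min_length:
                n_short += 1
            else:
                streamlines.append(sl)

    return TrackingResult(
        streamlines=streamlines,
        n_launched=int(n_launched),
        n_retained=len(streamlines),
        n_discarded={TERM_MIDLINE: n_excluded, "min_length": n_short},
        hemisphere=hemisphere,
        params=params,
        grid_shape=field.grid_shape,
        affine=field.affine.copy(),
        step_size=step,
    )


def compute_acm(
    streamlines: Sequence[Streamline],
    grid_shape: Sequence[int],
    affine: np.ndarray,
    hemisphere: str,
    step_size: float,
    n_launched: int = 0,
    n_retained: int | None = None,
    params: TrackingParams | None = None,
) -> AcmMap:
    """Count, per voxel, the number of distinct streamlines passing through.

    Each streamline increments a voxel at most once.  Voxel membership is
    decided point-in-voxel after supersampling every segment at half the
    step size.
    """
    shape = tuple(int(s) for s in grid_shape)
    n_vox = int(np.prod(shape))
    counts = np.zeros(shape, dtype=np.int32)
    inv = np.linalg.inv(affine)

    codes: list[np.ndarray] = []
    for sid, sl in enumerate(streamlines):
        pts = np.asarray(sl.points)
        if len(pts) > 1:
            mids = 0.5 * (pts[:-1] + pts[1:])
            dense = np.empty((len(pts) + len(mids), 3))
            dense[0::2] = pts
            dense[1::2] = mids
        else:
            dense = pts
        vox = np.rint(dense @ inv[:3, :3].T + inv[:3, 3]).astype(np.int64)
        if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
            raise ValidationError(
                f"streamline {sid} has points outside the grid (tracker contract violation)"
            )
        lin = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
        codes.append(np.unique(lin))
    if codes:
        all_lin = np.concatenate(codes)
        counts.reshape(-1)[:] = np.bincount(all_lin, minlength=n_vox).astype(np.int32)

    return AcmMap(
        counts=counts,
        hemisphere=hemisphere,
        n_launched=int(n_launched),
        n_retained=len(streamlines) if n_retained is None else int(n_retained),
        params=params,
        affine=np.asarray(affine, dtype=float).copy(),
    )


def track_and_count(
    field: OrientationField,
    wm_mask: np.ndarray,
    hemisphere: str,
    params: TrackingParams | None = None,
) -> AcmMap:
    """Convenience: :func:`track_unilateral` followed by :func:`compute_acm`."""
    result = track_unilateral(field, wm_mask, hemisphere, params)
    return compute_acm(
        result.streamlines,
        result.grid_shape,
        result.affine,
        hemisphere,
        result.step_size,
        n_launched=result.n_launched,
        n_retained=result.n_retained,
        params=result.params,
    )


def smooth_map(grid: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Gaussian smoothing with a full-width-half-maximum given in mm.

    ``fwhm_mm = 0`` is the identity.  Reflective boundaries keep constant
    images constant and preserve the total mass of interior deltas.
    """
    if fwhm_mm < 0:
        raise ValidationError("fwhm_mm must be non-negative")
    grid = np.asarray(grid, dtype=float)
    if fwhm_mm == 0:
        return grid.copy()
    from scipy.ndimage import gaussian_filter

    sigma_mm = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_vox = sigma_mm / np.asarray(voxel_size, dtype=float)
    return gaussian_filter(grid, sigma=sigma_vox, mode="reflect")
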