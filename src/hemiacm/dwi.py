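"""Diffusion-signal modeling: shell calibration, tensor fit, peak extraction.

The multi-shell acquisition uses different TE/TR settings per shell, which
offsets the absolute signal intensity between shells.  ``calibrate_shells``
removes those offsets by referencing every shell to a common mean b0 image.
``fit_tensor`` estimates the single diffusion tensor per voxel by weighted
least squares on log-signals and derives fractional anisotropy (FA) and
mean diffusivity (MD).  ``extract_peaks`` reduces the fit to a one-peak
orientation field for tracking on fitted (rather than ground-truth) data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import (
    MAX_POPULATIONS,
    AcquisitionScheme,
    OrientationField,
    ValidationError,
    hemisphere_labels,
)

__all__ = [
    "DwiVolumeSet",
    "TensorFit",
    "calibrate_shells",
    "fit_tensor",
    "extract_peaks",
    "tensor_signal",
    "fa_md_from_eigenvalues",
]

# b0 images of these shells define the overall mean b0 used for calibration
# (the low-b shell and reversed-phase b0 sets do not contribute).
DEFAULT_CALIBRATION_BVALUES = (1000.0, 2000.0)


@dataclass
class DwiVolumeSet:
    """4D diffusion-weighted signal volumes plus their gradient scheme."""

    data: np.ndarray  # (x, y, z, volume)
    scheme: AcquisitionScheme
    affine: np.ndarray
    calibration_qc: np.ndarray | None = None  # True where calibration undefined

    @property
    def grid_shape(self) -> tuple:
        return tuple(self.data.shape[:3])

    def validate(self) -> None:
        if self.data.ndim != 4:
            raise ValidationError("DWI data must be 4D (x, y, z, volume)")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValidationError(
                f"volume count {self.data.shape[3]} != scheme entries {self.scheme.n_volumes}"
            )
        if np.any(self.data < 0):
            raise ValidationError("signals must be non-negative")

    def shell_b0_image(self, shell_id: int) -> np.ndarray:
        """Mean of the shell's b0 volumes."""
        sel = (self.scheme.shell_ids == shell_id) & (self.scheme.bvals == 0)
        if not np.any(sel):
            raise ValidationError(f"shell {shell_id} has no b0 volume")
        return self.data[..., sel].mean(axis=-1)


def calibrate_shells(
    dwi: DwiVolumeSet,
    calibration_bvalues: tuple = DEFAULT_CALIBRATION_BVALUES,
) -> DwiVolumeSet:
    """Reference every shell to the overall mean b0.

    The overall mean b0 is the voxel-wise mean of the b0 images of the
    shells whose b-value is in ``calibration_bvalues``.  Each shell's
    calibration image is its own b0 divided by the overall mean b0, and all
    volumes of the shell are divided voxel-wise by that calibration image,
    so every shell's b0 afterwards equals the overall mean b0 wherever the
    calibration image is finite and nonzero.  Voxels where calibration is
    undefined (zero mean b0 or zero shell b0) are flagged in
    ``calibration_qc`` and passed through unchanged.
    """
    dwi.validate()
    shells = dwi.scheme.shells
    ref_shells = [
        s for s in shells if dwi.scheme.shell_bvalue(s) in tuple(float(b) for b in calibration_bvalues)
    ]
    if not ref_shells:
        raise ValidationError(
            f"no shell with b-value in {calibration_bvalues}; cannot form the overall mean b0"
        )
    overall = np.mean([dwi.shell_b0_image(s) for s in ref_shells], axis=0)

    data = dwi.data.copy()
    undefined = overall == 0
    for shell in shells:
        shell_b0 = dwi.shell_b0_image(shell)
        with np.errstate(divide="ignore", invalid="ignore"):
            calibration = shell_b0 / overall
        bad = undefined | (calibration == 0) | ~np.isfinite(calibration)
        factor = np.where(bad, 1.0, calibration)
        sel = dwi.scheme.shell_ids == shell
        data[..., sel] = data[..., sel] / factor[..., None]
        undefined = undefined | bad

    return DwiVolumeSet(
        data=data,
        scheme=dwi.scheme,
        affine=dwi.affine.copy(),
        calibration_qc=undefined,
    )


# ---------------------------------------------------------------------------
# Tensor model
# ---------------------------------------------------------------------------

# Tensor component order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
def _design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )


def tensor_matrices(components: np.ndarray) -> np.ndarray:
    """(..., 6) unique components -> (..., 3, 3) symmetric matrices."""
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(components, -1, 0)
    out = np.empty(components.shape[:-1] + (3, 3))
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


def tensor_signal(s0: float, tensor: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Closed-form single-tensor signal S = s0 exp(-b g'Dg)."""
    D = tensor_matrices(np.asarray(tensor)) if np.asarray(tensor).shape[-1] == 6 else np.asarray(tensor)
    quad = np.einsum("nj,...jk,nk->...n", bvecs, D, bvecs)
    return s0 * np.exp(-np.asarray(bvals) * quad)


def fa_md_from_eigenvalues(evals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA (normalized eigenvalue dispersion) and MD (mean eigenvalue)."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1)
    num = np.sum((evals - md[..., None]) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md


@dataclass
class TensorFit:
    """Voxel-wise diffusion-tensor fit with derived scalar maps."""

    tensor: np.ndarray  # (x, y, z, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz (mm^2/s)
    fa: np.ndarray
    md: np.ndarray
    fit_ok: np.ndarray
    eigenvalues: np.ndarray  # ascending, (x, y, z, 3)
    principal_direction: np.ndarray  # (x, y, z, 3)
    affine: np.ndarray
    voxel_size: np.ndarray

    @property
    def grid_shape(self) -> tuple:
        return tuple(self.fa.shape)


def fit_tensor(dwi: DwiVolumeSet, mask: np.ndarray | None = None) -> TensorFit:
    """Weighted-least-squares tensor fit on log-signals.

    A first ordinary-least-squares pass on ``log S`` provides predicted
    signals; the second pass weights each observation by the squared
    predicted signal, the standard WLS correction for log-transformed
    Rician-free noise.  Non-positive signals are excluded per voxel rather
    than clamped; voxels with fewer than 7 usable volumes (or a non-positive
    mean eigenvalue) are marked ``fit_ok = False`` and carry zero maps.
    """
    dwi.validate()
    X = _design_matrix(dwi.scheme)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        dw = dwi.scheme.bvals > 0
        n_unique = np.unique(np.round(dwi.scheme.bvecs[dw], 6), axis=0).shape[0]
        raise ValidationError(
            "rank-deficient gradient design: "
            f"rank {rank} < 7 with {n_unique} unique diffusion directions; "
            "at least 6 non-collinear directions plus b0 are required"
        )

    shape = dwi.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    flat = dwi.data.reshape(-1, dwi.scheme.n_volumes)
    sel = np.flatnonzero(mask.reshape(-1))
    signals = flat[sel]

    valid = signals > 0
    usable = valid.sum(axis=1) >= 7
    logs = np.where(valid, np.log(np.where(valid, signals, 1.0)), 0.0)

    def _wls(weights: np.ndarray) -> np.ndarray:
        # Solve (X'WX) beta = X'W y per voxel, batched.
        xtwx = np.einsum("ni,vn,nj->vij", X, weights, X)
        xtwy = np.einsum("ni,vn,vn->vi", X, weights, logs)
        return np.linalg.solve(xtwx, xtwy[..., None])[..., 0]

    w0 = valid.astype(float)
    w0[~usable] = 0.0
    w0[~usable, :7] = 1.0  # keep the batched solve non-singular; discarded below
    beta = _wls(w0)
    predicted = np.exp(X @ beta.T).T  # (v, n)
    w1 = np.where(valid, predicted**2, 0.0)
    w1[~usable] = 0.0
    w1[~usable, :7] = 1.0
    beta = _wls(w1)

    tensor = np.zeros(shape + (6,))
    fa = np.zeros(shape)
    md = np.zeros(shape)
    fit_ok = np.zeros(shape, dtype=bool)
    evals_map = np.zeros(shape + (3,))
    pdir = np.zeros(shape + (3,))

    D = tensor_matrices(beta[:, 1:])
    evals, evecs = np.linalg.eigh(D)
    fa_v, md_v = fa_md_from_eigenvalues(evals)
    ok = usable & (md_v > 0)

    flat_idx = sel
    tensor.reshape(-1, 6)[flat_idx] = np.where(ok[:, None], beta[:, 1:], 0.0)
    fa.reshape(-1)[flat_idx] = np.where(ok, fa_v, 0.0)
    md.reshape(-1)[flat_idx] = np.where(ok, md_v, 0.0)
    fit_ok.reshape(-1)[flat_idx] = ok
    evals_map.reshape(-1, 3)[flat_idx] = np.where(ok[:, None], evals, 0.0)
    pdir.reshape(-1, 3)[flat_idx] = np.where(ok[:, None], evecs[..., 2], 0.0)

    voxel_size = np.linalg.norm(dwi.affine[:3, :3], axis=0)
    return TensorFit(
        tensor=tensor,
        fa=fa,
        md=md,
        fit_ok=fit_ok,
        eigenvalues=evals_map,
        principal_direction=pdir,
        affine=dwi.affine.copy(),
        voxel_size=voxel_size,
    )


def extract_peaks(tf: TensorFit, amplitude_floor: float = 0.1) -> OrientationField:
    """Single-peak orientation field from a tensor fit.

    Each well-fitted voxel contributes one population: the principal
    eigenvector with amplitude FA; populations below ``amplitude_floor``
    are dropped.  This is the default orientation source when tracking
    fitted data; phantom ground-truth fields provide the multi-peak case.
    """
    if amplitude_floor < 0:
        raise ValidationError("amplitude_floor must be non-negative")
    shape = tf.grid_shape
    directions = np.zeros(shape + (MAX_POPULATIONS, 3))
    amplitudes = np.zeros(shape + (MAX_POPULATIONS,))

    keep = tf.fit_ok & (tf.fa >= amplitude_floor)
    norms = np.linalg.norm(tf.principal_direction, axis=-1)
    keep &= norms > 0
    unit = np.zeros_like(tf.principal_direction)
    nz = norms > 0
    unit[nz] = tf.principal_direction[nz] / norms[nz][..., None]
    directions[..., 0, :] = np.where(keep[..., None], unit, 0.0)
    amplitudes[..., 0] = np.where(keep, tf.fa, 0.0)

    field = OrientationField(
        directions=directions,
        amplitudes=amplitudes,
        wm_mask=keep,
        hemisphere_labels=hemisphere_labels(shape),
        voxel_size=tf.voxel_size.copy(),
        affine=tf.affine.copy(),
    )
    field.validate()
    return field
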