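"""File I/O: NIfTI volumes, FSL-style bval/bvec gradient tables, TSV tables.

Gradient tables follow the FSL convention: the ``.bval`` file holds one
whitespace-separated row of b-values and the ``.bvec`` file three rows with
the x, y and z components of the diffusion directions.  Because b0 volumes
carry no direction, shell membership of b0s and per-shell scale factors are
kept in a small JSON sidecar; when it is absent each b0 is assigned to the
shell of the next diffusion-weighted volume in acquisition order.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import AcquisitionScheme, ValidationError

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_gradient_table",
    "read_gradient_table",
    "write_dwi",
    "read_dwi",
    "write_json",
    "read_json",
]


def save_nifti(data: np.ndarray, affine: np.ndarray, path, dtype=None) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_gradient_table(scheme: AcquisitionScheme, prefix) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.bval``, ``<prefix>.bvec`` and ``<prefix>.shells.json``."""
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    json_path = prefix.with_suffix(".shells.json")
    bval_path.write_text(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    rows = [" ".join(f"{v:.10f}" for v in scheme.bvecs[:, ax]) for ax in range(3)]
    bvec_path.write_text("\n".join(rows) + "\n")
    json_path.write_text(
        json.dumps(
            {
                "shell_ids": scheme.shell_ids.tolist(),
                "shell_scales": scheme.shell_scales.tolist(),
            },
            indent=2,
        )
    )
    return bval_path, bvec_path, json_path


def read_gradient_table(prefix) -> AcquisitionScheme:
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    if not bval_path.exists() or not bvec_path.exists():
        missing = bval_path if not bval_path.exists() else bvec_path
        raise ValidationError(f"gradient table file not found: {missing}")
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.shape[0], 3):
        raise ValidationError(
            f"gradient table mismatch: {bvals.shape[0]} b-values vs {bvecs.shape} directions"
        )

    json_path = prefix.with_suffix(".shells.json")
    if json_path.exists():
        meta = json.loads(json_path.read_text())
        shell_ids = np.asarray(meta["shell_ids"], dtype=int)
        shell_scales = np.asarray(meta["shell_scales"], dtype=float)
    else:
        # Assign each volume (b0s included) to the shell of the next
        # diffusion-weighted volume in acquisition order.
        nonzero = sorted(set(np.round(bvals[bvals > 0], 0)))
        shell_of_b = {b: i for i, b in enumerate(nonzero)}
        shell_ids = np.empty(len(bvals), dtype=int)
        current = None
        for j in range(len(bvals) - 1, -1, -1):
            if bvals[j] > 0:
                current = shell_of_b[round(float(bvals[j]), 0)]
            shell_ids[j] = current if current is not None else 0
        shell_scales = np.ones(len(nonzero) if nonzero else 1)
    scheme = AcquisitionScheme(
        bvals=bvals, bvecs=bvecs, shell_ids=shell_ids, shell_scales=shell_scales
    )
    scheme.validate()
    return scheme


def write_dwi(dwi, prefix) -> dict:
    """Write a DWI volume set as ``<prefix>.nii.gz`` plus gradient files."""
    prefix = Path(prefix)
    nii = save_nifti(dwi.data, dwi.affine, prefix.parent / (prefix.name + ".nii.gz"))
    bval, bvec, shells = write_gradient_table(dwi.scheme, prefix)
    return {"nifti": nii, "bval": bval, "bvec": bvec, "shells": shells}


def read_dwi(prefix):
    from .dwi import DwiVolumeSet

    prefix = Path(prefix)
    data, affine = load_nifti(prefix.parent / (prefix.name + ".nii.gz"))
    scheme = read_gradient_table(prefix)
    dwi = DwiVolumeSet(data=data, scheme=scheme, affine=affine)
    dwi.validate()
    return dwi


def write_json(obj, path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
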