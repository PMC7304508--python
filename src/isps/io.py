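"""NIfTI group loading and map serialization.

Voxel linear ordering inside a mask is fixed as x-fastest (Fortran flatten of
the (x, y, z) volume), so that matrices, serialized maps and the run-length
encoded masks in ground-truth files all agree bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "mask_indices",
    "apply_mask",
    "unmask",
    "load_group",
    "save_map",
]


def mask_indices(mask: np.ndarray) -> np.ndarray:
    """Flat indices (x-fastest order) of the true voxels of a 3D mask."""
    return np.flatnonzero(np.asarray(mask, dtype=bool).reshape(-1, order="F"))


def apply_mask(vol4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract a voxels x time matrix from a 4D volume, x-fastest row order."""
    vol4d = np.asarray(vol4d)
    n_t = vol4d.shape[-1]
    flat = vol4d.reshape(-1, n_t, order="F")
    return flat[mask_indices(mask)]


def unmask(matrix: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Restore a voxels x (time|components) matrix into a 4D volume."""
    matrix = np.atleast_2d(matrix)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros((mask.size, matrix.shape[1]))
    out[mask_indices(mask)] = matrix
    return out.reshape(mask.shape + (matrix.shape[1],), order="F")


def load_group(
    subjects_dir, mask_path=None
) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Load every subject NIfTI in a directory as a masked matrix.

    Returns (matrices, mask, filenames); all files must share one grid and
    volume count.  Without an explicit mask, all voxels are analysed.
    """
    paths = sorted(
        p for p in Path(subjects_dir).iterdir()
        if p.name.endswith((".nii", ".nii.gz")) and not p.name.startswith("mask")
    )
    if len(paths) < 2:
        raise ValueError(f"need at least 2 subject NIfTI files in {subjects_dir}")
    vols = []
    shape = None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{p.name}: expected a 4D image, got shape {data.shape}")
        if shape is None:
            shape = data.shape
        elif data.shape[:3] != shape[:3]:
            raise ValueError(f"{p.name}: grid {data.shape[:3]} != {shape[:3]}")
        elif data.shape[3] != shape[3]:
            raise ValueError(f"{p.name}: {data.shape[3]} volumes != {shape[3]}")
        vols.append(data)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != shape[:3]:
            raise ValueError(f"mask grid {mask.shape} != data grid {shape[:3]}")
    else:
        mask = np.ones(shape[:3], dtype=bool)
    return [apply_mask(v, mask) for v in vols], mask, [p.name for p in paths]


def save_map(matrix: np.ndarray, mask: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a voxels x (time|components) matrix as a 4D NIfTI."""
    vol = unmask(matrix, mask)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine if affine is not None else np.eye(4)), str(path))
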