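"""Volume and table IO: NIfTI-1 round trips, CSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np


def save_volume(
    data: np.ndarray, grid_shape: Tuple[int, int, int], path, affine: np.ndarray | None = None
) -> None:
    """Write a flat (n_voxels,) or (n_voxels, T) array as a 3-D/4-D NIfTI-1 image."""
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    n_vox = int(np.prod(grid_shape))
    arr = np.asarray(data)
    if arr.shape[0] != n_vox:
        raise ValueError(f"data has {arr.shape[0]} voxels, grid holds {n_vox}")
    if arr.ndim == 1:
        vol = arr.reshape(grid_shape)
    elif arr.ndim == 2:
        vol = arr.reshape(grid_shape + (arr.shape[1],))
    else:
        raise ValueError("data must be 1-D or 2-D (voxels [x time])")
    nib.save(nib.Nifti1Image(np.asarray(vol), affine), str(path))


def load_volume(path, expect_4d: bool = False) -> Tuple[np.ndarray, Tuple[int, ...], np.ndarray]:
    """Load a NIfTI image back to a flat array; returns (data, grid_shape, affine)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format-specific errors
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    arr = np.asarray(img.dataobj)
    if expect_4d and arr.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {arr.ndim}-D")
    if arr.ndim == 3:
        return arr.reshape(-1), arr.shape, img.affine
    if arr.ndim == 4:
        grid = arr.shape[:3]
        return arr.reshape(-1, arr.shape[3]), grid, img.affine
    raise ValueError(f"{path}: unsupported dimensionality {arr.ndim}")


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path):
    return json.loads(Path(path).read_text())
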