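"""Image input/output and intensity normalization.

Supported containers: NIfTI-1 (``.nii`` / ``.nii.gz``) through nibabel, and a
plain ``.npz`` array container for tests. Only square (2D) or cubic (3D)
single-channel volumes are accepted — the solver maps the voxel lattice onto
the periodic domain [0, 2pi)^d, which requires equal axis lengths. Physical
voxel spacing from the NIfTI header is recorded in the written files but the
solver always works on the normalized domain.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .grid import Grid, ScalarField

__all__ = ["read_image", "write_image", "normalize_intensity"]

_NIFTI_EXTS = (".nii", ".nii.gz")


def _extension(path: str) -> str:
    low = str(path).lower()
    if low.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(low)[1]


def _validate_volume(values: np.ndarray, path) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    values = np.squeeze(values)
    if values.ndim not in (2, 3):
        raise ValueError(
            f"{path}: expected a single-channel 2D or 3D volume, got shape {values.shape}"
        )
    if len(set(values.shape)) != 1:
        raise ValueError(
            f"{path}: non-square volume {values.shape}; the periodic solver "
            "requires equal axis lengths (square/cubic grids)"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: volume contains NaN or infinite voxels")
    return values


def read_image(path) -> ScalarField:
    """Read a scalar image as a field on the periodic grid."""
    ext = _extension(path)
    if ext in _NIFTI_EXTS:
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
    elif ext == ".npz":
        with np.load(path) as data:
            if "values" not in data:
                raise ValueError(f"{path}: npz container missing 'values' array")
            values = data["values"]
    else:
        raise ValueError(f"{path}: unknown image extension {ext!r}")
    values = _validate_volume(values, path)
    return ScalarField(Grid(values.shape), values)


def write_image(field: ScalarField, path, spacing: float | None = None) -> None:
    """Write a field; voxel spacing (defaults to the grid spacing) goes into
    the header/affine. Round trip through either format is bit exact."""
    ext = _extension(path)
    values = np.asarray(field.values, dtype=np.float64)
    h = spacing if spacing is not None else field.grid.spacing[0]
    if ext in _NIFTI_EXTS:
        d = values.ndim
        affine = np.eye(4)
        for i in range(d):
            affine[i, i] = h
        img = nib.Nifti1Image(values, affine)
        img.header.set_data_dtype(np.float64)
        zooms = tuple([h] * d)
        img.header.set_zooms(zooms)
        nib.save(img, str(path))
    elif ext == ".npz":
        np.savez(path, values=values, spacing=np.asarray([h] * values.ndim))
    else:
        raise ValueError(f"{path}: unknown image extension {ext!r}")


def normalize_intensity(f: ScalarField) -> ScalarField:
    """Affinely rescale intensities to [0, 1]; a constant image maps to 0."""
    lo = float(f.values.min())
    hi = float(f.values.max())
    if hi == lo:
        return ScalarField(f.grid, np.zeros(f.grid.dims))
    return ScalarField(f.grid, (f.values - lo) / (hi - lo))
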