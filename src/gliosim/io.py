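"""NIfTI input/output for scalar volumes, binary masks and tensor fields.

All volumes are NIfTI-1 (.nii / .nii.gz) with an affine; masks are uint8.
Diffusion-tensor fields are stored as 4D NIfTI with six components per
voxel in lower-triangular row order ``(dxx, dxy, dxz, dyy, dyz, dzz)``.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .fields import Grid3D

TENSOR_COMPONENT_ORDER = ("dxx", "dxy", "dxz", "dyy", "dyz", "dzz")


class VolumeFormatError(ValueError):
    """File does not match the expected NIfTI layout."""


def grid_to_affine(grid: Grid3D) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    # Voxel (0,0,0) centre sits at origin + 0.5*spacing.
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.spacing)
    return aff


def grid_from_affine(shape, affine: np.ndarray) -> Grid3D:
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(affine[i, 3] - 0.5 * spacing[i]) for i in range(3))
    return Grid3D(tuple(int(n) for n in shape[:3]), spacing, origin)


def write_volume(field: np.ndarray, path, grid: Grid3D | None = None) -> None:
    field = np.asarray(field)
    if field.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got ndim={field.ndim}")
    affine = grid_to_affine(grid) if grid is not None else np.eye(4)
    dtype = np.uint8 if field.dtype == bool else field.dtype
    nib.save(nib.Nifti1Image(field.astype(dtype), affine), str(path))


def read_volume(path) -> tuple[np.ndarray, Grid3D]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got shape {data.shape}")
    if img.affine is None:
        raise VolumeFormatError("volume has no affine")
    return data, grid_from_affine(data.shape, img.affine)


def read_mask(path, tol: float = 1e-6) -> tuple[np.ndarray, Grid3D]:
    """Read a binary VOI mask; values must be within ``tol`` of {0, 1}."""
    data, grid = read_volume(path)
    near0 = np.abs(data) <= tol
    near1 = np.abs(data - 1.0) <= tol
    if not np.all(near0 | near1):
        bad = data[~(near0 | near1)]
        raise VolumeFormatError(
            f"mask has {bad.size} non-binary values (e.g. {bad.flat[0]!r})"
        )
    return near1, grid


def project_spd(tensors: np.ndarray, floor_frac: float = 1e-12) -> tuple[np.ndarray, int]:
    """Clip negative tensor eigenvalues to ``floor_frac`` of the trace.

    ``tensors`` has shape (..., 3, 3) symmetric.  Returns the projected
    field and the number of voxels that needed clipping.
    """
    w, v = np.linalg.eigh(tensors)
    trace = np.clip(tensors[..., 0, 0] + tensors[..., 1, 1] + tensors[..., 2, 2], 0, None)
    floor = floor_frac * np.maximum(trace, 1e-300)[..., None]
    clipped = int(np.sum(np.any(w < 0, axis=-1)))
    w = np.maximum(w, floor)
    out = np.einsum("...ij,...j,...kj->...ik", v, w, v)
    return 0.5 * (out + np.swapaxes(out, -1, -2)), clipped


def tensor_from_components(comp: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric tensors."""
    dxx, dxy, dxz, dyy, dyz, dzz = np.moveaxis(comp, -1, 0)
    out = np.empty(comp.shape[:-1] + (3, 3))
    out[..., 0, 0] = dxx
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 1] = dyy
    out[..., 1, 2] = out[..., 2, 1] = dyz
    out[..., 2, 2] = dzz
    return out


def tensor_to_components(tensors: np.ndarray) -> np.ndarray:
    i, j = [0, 0, 0, 1, 1, 2], [0, 1, 2, 1, 2, 2]
    return np.stack([tensors[..., a, b] for a, b in zip(i, j)], axis=-1)


def write_tensor_field(tensors: np.ndarray, path, grid: Grid3D | None = None) -> None:
    comp = tensor_to_components(np.asarray(tensors))
    affine = grid_to_affine(grid) if grid is not None else np.eye(4)
    nib.save(nib.Nifti1Image(comp.astype(np.float64), affine), str(path))


def read_tensor_field(path) -> tuple[np.ndarray, Grid3D, int]:
    """Read a 6-component tensor NIfTI; tensors are SPD-projected.

    Returns ``(tensors, grid, n_clipped)`` where ``n_clipped`` counts voxels
    whose tensors had negative eigenvalues clipped.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 6:
        raise VolumeFormatError(
            f"expected a 4D volume with 6 tensor components, got shape {data.shape}"
        )
    tensors = tensor_from_components(data)
    tensors, clipped = project_spd(tensors)
    return tensors, grid_from_affine(data.shape, img.affine), clipped
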