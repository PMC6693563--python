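"""NIfTI adapters: flatten 4-D volumes to vertex series and back.

Real datasets often arrive as NIfTI time series; these helpers map between
that container and the (n_vertices, T) arrays the pipeline operates on.
nibabel is an optional dependency (install the ``nifti`` extra).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ValidationError
from .sweep_design import ApertureStack


def _nib():
    try:
        import nibabel
    except ImportError as err:  # pragma: no cover
        raise ImportError("NIfTI support requires nibabel (pip install "
                          "'motionprf[nifti]')") from err
    return nibabel


def load_timeseries_nifti(path: str | Path, mask: np.ndarray | None = None
                          ) -> np.ndarray:
    """Load a 4-D NIfTI as an (n_voxels, T) array, voxels flattened in C order.

    ``mask`` (3-D boolean, same grid) restricts which voxels become rows.
    """
    img = _nib().load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D time-series image, got {data.ndim}-D")
    flat = data.reshape(-1, data.shape[-1])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValidationError("mask shape does not match the image grid")
        flat = flat[mask.ravel()]
    return np.asarray(flat, dtype=float)


def save_timeseries_nifti(series: np.ndarray, path: str | Path,
                          shape3d: tuple[int, int, int] | None = None) -> None:
    """Write (n_voxels, T) series as a 4-D NIfTI (identity affine).

    Without ``shape3d`` the voxels are laid out along the first axis
    (n x 1 x 1 grid).
    """
    nib = _nib()
    series = np.asarray(series, dtype=np.float32)
    if series.ndim != 2:
        raise ValidationError("series must be 2-D (n_voxels, T)")
    n, T = series.shape
    if shape3d is None:
        shape3d = (n, 1, 1)
    if int(np.prod(shape3d)) != n:
        raise ValidationError(f"shape3d {shape3d} does not hold {n} voxels")
    vol = series.reshape(*shape3d, T)
    nib.Nifti1Image(vol, np.eye(4)).to_filename(str(path))


def save_apertures_nifti(stack: ApertureStack, path: str | Path) -> None:
    """Write the aperture stack as a 4-D NIfTI (H x W x 1 x T, identity affine)."""
    nib = _nib()
    vol = np.transpose(stack.frames, (1, 2, 0))[:, :, None, :].astype(np.uint8)
    nib.Nifti1Image(vol, np.eye(4)).to_filename(str(path))
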