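"""Measurement-container and image I/O.

The measurement container is an NPZ or HDF5 file with named fields:
``kspace`` (coils x M complex), ``mask`` (boolean grid), optional ``maps``
(coils x grid complex) and ``shape``.  Magnitude images are written as NIfTI
(float) or PNG (8-bit preview).
"""

from __future__ import annotations

import os

import h5py
import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .operators import KSpaceData
from .sampling import SamplingMask

__all__ = ["save_measurements", "load_measurements", "save_image",
           "load_image", "save_mask_png"]


def _mask_kind(kind) -> str:
    if isinstance(kind, bytes):
        return kind.decode()
    return str(kind)


def save_measurements(path, data: KSpaceData) -> None:
    """Write a KSpaceData container to ``path`` (.npz or .h5/.hdf5)."""
    ext = os.path.splitext(str(path))[1].lower()
    mask = data.mask
    fields = {
        "kspace": data.y,
        "mask": mask.grid,
        "shape": np.asarray(mask.shape),
        "mask_kind": np.asarray(mask.kind),
    }
    if data.sensitivities is not None:
        fields["maps"] = np.stack(data.sensitivities)
    if ext == ".npz":
        np.savez(path, **fields)
    elif ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for k, v in fields.items():
                if k == "mask_kind":
                    f.attrs["mask_kind"] = mask.kind
                else:
                    f.create_dataset(k, data=v)
    else:
        raise ValueError(f"unsupported container extension: {ext}")


def load_measurements(path) -> KSpaceData:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".npz":
        with np.load(path, allow_pickle=False) as f:
            kind = _mask_kind(f["mask_kind"][()]) if "mask_kind" in f else "full"
            mask = SamplingMask(np.asarray(f["mask"], dtype=bool), kind=kind)
            maps = [m for m in f["maps"]] if "maps" in f.files else None
            return KSpaceData(y=f["kspace"], mask=mask, sensitivities=maps)
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            kind = _mask_kind(f.attrs.get("mask_kind", "full"))
            mask = SamplingMask(np.asarray(f["mask"], dtype=bool), kind=kind)
            maps = [m for m in f["maps"][...]] if "maps" in f else None
            return KSpaceData(y=f["kspace"][...], mask=mask,
                              sensitivities=maps)
    raise ValueError(f"unsupported container extension: {ext}")


def save_image(path, image, max_mr: float = 255.0) -> None:
    """Write a magnitude image: NIfTI keeps float values, PNG is an 8-bit
    preview scaled by ``max_mr``."""
    mag = np.abs(np.asarray(image)).astype(np.float64)
    ext = str(path).lower()
    if ext.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(mag, affine=np.eye(4)), str(path))
    elif ext.endswith(".png"):
        scaled = np.clip(mag / max_mr, 0, 1)
        iio.imwrite(path, (scaled * 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image extension for {path}")


def load_image(path) -> np.ndarray:
    ext = str(path).lower()
    if ext.endswith((".nii", ".nii.gz")):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    if ext.endswith(".png"):
        return np.asarray(iio.imread(path), dtype=np.float64)
    raise ValueError(f"unsupported image extension for {path}")


def save_mask_png(path, mask: SamplingMask) -> None:
    """Export a sampling mask as a black/white PNG for inspection."""
    iio.imwrite(path, (mask.grid.astype(np.uint8) * 255))
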