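"""File I/O: PNG and NIfTI masks/images, field volumes, CSV reports, YAML configs.

Dialects enforced here: PNG masks are 0/255 (8-bit), NIfTI masks are
0/1; multi-channel data is stored as a multi-volume NIfTI with the
channel on the last axis; deformation fields are 2-volume NIfTI files
(row- then column-displacement) with the grid spacing in the header.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml

from .fields import DeformationField, DisplacementField, Grid2D

__all__ = [
    "save_mask",
    "load_mask",
    "save_image",
    "load_image",
    "save_field",
    "load_field",
    "load_yaml",
    "dump_yaml",
]


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask: PNG (0/255) or NIfTI (0/1, channels last)."""
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix == ".png":
        if mask.ndim != 2:
            raise ValueError("PNG masks are single-channel; use NIfTI for stacks")
        iio.imwrite(path, (mask > 0).astype(np.uint8) * 255)
    else:
        data = (mask > 0).astype(np.uint8)
        if data.ndim == 3:  # [c, H, W] -> [H, W, c]
            data = np.moveaxis(data, 0, -1)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`save_mask`; returns [H, W] or [c, H, W]."""
    path = Path(path)
    if path.suffix == ".png":
        return (iio.imread(path) > 127).astype(np.uint8)
    data = np.asarray(nib.load(str(path)).dataobj)
    data = (data > 0).astype(np.uint8)
    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)
    return data


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as 16-bit PNG or float NIfTI."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.suffix == ".png":
        iio.imwrite(path, np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16))
    else:
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), str(path))


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".png":
        raw = iio.imread(path).astype(float)
        scale = 65535.0 if raw.max() > 255 else 255.0
        return raw / scale
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_field(phi: DeformationField, path: str | Path) -> None:
    """Store a deformation as a 2-volume NIfTI of displacements."""
    data = np.moveaxis(phi.displacement.values.astype(np.float64), 0, -1)
    img = nib.Nifti1Image(data, np.eye(4) * phi.grid.spacing)
    img.header.set_zooms((phi.grid.spacing, phi.grid.spacing, 1.0))
    nib.save(img, str(path))


def load_field(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    spacing = float(img.header.get_zooms()[0])
    grid = Grid2D(data.shape[1], data.shape[2], spacing)
    return DeformationField(DisplacementField(data, grid))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
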