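"""NIfTI-1 and config file I/O.

Volumes are written one file per channel as 32-bit float NIfTI-1 with a
diagonal affine (axis-aligned grids only; the translation column is the world
position of voxel (0,0,0)).  Deformation fields are 4-D NIfTI with the vector
dimension last, unit mm, direction reference->subject recorded in the header
description.  Round trips preserve dims, spacing, origin and 32-bit values
bit-exactly.
"""
from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError
from .grids import DeformationField, ImageGrid3D, ScalarVolume, TissueLabelVolume

FIELD_DESCRIP = b"displacement mm reference->subject"


def _affine(grid: ImageGrid3D) -> np.ndarray:
    aff = np.eye(4)
    for i in range(3):
        aff[i, i] = grid.spacing[i]
        aff[i, 3] = grid.origin[i]
    return aff


def _grid_from_image(img, path) -> ImageGrid3D:
    aff = img.affine
    rot = aff[:3, :3].copy()
    spacing = np.diag(rot).copy()
    np.fill_diagonal(rot, 0.0)
    if np.abs(rot).max() > 1e-6:
        raise FormatError(f"{path}: affine is not axis-aligned (rotation/shear present)")
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise FormatError(f"{path}: non-positive voxel spacing {tuple(spacing)}")
    dims = img.shape[:3]
    # NIfTI-1 stores the affine in 32-bit floats; snap to 6 decimals so grids
    # like 2.07 mm spacing round-trip to their written values exactly
    spacing = np.round(spacing.astype(float), 6)
    origin = np.round(np.asarray(aff[:3, 3], dtype=float), 6)
    return ImageGrid3D(tuple(int(d) for d in dims), tuple(spacing), tuple(origin))


def _load(path):
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse NIfTI ({exc})") from exc
    return img, data


def write_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), _affine(vol.grid))
    img.to_filename(str(path))


def read_volume(path) -> ScalarVolume:
    img, data = _load(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D scalar volume, got shape {data.shape}")
    grid = _grid_from_image(img, path)
    return ScalarVolume(grid, np.asarray(data, dtype=float))


def write_labels(labels: TissueLabelVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(labels.labels, dtype=np.int16), _affine(labels.grid))
    img.to_filename(str(path))


def read_labels(path) -> TissueLabelVolume:
    img, data = _load(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D label volume, got shape {data.shape}")
    grid = _grid_from_image(img, path)
    return TissueLabelVolume(grid, np.asarray(data, dtype=np.int16))


def write_field(field: DeformationField, path) -> None:
    img = nib.Nifti1Image(np.asarray(field.u, dtype=np.float32), _affine(field.grid))
    img.header["descrip"] = FIELD_DESCRIP
    img.to_filename(str(path))


def read_field(path) -> DeformationField:
    img, data = _load(path)
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(
            f"{path}: expected a 4-D displacement field (..., 3), got shape {data.shape}"
        )
    grid = _grid_from_image(img, path)
    return DeformationField(grid, np.asarray(data, dtype=float))


def write_config(obj, path) -> None:
    """Serialise a (nested) dataclass config as plain-text YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(obj), fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a key-value mapping")
    return data


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
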