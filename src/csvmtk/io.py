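"""Readers and writers for the toolkit's standard formats.

Float images round-trip losslessly through NIfTI and TIFF; PNG
round-trips after the documented 8-bit quantization of the [0, 1]
scale. Label maps round-trip exactly as integers in every format.
Series are stored as multi-page TIFF stacks or 4D NIfTI volumes;
transforms and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .errors import FormatError
from .transforms import RigidTransform2D

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _check_finite(arr: np.ndarray, path: Path) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        coords = tuple(int(c) for c in np.argwhere(bad)[0])
        raise FormatError(
            f"{path}: non-finite pixel value at coordinates {coords}")


def read_image(path) -> np.ndarray:
    """Read a 2D grayscale image as float; PNG is rescaled to [0, 1]."""
    path = Path(path)
    suffix = _suffix(path)
    try:
        if suffix in _NIFTI_SUFFIXES:
            arr = np.asarray(nib.load(path).dataobj, dtype=float)
            arr = np.squeeze(arr)
        elif suffix in _TIFF_SUFFIXES:
            arr = tifffile.imread(path).astype(float)
        elif suffix == ".png":
            arr = iio.imread(path).astype(float)
            if arr.ndim == 3:
                arr = arr[..., 0]
            arr = arr / 255.0
        else:
            raise FormatError(f"unsupported image format: {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D image, got {arr.shape}")
    _check_finite(arr, path)
    return arr


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(image, dtype=float)
    _check_finite(arr, path)
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        nib.save(nib.Nifti1Image(arr[..., None].astype(np.float64),
                                 np.eye(4)), path)
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr.astype(np.float64))
    elif suffix == ".png":
        data = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
        iio.imwrite(path, data)
    else:
        raise FormatError(f"unsupported image format: {path}")


def read_labels(path) -> np.ndarray:
    """Read an integer label map (exact round-trip in every format)."""
    path = Path(path)
    suffix = _suffix(path)
    try:
        if suffix in _NIFTI_SUFFIXES:
            arr = np.squeeze(np.asarray(nib.load(path).dataobj))
        elif suffix in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = iio.imread(path)
            if arr.ndim == 3:
                arr = arr[..., 0]
        else:
            raise FormatError(f"unsupported label format: {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    return np.asarray(arr).astype(int)


def write_labels(path, labels: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(labels)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError("label maps must be integer-valued")
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        nib.save(nib.Nifti1Image(arr[..., None].astype(np.int16),
                                 np.eye(4)), path)
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr.astype(np.int16))
    elif suffix == ".png":
        if arr.min() < 0 or arr.max() > 255:
            raise FormatError("PNG label maps must fit in 8 bits")
        iio.imwrite(path, arr.astype(np.uint8))
    else:
        raise FormatError(f"unsupported label format: {path}")


def read_series(path) -> np.ndarray:
    """Read an ``(n, H, W)`` frame stack from TIFF or 4D NIfTI."""
    path = Path(path)
    suffix = _suffix(path)
    try:
        if suffix in _TIFF_SUFFIXES:
            arr = tifffile.imread(path).astype(float)
        elif suffix in _NIFTI_SUFFIXES:
            arr = np.asarray(nib.load(path).dataobj, dtype=float)
            if arr.ndim == 4:  # stored (H, W, 1, n)
                arr = np.moveaxis(arr[:, :, 0, :], -1, 0)
            elif arr.ndim == 3:
                arr = np.moveaxis(arr, -1, 0)
            else:
                raise FormatError(f"{path}: expected a series volume")
        else:
            raise FormatError(f"unsupported series format: {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected (n, H, W) frames, got {arr.shape}")
    _check_finite(arr, path)
    return arr


def write_series(path, frames: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3:
        raise FormatError("series must be an (n, H, W) stack")
    _check_finite(arr, path)
    suffix = _suffix(path)
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr.astype(np.float64),
                         photometric="minisblack")
    elif suffix in _NIFTI_SUFFIXES:
        vol = np.moveaxis(arr, 0, -1)[:, :, None, :]
        nib.save(nib.Nifti1Image(vol.astype(np.float64), np.eye(4)), path)
    else:
        raise FormatError(f"unsupported series format: {path}")


def write_transforms(path, transforms: Sequence[RigidTransform2D]) -> None:
    records = [{"frame": i, **t.to_dict()} for i, t in enumerate(transforms)]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_transforms(path) -> list[RigidTransform2D]:
    records = json.loads(Path(path).read_text())
    records = sorted(records, key=lambda r: r["frame"])
    return [RigidTransform2D.from_dict(r) for r in records]


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify)
                          + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_trace(path, values: np.ndarray) -> None:
    """Energy/iteration trace as a two-column CSV."""
    values = np.asarray(values, dtype=float)
    rows = np.column_stack([np.arange(values.size), values])
    np.savetxt(path, rows, delimiter=",", header="iteration,energy",
               comments="", fmt=["%d", "%.10g"])
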