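"""NIfTI reading/writing and SimpleITK interop for volumes and masks.

Masks are stored as uint8 0/1 NIfTI; any nonzero voxel reads back as true.
"""

from __future__ import annotations

import logging
import os
import sys

import numpy as np
import SimpleITK as sitk

from .volume import BinaryMask, ScalarVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "to_sitk",
    "from_sitk",
    "get_logger",
]

_log = logging.getLogger("handmuscle")


def get_logger(logfile: str | None = None, verbose: bool = False) -> logging.Logger:
    """Pipeline logger writing timestamped stage lines to stderr (and a file)."""
    if not _log.handlers:
        fmt = logging.Formatter("%(asctime)s %(name)s [%(levelname)s] %(message)s")
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(fmt)
        _log.addHandler(h)
        if logfile:
            fh = logging.FileHandler(logfile)
            fh.setFormatter(fmt)
            _log.addHandler(fh)
    _log.setLevel(logging.DEBUG if verbose else logging.INFO)
    return _log


def to_sitk(obj: ScalarVolume | BinaryMask) -> sitk.Image:
    """Convert to a SimpleITK image (identity direction matrix)."""
    arr = obj.data.astype(np.uint8) if isinstance(obj, BinaryMask) else obj.data
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(obj.spacing))
    img.SetOrigin(tuple(obj.origin))
    return img


def from_sitk(img: sitk.Image, as_mask: bool = False) -> ScalarVolume | BinaryMask:
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    if as_mask:
        return BinaryMask(arr != 0, spacing, origin)
    return ScalarVolume(arr.astype(np.float32), spacing, origin)


def _read(path: str) -> sitk.Image:
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    if any(s <= 0 for s in img.GetSpacing()):
        raise ValueError(f"{path}: non-positive voxel spacing {img.GetSpacing()}")
    return img


def read_volume(path: str) -> ScalarVolume:
    """Read a 3D NIfTI scalar volume; spacing/origin come from the header."""
    return from_sitk(_read(path), as_mask=False)


def write_volume(volume: ScalarVolume, path: str) -> None:
    sitk.WriteImage(to_sitk(volume), path)


def read_mask(path: str, reference: ScalarVolume | BinaryMask | None = None) -> BinaryMask:
    """Read a binary mask (nonzero → true), optionally checking its geometry
    against a reference volume."""
    mask = from_sitk(_read(path), as_mask=True)
    if reference is not None and not mask.same_geometry(reference):
        raise ValueError(f"{path}: mask geometry does not match the reference volume")
    return mask


def write_mask(mask: BinaryMask, path: str, reference: ScalarVolume | BinaryMask | None = None) -> None:
    if reference is not None and not mask.same_geometry(reference):
        raise ValueError("mask geometry does not match the declared reference")
    sitk.WriteImage(to_sitk(mask), path)
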