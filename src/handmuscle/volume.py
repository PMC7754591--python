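"""Shared image data model: scalar volumes, binary masks, slice-range VOIs.

Arrays are stored in ``(z, y, x)`` index order (slice axis first, matching
``SimpleITK.GetArrayFromImage``), while ``spacing`` and ``origin`` are given
in physical ``(x, y, z)`` order in millimetres, the NIfTI/ITK convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ScalarVolume", "BinaryMask", "VoiSpec", "crop_to_voi"]

#: Upper bound of the per-mille fat-fraction scale.
FF_MAX = 1000.0


def _check_geometry(data: np.ndarray, spacing, name: str) -> None:
    if data.ndim != 3:
        raise ValueError(f"{name} requires a 3D array, got {data.ndim} dimensions")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"{name} spacing must be three positive values, got {spacing!r}")


@dataclass
class ScalarVolume:
    """A 3D scalar image on an anisotropic voxel grid.

    Parameters
    ----------
    data
        Intensities, shape ``(nz, ny, nx)``. MR units are arbitrary; fat
        fraction volumes use per-mille (0–1000).
    spacing
        Voxel size ``(sx, sy, sz)`` in mm.
    origin
        Physical offset ``(ox, oy, oz)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        _check_geometry(self.data, self.spacing, "ScalarVolume")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ScalarVolume | BinaryMask") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        """New volume on the same grid with different intensities."""
        if np.asarray(data).shape != self.data.shape:
            raise ValueError("with_data must preserve the grid shape")
        return replace(self, data=np.asarray(data, dtype=np.float32))


@dataclass
class BinaryMask:
    """A boolean voxel set aligned to a :class:`ScalarVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        _check_geometry(self.data, self.spacing, "BinaryMask")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        """Physical volume of the mask in mm³."""
        return self.voxel_count * self.voxel_volume

    def same_geometry(self, other: "ScalarVolume | BinaryMask") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def like(self, data: np.ndarray) -> "BinaryMask":
        if np.asarray(data).shape != self.data.shape:
            raise ValueError("like() must preserve the grid shape")
        return replace(self, data=np.asarray(data) != 0)

    @classmethod
    def empty_like(cls, ref: "ScalarVolume | BinaryMask") -> "BinaryMask":
        return cls(np.zeros(ref.data.shape, dtype=bool), ref.spacing, ref.origin)


@dataclass(frozen=True)
class VoiSpec:
    """Inclusive slice range ``[z_start, z_end]`` delimiting the analysis VOI.

    Mirrors the manual placement of the proximal and distal MCP III
    boundary slices: the operator picks two delimiting slices, both kept.
    Indices are 0-based.
    """

    z_start: int
    z_end: int

    def __post_init__(self) -> None:
        if self.z_start < 0 or self.z_end < self.z_start:
            raise ValueError(f"invalid VOI slice range [{self.z_start}, {self.z_end}]")

    @property
    def n_slices(self) -> int:
        return self.z_end - self.z_start + 1

    def length_mm(self, slice_thickness: float) -> float:
        """Physical length of the VOI along the scan direction."""
        return self.n_slices * slice_thickness

    def validate_for(self, n_slices: int) -> None:
        if self.z_end >= n_slices:
            raise ValueError(
                f"VOI [{self.z_start}, {self.z_end}] exceeds the {n_slices}-slice volume"
            )

    def shifted(self, dz: int, n_slices: int | None = None) -> "VoiSpec":
        z0, z1 = self.z_start + dz, self.z_end + dz
        if n_slices is not None:
            z0 = int(np.clip(z0, 0, n_slices - 1))
            z1 = int(np.clip(z1, z0, n_slices - 1))
        return VoiSpec(z0, z1)


def crop_to_voi(mask: BinaryMask, voi: VoiSpec) -> BinaryMask:
    """Zero every mask voxel outside the inclusive slice range of *voi*.

    Idempotent; voxels inside the range are untouched.
    """
    voi.validate_for(mask.shape[0])
    out = np.zeros_like(mask.data)
    out[voi.z_start : voi.z_end + 1] = mask.data[voi.z_start : voi.z_end + 1]
    return mask.like(out)
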