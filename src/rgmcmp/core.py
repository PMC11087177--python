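"""Core grid containers shared by every pipeline stage.

Arrays are indexed ``[x, y, z]`` with the axial (slice) direction on the
last axis; ``spacing`` is the physical voxel size in millimetres per axis.
Orientation is assumed axis-aligned (identity direction matrix): physical
coordinates are ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "LabelMask", "GridError"]


class GridError(ValueError):
    """Two grids that must share a lattice do not."""


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {x!r}")
    return t


@dataclass
class Volume:
    """A 3D scalar image (HU or normalized intensities) with voxel spacing."""

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.array.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    def same_lattice(self, other: "Volume | LabelMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_array(self, array: np.ndarray) -> "Volume":
        return replace(self, array=array)

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.array.transpose(2, 1, 0)).astype(np.float64)
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


@dataclass
class LabelMask(Volume):
    """A binary mask on the same lattice as its companion Volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.array
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:8]}")
        self.array = arr.astype(np.uint8)

    @property
    def volume_ml(self) -> float:
        """Mask volume in millilitres."""
        return float(self.array.sum() * np.prod(self.spacing) / 1000.0)

    def with_array(self, array: np.ndarray) -> "LabelMask":
        return LabelMask(array, self.spacing, self.origin)


def require_same_lattice(a: Volume, b: Volume, what: str = "inputs") -> None:
    if not a.same_lattice(b):
        raise GridError(
            f"{what} must share a lattice: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )
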