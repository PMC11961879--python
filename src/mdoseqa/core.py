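"""Core volumetric containers shared by every mdoseqa module.

Axis convention
---------------
All volumes are stored as numpy arrays indexed ``(z, y, x)`` — slice first,
then row, then column — with ``spacing`` and ``origin`` given in the same
order, in millimetres.  ``origin`` is the physical coordinate of the *center*
of voxel ``(0, 0, 0)``.  Only axis-aligned geometry (identity direction
cosines) is supported; oblique volumes are rejected at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

AXIS_ORDER = "zyx"

__all__ = ["VolumeGrid", "StructureSet", "PatientCase", "AXIS_ORDER"]


@dataclass
class VolumeGrid:
    """A 3D scalar field with physical geometry.

    Carrier for CT volumes (Hounsfield units) and dose volumes (Gy).

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values.  Must be finite.
    spacing : tuple of 3 floats
        Voxel spacing in mm, ``(z, y, x)`` order; all positive.
    origin : tuple of 3 floats
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    axis_order : str
        Convention tag; always ``"zyx"``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.axis_order != AXIS_ORDER:
            raise ValueError(f"unsupported axis order {self.axis_order!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert (N, 3) physical points (z, y, x mm) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy_with(self, data: np.ndarray) -> "VolumeGrid":
        """New volume with the same geometry and different values."""
        return VolumeGrid(np.asarray(data), self.spacing, self.origin)

    def require_same_geometry(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"{what} are on different grids: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )


def _normalize_name(name: str) -> str:
    return name.strip().lower()


class StructureSet:
    """Named boolean masks sharing one grid geometry.

    Lookup is case-insensitive; the originally supplied spelling is kept for
    reports (e.g. ``PTV7000``, ``Parotid_L``).
    """

    def __init__(self, grid: VolumeGrid, masks: Mapping[str, np.ndarray] | None = None):
        self.grid = grid
        self._masks: Dict[str, np.ndarray] = {}
        self._display: Dict[str, str] = {}
        if masks:
            for name, mask in masks.items():
                self.add(name, mask)

    def add(self, name: str, mask: np.ndarray) -> None:
        key = _normalize_name(name)
        mask = np.asarray(mask)
        if mask.shape != self.grid.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} != grid shape {self.grid.shape}"
            )
        if mask.dtype != bool:
            mask = mask.astype(bool)
        if key in self._masks:
            raise ValueError(f"duplicate structure name {name!r}")
        self._masks[key] = mask
        self._display[key] = name

    def __getitem__(self, name: str) -> np.ndarray:
        return self._masks[_normalize_name(name)]

    def __contains__(self, name: str) -> bool:
        return _normalize_name(name) in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._display.values())

    def __len__(self) -> int:
        return len(self._masks)

    def names(self) -> list:
        return list(self._display.values())

    def items(self):
        for key, mask in self._masks.items():
            yield self._display[key], mask


@dataclass
class PatientCase:
    """One training / evaluation unit.

    ``mdose`` (the measurement-reconstructed ground-truth dose) is optional:
    prediction-only cases carry CT and planned dose alone.
    """

    case_id: str
    ct: VolumeGrid
    rtdose: VolumeGrid
    structures: StructureSet
    prescription_dose: float
    mdose: VolumeGrid | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        self.ct.require_same_geometry(self.rtdose, "CT and RTDose")
        if self.mdose is not None:
            self.ct.require_same_geometry(self.mdose, "CT and MDose")
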