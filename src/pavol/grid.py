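"""Metric voxel grids for volumetric photoacoustic imaging.

Axis convention used throughout the package: ``(axial, lateral, elevation)``.
Axial points away from the transducer face, lateral runs along the array's
128-element aperture, and elevation is the mechanical scan direction of the
linear array. Depth below the transducer face is ``standoff_mm`` plus the
local axial coordinate, so the first axial voxel sits at the reconstruction
standoff (30 mm by default, matching a water-coupled scanning head).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular metric voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (axial, lateral, elevation).
    spacing_mm
        Voxel edge length per axis in mm. A scalar is broadcast to all
        three axes. Default 0.1 mm (isotropic).
    standoff_mm
        Distance from the transducer face to the first axial voxel plane.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (0.1, 0.1, 0.1)
    standoff_mm: float = 30.0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in np.atleast_1d(self.shape))
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape!r}")
        sp = np.atleast_1d(np.asarray(self.spacing_mm, dtype=float))
        if sp.size == 1:
            sp = np.repeat(sp, 3)
        if sp.size != 3 or np.any(sp <= 0):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm!r}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in sp))
        if self.standoff_mm < 0:
            raise ValueError("standoff_mm must be non-negative")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths (axial, lateral, elevation) in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis, in local mm.

        Local coordinates start at the grid origin; add ``standoff_mm`` to
        the axial coordinate to obtain depth below the transducer face.
        """
        n = self.shape[axis]
        s = self.spacing_mm[axis]
        return (np.arange(n) + 0.5) * s

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing_mm": list(self.spacing_mm),
            "standoff_mm": self.standoff_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGrid":
        return cls(
            shape=tuple(d["shape"]),
            spacing_mm=tuple(d["spacing_mm"]),
            standoff_mm=float(d.get("standoff_mm", 30.0)),
        )
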