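"""Voxel-grid geometry, binary masks, and voxel-face surfaces.

All geometry is axis-aligned and cell-centered: the world position of voxel
index ``(i, j, k)`` is ``origin + index * spacing``, in millimetres.
Anisotropic spacing is supported (planning CTs commonly have 3 mm slices).
Surfaces are represented as the set of voxel faces separating foreground from
background (the grid exterior counts as background), each face carrying its
center point and area — the representation every distance-based metric in
this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "SurfaceElementSet",
    "grids_compatible",
    "mask_volume",
    "extract_surface",
    "EmptyMaskError",
]

#: geometric comparison tolerance, mm
GEOM_ATOL = 1e-6


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice shared by all contours of one planning CT.

    Parameters
    ----------
    origin : world coordinate (mm) of the center of voxel (0, 0, 0).
    spacing : per-axis voxel edge length in mm; strictly positive.
    shape : voxel counts per axis; strictly positive.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("VoxelGrid is strictly three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(n) <= 0 or int(n) != n for n in self.shape):
            raise ValueError(f"shape must be strictly positive integers, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world points (mm)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def isclose(self, other: "VoxelGrid", atol: float = GEOM_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol, rtol=0.0)
            and np.allclose(self.spacing, other.spacing, atol=atol, rtol=0.0)
        )


@dataclass
class BinaryMask:
    """One observer's delineation rasterized on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray
    mask_id: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid shape {self.grid.shape}"
            )
        self.occupancy = occ.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    @property
    def volume(self) -> float:
        """Delineated volume in mm³."""
        return self.voxel_count * self.grid.voxel_volume


@dataclass
class SurfaceElementSet:
    """Boundary faces of a mask: face-center points (mm) and areas (mm²)."""

    centers: np.ndarray
    areas: np.ndarray
    source_mask_id: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.areas = np.asarray(self.areas, dtype=float).reshape(-1)
        if len(self.centers) != len(self.areas):
            raise ValueError("centers and areas must have equal length")
        if len(self.areas) and not (self.areas > 0).all():
            raise ValueError("all face areas must be strictly positive")

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def grids_compatible(a: BinaryMask, b: BinaryMask, atol: float = GEOM_ATOL) -> bool:
    """True iff the two masks share origin, spacing and shape within ``atol`` mm."""
    return a.grid.isclose(b.grid, atol=atol)


def mask_volume(m: BinaryMask) -> float:
    """Volume of the delineation in mm³ (voxel count × voxel volume)."""
    return m.volume


def extract_surface(m: BinaryMask) -> SurfaceElementSet:
    """Extract the voxel-face surface of a mask.

    One element per voxel face separating a foreground voxel from a background
    voxel or the grid exterior, so masks touching the grid edge still have
    closed surfaces. Each element's center is the face center in world
    coordinates and its area the product of the two in-plane spacings.

    Raises
    ------
    EmptyMaskError
        If the mask contains no foreground voxel (its surface is undefined).
    """
    if m.is_empty:
        raise EmptyMaskError(f"surface of empty mask {m.mask_id!r} is undefined")

    occ = m.occupancy
    spacing = np.asarray(m.grid.spacing)
    centers_parts: list[np.ndarray] = []
    areas_parts: list[np.ndarray] = []

    # exterior-padded occupancy: faces against the grid edge are exposed
    padded = np.pad(occ, 1, mode="constant", constant_values=False)
    for axis in range(3):
        in_plane = [ax for ax in range(3) if ax != axis]
        face_area = spacing[in_plane[0]] * spacing[in_plane[1]]
        for direction in (-1, +1):
            neighbor = np.roll(padded, -direction, axis=axis)
            exposed = padded & ~neighbor
            idx = np.argwhere(exposed) - 1  # un-pad
            if len(idx) == 0:
                continue
            # face center sits half a spacing from the voxel center
            pts = m.grid.world_coordinates(idx)
            pts[:, axis] += direction * 0.5 * spacing[axis]
            centers_parts.append(pts)
            areas_parts.append(np.full(len(idx), face_area))

    centers = np.concatenate(centers_parts, axis=0)
    areas = np.concatenate(areas_parts, axis=0)
    return SurfaceElementSet(centers=centers, areas=areas, source_mask_id=m.mask_id)
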