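"""Consensus ("median" and "total") contours from a set of observer masks.

The median contour of an observer group is the strict-majority vote: a voxel
belongs to the consensus iff more than 50 % of the observers marked it, so
with eight observers exactly four votes is *not* enough. The total contour is
the plain union — every voxel marked by at least one observer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import BinaryMask, VoxelGrid

__all__ = [
    "ObserverSet",
    "GridMismatchError",
    "agreement_fraction_map",
    "majority_contour",
    "union_contour",
]


class GridMismatchError(ValueError):
    """Raised when observer masks do not share one voxel grid."""


@dataclass
class ObserverSet:
    """The delineations of one observer group for one case.

    All masks must live on one shared grid; observer ids must be unique.
    ``group`` is conventionally one of ``RAD``, ``GTV-``, ``GTV+``.
    """

    masks: list[BinaryMask]
    observer_ids: list[str]
    group: str = ""

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("an ObserverSet needs at least one mask")
        if len(self.observer_ids) != len(self.masks):
            raise ValueError("one observer id per mask required")
        if len(set(self.observer_ids)) != len(self.observer_ids):
            raise ValueError("observer ids must be unique")
        ref = self.masks[0].grid
        for m in self.masks[1:]:
            if not ref.isclose(m.grid):
                raise GridMismatchError(
                    f"mask {m.mask_id!r} is not on the shared grid of group {self.group!r}"
                )

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def grid(self) -> VoxelGrid:
        return self.masks[0].grid


def agreement_fraction_map(s: ObserverSet) -> np.ndarray:
    """Per-voxel fraction of observers marking the voxel, in [0, 1]."""
    votes = np.zeros(s.grid.shape, dtype=np.int32)
    for m in s.masks:
        votes += m.occupancy
    return votes / float(len(s))


def majority_contour(s: ObserverSet, warn_if_empty: bool = True) -> BinaryMask:
    """Strict-majority (median) contour: voxels marked by > 50 % of observers.

    The inequality is strict, so an even split (e.g. 4 of 8) excludes the
    voxel. A legitimately empty result — possible with highly discordant
    observers — is returned with a warning rather than an error; metrics
    against an empty reference fail loudly downstream.
    """
    occ = agreement_fraction_map(s) > 0.5
    mask = BinaryMask(grid=s.grid, occupancy=occ, mask_id=f"median[{s.group}]")
    if warn_if_empty and mask.is_empty:
        warnings.warn(
            f"majority contour of group {s.group!r} is empty "
            f"({len(s)} observers, none agreeing above 50 %)",
            stacklevel=2,
        )
    return mask


def union_contour(s: ObserverSet) -> BinaryMask:
    """Total contour: voxels marked by at least one observer."""
    occ = np.zeros(s.grid.shape, dtype=bool)
    for m in s.masks:
        occ |= m.occupancy
    return BinaryMask(grid=s.grid, occupancy=occ, mask_id=f"union[{s.group}]")
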