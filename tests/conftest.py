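"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's accelerated code paths:
surface extraction by explicit neighbour loops, nearest distances by O(n²)
pairwise minima, consensus by per-voxel vote counting, and Mann-Whitney p
by exhaustive enumeration of rank assignments.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from contour_iov import BinaryMask, VoxelGrid

ISO_1MM = VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), shape=(10, 10, 10))


@pytest.fixture
def iso_grid():
    return ISO_1MM


def random_mask(grid: VoxelGrid, seed: int, p: float = 0.3, nonempty: bool = True) -> BinaryMask:
    rng = np.random.default_rng(seed)
    occ = rng.random(grid.shape) < p
    if nonempty and not occ.any():
        occ[tuple(d // 2 for d in grid.shape)] = True
    return BinaryMask(grid=grid, occupancy=occ, mask_id=f"rand{seed}")


def sphere_mask(grid: VoxelGrid, radius_mm: float, center_mm=None) -> BinaryMask:
    if center_mm is None:
        center_mm = np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) / 2 * np.asarray(
            grid.spacing
        )
    axes = [grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    occ = (
        (xx - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2 + (zz - center_mm[2]) ** 2
    ) <= radius_mm**2
    return BinaryMask(grid=grid, occupancy=occ)


# --- oracles -------------------------------------------------------------


def brute_force_surface(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate exposed voxel faces by explicit neighbour checks.

    Returns (centers, areas) in world mm / mm², unordered.
    """
    occ = mask.occupancy
    spacing = np.asarray(mask.grid.spacing)
    origin = np.asarray(mask.grid.origin)
    centers, areas = [], []
    for i, j, k in np.argwhere(occ):
        for axis, direction in [(a, d) for a in range(3) for d in (-1, 1)]:
            n = [i, j, k]
            n[axis] += direction
            outside = not (0 <= n[axis] < occ.shape[axis])
            if outside or not occ[tuple(n)]:
                c = origin + np.array([i, j, k]) * spacing
                c[axis] += direction * spacing[axis] / 2
                in_plane = [a for a in range(3) if a != axis]
                centers.append(c)
                areas.append(spacing[in_plane[0]] * spacing[in_plane[1]])
    return np.asarray(centers, dtype=float).reshape(-1, 3), np.asarray(areas, dtype=float)


def brute_force_nearest(from_pts: np.ndarray, to_pts: np.ndarray) -> np.ndarray:
    """O(n²) exhaustive nearest-distance computation."""
    diff = from_pts[:, None, :] - to_pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def vote_oracle(masks: list[BinaryMask], threshold_count: int) -> np.ndarray:
    """Per-voxel counting oracle: occupancy where votes >= threshold_count."""
    votes = np.zeros(masks[0].grid.shape, dtype=int)
    for m in masks:
        votes += m.occupancy.astype(int)
    return votes >= threshold_count


def exact_mwu_p(x, y) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration (tie-free samples)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)

    def u_of(rank_subset):
        r1 = sum(rank_subset)
        return r1 - n1 * (n1 + 1) / 2

    observed = u_of([ranks[v] for v in x])
    mean_u = n1 * n2 / 2
    us = [u_of(c) for c in combinations(range(1, n1 + n2 + 1), n1)]
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12)
    return extreme / len(us)
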