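"""Agreement metrics between an observer contour and a reference contour.

Four complementary measures of interobserver variation:

* **DSC** — Dice similarity coefficient, ``2|A∩B| / (|A|+|B|)`` on voxel
  counts; a volume-overlap measure, heavily influenced by structure volume.
* **SDSC** — surface Dice at a distance tolerance τ (default 3 mm): the
  area fraction of the two surfaces lying within τ of each other.
* **HD98** — the 98th percentile of all smallest distances from each surface
  element of the observer's contour to the reference surface; a
  directed, outlier-robust variant of the Hausdorff distance.
* **MDA** — mean (with SD) of those same nearest-surface distances.

All distances are Euclidean in world millimetres between voxel-face centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .consensus import GridMismatchError, ObserverSet, majority_contour
from .grids import BinaryMask, EmptyMaskError, SurfaceElementSet, extract_surface, grids_compatible
from .study import CaseStudy

__all__ = [
    "ToleranceConfig",
    "MetricRecord",
    "nearest_surface_distances",
    "dice",
    "surface_dice",
    "directed_percentile_hd",
    "mean_distance_to_agreement",
    "compute_mask_metrics",
    "compute_case_metrics",
]


@dataclass(frozen=True)
class ToleranceConfig:
    """Metric conventions: SDSC tolerance (mm) and Hausdorff percentile (%)."""

    sdsc_tolerance: float = 3.0
    hd_percentile: float = 98.0

    def __post_init__(self) -> None:
        if self.sdsc_tolerance < 0:
            raise ValueError("sdsc_tolerance must be >= 0")
        if not (0 < self.hd_percentile <= 100):
            raise ValueError("hd_percentile must lie in (0, 100]")


@dataclass
class MetricRecord:
    """One observer-vs-reference evaluation."""

    case_id: str
    observer_id: str
    group: str
    dsc: float
    sdsc: float
    hd98: float
    mda_mean: float
    mda_sd: float
    observer_volume: float
    reference_volume: float


def nearest_surface_distances(
    from_surface: SurfaceElementSet, to_surface: SurfaceElementSet
) -> np.ndarray:
    """Smallest distance (mm) from each element of ``from_surface`` to ``to_surface``.

    Exact nearest-neighbour search over face centers via a k-d tree.
    """
    if len(from_surface) == 0 or len(to_surface) == 0:
        raise EmptyMaskError("surface distances are undefined for an empty surface")
    tree = cKDTree(to_surface.centers)
    d, _ = tree.query(from_surface.centers, k=1)
    return np.asarray(d, dtype=float)


def _require_compatible(a: BinaryMask, b: BinaryMask) -> None:
    if not grids_compatible(a, b):
        raise GridMismatchError(
            f"masks {a.mask_id!r} and {b.mask_id!r} are not on the same grid"
        )


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient on voxel counts; undefined for two empty masks."""
    _require_compatible(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise EmptyMaskError("Dice of two empty masks is undefined")
    inter = int((a.occupancy & b.occupancy).sum())
    return 2.0 * inter / (na + nb)


def surface_dice(a: BinaryMask, b: BinaryMask, cfg: ToleranceConfig = ToleranceConfig()) -> float:
    """Surface Dice at tolerance: area-weighted, symmetric, in [0, 1].

    An element agrees when its nearest distance to the other surface is
    ``<=`` the tolerance (distances exactly at tolerance count as agreeing).
    On isotropic grids the area weighting reduces to face counting.
    """
    _require_compatible(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    d_ab = nearest_surface_distances(sa, sb)
    d_ba = nearest_surface_distances(sb, sa)
    tol = cfg.sdsc_tolerance
    agreeing = sa.areas[d_ab <= tol].sum() + sb.areas[d_ba <= tol].sum()
    return float(agreeing / (sa.total_area + sb.total_area))


def directed_percentile_hd(
    observer: BinaryMask,
    reference: BinaryMask,
    cfg: ToleranceConfig = ToleranceConfig(),
    symmetric: bool = False,
) -> float:
    """Percentile Hausdorff distance (mm), directed observer → reference.

    The ``cfg.hd_percentile``-th percentile (linear interpolation between
    order statistics) of the nearest-surface distances from the observer's
    surface to the reference surface; at percentile 100 this is the directed
    Hausdorff maximum. ``symmetric=True`` returns the larger of the two
    directed values (not the default convention here).
    """
    _require_compatible(observer, reference)
    so, sr = extract_surface(observer), extract_surface(reference)
    fwd = float(np.percentile(nearest_surface_distances(so, sr), cfg.hd_percentile))
    if not symmetric:
        return fwd
    bwd = float(np.percentile(nearest_surface_distances(sr, so), cfg.hd_percentile))
    return max(fwd, bwd)


def mean_distance_to_agreement(
    observer: BinaryMask, reference: BinaryMask
) -> tuple[float, float]:
    """Mean and population SD (mm) of observer→reference nearest-surface distances."""
    _require_compatible(observer, reference)
    d = nearest_surface_distances(extract_surface(observer), extract_surface(reference))
    return float(d.mean()), float(d.std())  # population SD (divisor n)


def compute_mask_metrics(
    observer: BinaryMask,
    reference: BinaryMask,
    cfg: ToleranceConfig = ToleranceConfig(),
    case_id: str = "",
    observer_id: str = "",
    group: str = "",
) -> MetricRecord:
    """All four agreement metrics of one observer mask against a reference."""
    mda_mean, mda_sd = mean_distance_to_agreement(observer, reference)
    return MetricRecord(
        case_id=case_id,
        observer_id=observer_id,
        group=group,
        dsc=dice(observer, reference),
        sdsc=surface_dice(observer, reference, cfg),
        hd98=directed_percentile_hd(observer, reference, cfg),
        mda_mean=mda_mean,
        mda_sd=mda_sd,
        observer_volume=observer.volume,
        reference_volume=reference.volume,
    )


def compute_case_metrics(
    case: CaseStudy,
    cfg: ToleranceConfig = ToleranceConfig(),
    reference_rule: str = "group_median",
    leave_one_out: bool = False,
) -> list[MetricRecord]:
    """Evaluate every observer contour against its own group's median contour.

    Each group's consensus is the strict-majority contour over all returned
    contours of that group for the case; by default an observer's own contour
    participates in the median it is compared against (leave-one-in).
    ``leave_one_out=True`` recomputes the median without the observer under
    evaluation — offered as an alternative convention, not the default.

    Raises
    ------
    EmptyMaskError
        If a group's majority reference is empty, naming the group and case.
    """
    if reference_rule != "group_median":
        raise ValueError(f"unknown reference rule {reference_rule!r}")
    records: list[MetricRecord] = []
    for label, obs in case.groups.items():
        reference = majority_contour(obs, warn_if_empty=False)
        if reference.is_empty and not leave_one_out:
            raise EmptyMaskError(
                f"majority reference of group {label!r} in case {case.case_id!r} is empty"
            )
        for i, (mask, oid) in enumerate(zip(obs.masks, obs.observer_ids)):
            if leave_one_out and len(obs) > 1:
                others = ObserverSet(
                    masks=[m for j, m in enumerate(obs.masks) if j != i],
                    observer_ids=[o for j, o in enumerate(obs.observer_ids) if j != i],
                    group=label,
                )
                ref_i = majority_contour(others, warn_if_empty=False)
            else:
                ref_i = reference
            if ref_i.is_empty:
                raise EmptyMaskError(
                    f"majority reference of group {label!r} in case {case.case_id!r} is empty"
                )
            records.append(
                compute_mask_metrics(
                    mask, ref_i, cfg, case_id=case.case_id, observer_id=oid, group=label
                )
            )
    return records
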