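"""Reading and writing delineations and study manifests.

Masks are exchanged as NIfTI (values > 0.5 are foreground) or as DICOM
RT-STRUCT planar contours rasterized onto a reference grid by the even-odd
rule at voxel centers. Only axis-aligned grids are supported: the analysis
compares contours drawn on one planning CT, so a shared axis-aligned frame
is the operative case, and oblique orientations are rejected at load time.

A study manifest is a JSON file listing, per case, its id, subtype tags and
per-observer entries (observer id, group, mask path), plus the grid
geometry and a config echo.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .consensus import ObserverSet
from .grids import GEOM_ATOL, BinaryMask, VoxelGrid
from .study import GROUPS, CaseStudy

__all__ = [
    "ObliqueGridError",
    "GeometryMismatchError",
    "read_nifti_mask",
    "write_nifti_mask",
    "read_structure_set",
    "points_in_polygon_evenodd",
    "rasterize_planar_contours",
    "write_study",
    "read_manifest",
]

logger = logging.getLogger(__name__)


class ObliqueGridError(ValueError):
    """The file's orientation is not axis-aligned."""


class GeometryMismatchError(ValueError):
    """The file's geometry differs from the reference grid beyond tolerance."""


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-4:
        raise ObliqueGridError("oblique/rotated grid orientations are not supported")
    spacing = np.abs(np.diag(rot))
    origin = affine[:3, 3].copy()
    # normalize negative axis directions to a positive-spacing convention
    for ax in range(3):
        if rot[ax, ax] < 0:
            origin[ax] = origin[ax] + rot[ax, ax] * (shape[ax] - 1)
    return VoxelGrid(origin=tuple(origin), spacing=tuple(spacing), shape=tuple(shape[:3]))


def read_nifti_mask(path, reference_grid: VoxelGrid | None = None) -> BinaryMask:
    """Load a NIfTI mask; values > 0.5 are foreground.

    If ``reference_grid`` is given, the file's geometry must match it within
    tolerance. An all-zero file loads as an (empty) mask with a warning.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape)
    if reference_grid is not None and not grid.isclose(reference_grid, atol=1e-3):
        raise GeometryMismatchError(
            f"{path}: geometry {grid} does not match reference {reference_grid}"
        )
    occ = data > 0.5
    mask = BinaryMask(grid=reference_grid or grid, occupancy=occ, mask_id=Path(path).name)
    if mask.is_empty:
        warnings.warn(f"{path}: mask is empty", stacklevel=2)
    return mask


def write_nifti_mask(mask: BinaryMask, path) -> None:
    """Write a mask as uint8 NIfTI with a diagonal affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.grid.spacing)
    affine[:3, 3] = mask.grid.origin
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    nib.save(img, str(path))


def points_in_polygon_evenodd(
    points: np.ndarray, polygon: np.ndarray, include_boundary: bool = True
) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test, vectorized over points.

    Points exactly on a polygon edge count as inside when
    ``include_boundary`` (the foreground rule used for rasterization;
    affects only a measure-zero set in practice).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    poly = np.asarray(polygon, dtype=float).reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        if crosses.any():
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1 + np.where(crosses, 0.0, 1.0))
            inside ^= crosses & (x < xint)
        if include_boundary:
            dx, dy = x2 - x1, y2 - y1
            seg2 = dx * dx + dy * dy
            if seg2 == 0:
                d2 = (x - x1) ** 2 + (y - y1) ** 2
            else:
                t = np.clip(((x - x1) * dx + (y - y1) * dy) / seg2, 0.0, 1.0)
                d2 = (x - (x1 + t * dx)) ** 2 + (y - (y1 + t * dy)) ** 2
            on_edge |= d2 <= 1e-12
    return inside | on_edge


def rasterize_planar_contours(
    contours: list[np.ndarray], grid: VoxelGrid, z_tolerance: float | None = None
) -> BinaryMask:
    """Rasterize closed planar (axial) polygons onto a grid.

    Each contour is an (n, 3) array of world points (mm) lying on one axial
    plane. Polygons on the same slice are combined by the even-odd rule
    (XOR), so a polygon inside another cuts a hole.
    """
    if z_tolerance is None:
        z_tolerance = grid.spacing[2] / 2 + GEOM_ATOL
    occ = np.zeros(grid.shape, dtype=bool)
    xs = grid.origin[0] + np.arange(grid.shape[0]) * grid.spacing[0]
    ys = grid.origin[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    for poly in contours:
        poly = np.asarray(poly, dtype=float).reshape(-1, 3)
        z = poly[:, 2]
        if np.ptp(z) > 1e-3:
            raise ValueError("contour is not planar in z")
        k = (z.mean() - grid.origin[2]) / grid.spacing[2]
        ki = int(round(k))
        if not (0 <= ki < grid.shape[2]) or abs(k - ki) * grid.spacing[2] > z_tolerance:
            raise GeometryMismatchError(
                f"contour plane z={z.mean():.2f} mm does not land on a grid slice"
            )
        inside = points_in_polygon_evenodd(centers, poly[:, :2]).reshape(
            grid.shape[0], grid.shape[1]
        )
        occ[:, :, ki] ^= inside
    return BinaryMask(grid=grid, occupancy=occ)


def read_structure_set(
    path, reference_grid: VoxelGrid, roi_name: str | None = None
) -> BinaryMask:
    """Read a delineation from NIfTI or DICOM RT-STRUCT onto a reference grid.

    For RT-STRUCT, the (first, or named) ROI's CLOSED_PLANAR contours are
    rasterized slice-wise by the even-odd rule at voxel centers.
    """
    p = Path(path)
    if p.suffix in (".nii", ".gz") or p.name.endswith(".nii.gz"):
        return read_nifti_mask(p, reference_grid)
    try:
        ds = pydicom.dcmread(str(p))
    except Exception as exc:  # noqa: BLE001 - normalize into one error type
        raise ValueError(f"{path}: unreadable as NIfTI or DICOM ({exc})") from exc
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ValueError(f"{path}: DICOM file is not an RT structure set")
    roi_numbers = {}
    for roi in ds.StructureSetROISequence:
        roi_numbers[roi.ROIName] = roi.ROINumber
    if roi_name is None:
        roi_name = next(iter(roi_numbers))
    if roi_name not in roi_numbers:
        raise ValueError(f"{path}: ROI {roi_name!r} not found (have {list(roi_numbers)})")
    target = roi_numbers[roi_name]
    polys: list[np.ndarray] = []
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber != target:
            continue
        for item in getattr(rc, "ContourSequence", []):
            if item.ContourGeometricType != "CLOSED_PLANAR":
                continue
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            polys.append(pts)
    if not polys:
        raise ValueError(f"{path}: ROI {roi_name!r} has no closed planar contours")
    mask = rasterize_planar_contours(polys, reference_grid)
    mask.mask_id = f"{p.name}:{roi_name}"
    return mask


def _grid_to_json(grid: VoxelGrid) -> dict:
    return {"origin": list(grid.origin), "spacing": list(grid.spacing), "shape": list(grid.shape)}


def write_study(cases: list[CaseStudy], out_dir, config: dict | None = None) -> Path:
    """Write a simulated study as NIfTI masks plus a JSON manifest.

    Returns the manifest path. Layout: ``<out>/<case_id>/<observer_id>.nii.gz``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"grid": None, "config": config or {}, "cases": []}
    for case in cases:
        case_dir = out / case.case_id
        case_dir.mkdir(exist_ok=True)
        entry = {"case_id": case.case_id, "subtypes": list(case.subtypes), "observers": []}
        for group, obs in case.groups.items():
            for mask, oid in zip(obs.masks, obs.observer_ids):
                rel = f"{case.case_id}/{oid}.nii.gz"
                write_nifti_mask(mask, out / rel)
                entry["observers"].append({"observer_id": oid, "group": group, "path": rel})
                if manifest["grid"] is None:
                    manifest["grid"] = _grid_to_json(mask.grid)
        manifest["cases"].append(entry)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_manifest(manifest_path) -> list[CaseStudy]:
    """Load a study manifest and its masks into per-case observer sets."""
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    g = manifest["grid"]
    grid = VoxelGrid(origin=tuple(g["origin"]), spacing=tuple(g["spacing"]), shape=tuple(g["shape"]))
    base = mpath.parent
    case_ids = [c["case_id"] for c in manifest["cases"]]
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("manifest contains duplicate case ids")
    cases: list[CaseStudy] = []
    for c in manifest["cases"]:
        by_group: dict[str, tuple[list, list]] = {}
        for o in c["observers"]:
            if o["group"] not in GROUPS:
                raise ValueError(
                    f"case {c['case_id']}: unknown group {o['group']!r} (expected one of {GROUPS})"
                )
            mask = read_structure_set(base / o["path"], grid)
            masks, ids = by_group.setdefault(o["group"], ([], []))
            masks.append(mask)
            ids.append(o["observer_id"])
        groups = {
            g_: ObserverSet(masks=m, observer_ids=i, group=g_)
            for g_, (m, i) in by_group.items()
        }
        logger.info(
            "case %s: %s", c["case_id"],
            ", ".join(f"{g_}={len(s)}" for g_, s in groups.items()),
        )
        cases.append(
            CaseStudy(case_id=c["case_id"], groups=groups, subtypes=tuple(c.get("subtypes", ())))
        )
    return cases
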