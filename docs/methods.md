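# Methods

## Problem

When several observers delineate the same gross tumour volume (GTV) on a
planning CT — radiologists and radiation oncologists contouring a pelvic
recurrence, say — their contours disagree. This package quantifies that
interobserver variation (IOV), builds group consensus contours, and compares
observer groups statistically. The central comparison is between two
radiation-oncologist arms: one contouring without (GTV−) and one with (GTV+)
access to a radiologists' consensus contour.

## Geometry and surfaces

All contours live on one shared, axis-aligned voxel grid (the planning-CT
lattice), cell-centered: the world position of voxel index *i* is
`origin + i · spacing`, in mm. Anisotropic spacing is supported; the default
synthetic geometry is 1 × 1 × 3 mm, the common planning-CT slice thickness.
Oblique orientations are rejected at load time — the analysis compares
contours drawn on a single CT, so a shared axis-aligned frame is the
operative case.

A mask's surface is the set of voxel faces separating foreground from
background (grid exterior counts as background, so masks touching the edge
still have closed surfaces). Each face contributes its center point and its
area (product of the two in-plane spacings). This voxel-face representation
was chosen over marching-cubes meshes because the consensus contour is
voxel-defined, so surfaces stay exactly consistent with the masks, and
because an exact brute-force oracle (explicit face enumeration) exists for
testing. Commercial treatment-planning systems may measure on meshes
instead; the difference is a sub-voxel discretization effect of unknown but
bounded magnitude.

## Consensus

The *median* contour of a group is the strict-majority vote: a voxel is
consensus iff **more than** 50 % of the group's observers marked it. The
inequality is strict, so with 8 observers an even 4/4 split excludes the
voxel. The *total* contour is the union over observers. An observer is
compared against the median of their **own** group computed from **all** of
that group's contours (leave-one-in); a leave-one-out option exists but is
not the default, since nothing indicates the reference analyses excluded
the observer under evaluation. A legitimately empty median (highly
discordant observers) is surfaced as a warning; metrics against an empty
reference raise an error rather than emit silent NaNs.

## Metrics

For observer mask *A* and reference *B*, with surface element sets
S(A), S(B) and the nearest-surface distance d(x, S) measured in Euclidean mm
between face centers:

* **DSC** = 2|A∩B| / (|A|+|B|) on voxel counts. Undefined (error) when both
  masks are empty.
* **SDSC(τ)** — surface Dice at tolerance τ (default 3 mm): the area of
  elements of S(A) within τ of S(B), plus the area of elements of S(B)
  within τ of S(A), divided by the total area of both surfaces. Distances
  exactly at τ count as agreeing (≤). Area-weighted; on isotropic grids this
  reduces to face counting. Symmetric, in [0, 1], non-decreasing in τ.
* **HD98** — the 98th percentile (linear interpolation between order
  statistics, unweighted per-element distances) of {d(x, S(B)) : x ∈ S(A)}.
  Directed observer→reference by definition; a symmetric max-of-both
  variant is available behind a flag. At percentile 100 this is the directed
  Hausdorff maximum.
* **MDA** — mean and **population** SD (divisor *n*) of the same directed
  nearest-surface distances.

Nearest distances are computed exactly over face centers with a k-d tree;
the test suite checks equality with an O(n²) brute-force scan to 10⁻⁶ mm.
Measuring between face centers (not point-to-face) introduces at most a
half-voxel bias, identical in implementation and oracle.

## Categories, relevance thresholds, statistics

Per-metric variation categories: DSC/SDSC < 0.6 large, 0.6 ≤ v < 0.8
average, ≥ 0.8 little; HD98 < 10 mm little, 10–20 mm average, ≥ 20 mm
large. Group differences are median(GTV+) − median(GTV−); a change is
*relevant* only when its magnitude strictly exceeds ±0.1 (DSC/SDSC) or
±3 mm (HD98) — values exactly at the threshold are "no relevant
difference" (the tie semantics are not externally fixed; exclusive
thresholds are this package's documented choice). The improvement direction
(higher is better for DSC/SDSC, lower for HD98) is encoded once, centrally.
A case shows *consistent* improvement (deterioration) iff all three metrics
are relevant improvements (deteriorations).

Group summaries are median with IQR as the 25th/75th percentiles (linear
interpolation — the convention is stated in the report metadata) and range.
Arms are compared per-contour with the two-sided Mann-Whitney U test
(midranks for ties; exact enumeration for tie-free pooled n ≤ 20, otherwise
normal approximation with tie and continuity correction), significance at
α ≤ 0.05, raw p-values reported, no multiple-testing correction. The
exclusion analysis removes cases whose radiologist-group per-case medians
are categorized "large" on all three metrics (configurable to any-metric)
and re-runs the pooled comparison.

## Synthetic observer studies

No clinical delineations ship with the package, so the pipeline is
exercised on simulated studies with known truth. A case is a phantom lesion
on the default grid: sphere (lateral/nodal recurrences), ellipsoid
(anastomotic/intraluminal), smoothed-noise blob (fibrotic), or a two-lesion
configuration (multifocal, a primary plus a smaller detached secondary
lesion). The default study has 14 cases with overlapping subtype tags and
observer groups of 8 (RAD), 6 (GTV−) and 6 (GTV+).

An observer contour is produced from the truth by, in order:

1. **secondary-lesion omission** — each detached secondary component is
   retained with probability `second_lesion_inclusion_prob` (radiologists
   default 0.5, emulating lesions read as benign by some observers);
2. **systematic margin** — signed uniform dilation/erosion in mm via the
   signed Euclidean distance transform (radiologists default −2 mm,
   emulating their consistently smaller volumes);
3. **systematic translation** (mm vector, rounded to whole voxels);
4. **coherent boundary noise** — a Gaussian random field smoothed to a
   5 mm correlation length, renormalized to unit SD, scaled by
   `boundary_noise_sd` and added to the signed distance before thresholding
   at zero. This yields spatially smooth over/under-contouring, not voxel
   salt-and-pepper.

Per-case difficulty scales the noise (solitary nodal 0.55 … fibrotic 1.6).
Default noise SDs are 7.0 mm (GTV−), 3.5 mm (GTV+ — half, injecting the
radiological-input benefit purely as a concordance parameter) and 4.5 mm
(RAD); with these, the default study's pooled radiation-oncologist MDA
comes out near 3.8 mm, the scale typical of pelvic-recurrence delineation.
These magnitudes were fixed once by a forward calibration of the generator
and are study conditions, not tuning knobs.

Seeding: every observer's seed is derived as
`SeedSequence(master_seed, spawn_key=(case_index, group_index, observer_index))`
reduced to one uint32, so any single observer is regenerable in isolation
and the whole study is a pure function of its spec.

What the generator does **not** emulate: anatomical pelvic context and image
appearance, per-case variation in how many observers return contours
(counts are fixed at 8/6/6; 12 RO returns per case sits inside the 9–12
range typical of such exercises), reader-specific styles or learning
effects, and the mechanism of radiological-input exposure itself. Passing
tests therefore demonstrate correctness of the metrics, consensus,
categorization and comparison machinery under controlled conditions — not
that any clinical effect size is reproduced.

## Numerical choices and degenerate inputs

* Grid equality tolerance 10⁻⁶ mm; NIfTI loaded as foreground where
  value > 0.5; RT-STRUCT polygons rasterized slice-wise by the even-odd
  rule at voxel centers, with centers exactly on an edge counted inside
  (measure-zero in practice).
* Empty masks: surface, SDSC, HD, MDA raise; DSC raises only when both
  masks are empty (one empty mask gives DSC 0).
* Mann-Whitney with all observations identical returns p = 1 (no
  separation; the tie-corrected normal variance degenerates to 0).
* Problem sizes: tests and the acceptance script run phantoms on grids of
  about 64³ voxels at 1 mm (metric checks) and 72 × 72 × 36 at 1 × 1 × 3 mm
  (the 14-case study), sizes at which sphere rasterization error stays
  within the stated analytic tolerances while the full study completes in
  well under a minute.

## Known limitations

Surface distances are face-center-to-face-center (half-voxel bias); the
percentile convention (linear interpolation) and the directed HD98 are
explicit choices among several in field use; consensus is leave-one-in; the
generator's noise model is isotropic in the field sense and knows nothing
of anatomy. All of these are stated in the report metadata so results are
self-describing.
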