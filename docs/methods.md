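# Methods

## Measurement model

`ctsubvol` measures two quantities on a CT series: the volume of a
polygon-bounded region and the sub-volume of voxels within a closed
Hounsfield-unit (HU) interval. The model is deliberately the simplest
one consistent with per-pixel counting:

1. **Calibration.** Stored pixel values are mapped to HU by the DICOM
   affine rescale, `HU = stored · slope + intercept`, kept as floats
   with no rounding or clipping so that comparisons at interval
   endpoints are exact.
2. **Region membership.** A voxel belongs to the region iff its centre
   lies inside one of the slice's polygons under the even–odd rule.
   Polygons on one slice are OR-combined; there are no holes or
   subtractive ROIs. Pixel centres exactly on an edge are resolved by
   shifting every test point by (+ε, +ε), ε = 2⁻²⁰ px — an arbitrary
   but fixed and platform-independent tie-break that changes counts
   only on a measure-zero set of polygons.
3. **Thresholding.** A region voxel is in the sub-volume iff
   `lo ≤ HU ≤ hi`, both ends inclusive. The default [−150, −50] HU is
   the conventional CT attenuation range for adipose tissue. Closed
   endpoints are the only symmetric reading of a range stated as
   "−150 to −50"; the choice is pinned by unit tests.
4. **Integration.** Counts are multiplied by the voxel volume
   `p_r · p_c · d`. The per-slice depth `d` is the reconstruction
   increment (median centre-to-centre slice distance) by default.
   Clinical protocols often reconstruct overlapping slices — the
   emulated geometry is 1.25 mm thickness at a 1 mm increment — and
   summing thickness over overlapping slices would overcount by the
   overlap fraction (25 % here). Because source descriptions of such
   pipelines rarely state which depth they used, both readings are
   exposed (`depth_mode = increment | thickness`); their outputs differ
   by exactly the thickness/increment ratio.

No partial-volume weighting is applied: a voxel is wholly in or out,
matching the per-pixel decision the workflow digitizes. The fat
percentage is `100 · V_sub / V_total`, defined as 0 when the region
encloses no pixel centre (legal, e.g. a sliver polygon), with a logged
warning rather than an error.

## Series geometry

The stack axis is the patient-coordinate axis with the largest
positional variance across slices — robust to small obliquity, with no
support for gantry tilt or multi-frame objects. Slices are ordered by
position along that axis (ties by `InstanceNumber`), making the result
independent of file naming. The increment is the median absolute gap
between consecutive positions; gaps deviating from the median by more
than 1 % log a warning, a zero gap is an error, and a single-slice
series falls back to the slice thickness. Directories mixing image
dimensions or pixel spacings are rejected outright rather than
partially read.

## ROI representation

ROIs travel as a flat CSV (`slice_index,roi_id,vertex_index,x_px,y_px`)
in pixel coordinates, slice-addressed by sorted position rather than
scanner instance numbering, which is vendor-dependent. Viewer-native
export formats are treated as a pre-conversion step: defining a minimal
dialect makes round-trips bit-exactly testable, which no
reverse-engineered proprietary layout would be. Whether original
exports use pixel or mm patient coordinates varies by tool; this
dialect fixes pixel indices, and mm support (requiring the inverse
orientation transform) is out of scope.

## Statistics

* **Bland–Altman**: differences `a − b`, bias = mean, limits =
  bias ± 1.96·SD with the n−1 denominator — the standard formulation.
  No confidence intervals on the limits and no repeated-measures
  variant.
* **Group comparisons**: Shapiro–Wilk per group at α = 0.05 gates the
  test choice — two normal groups → two-sample t, any non-normal →
  Mann–Whitney U; three or more → ANOVA or Kruskal–Wallis. The gate's
  per-group outcome is recorded in the result, not hidden. A `paired`
  flag (default off) switches two equal-length groups to paired
  t / Wilcoxon signed-rank. Simulation in the test suite checks the
  gated pipeline's type-I error stays near the nominal 5 %.
* **Correlation**: two-tailed Spearman, with the Chan verbal scale on
  |r| (1.0 perfect, ≥ 0.8 very strong, ≥ 0.6 moderate, ≥ 0.3 fair,
  ≥ 0.1 weak, else negligible).
* No multiple-testing correction is applied anywhere — a reproduction
  choice mirroring common practice in method-validation studies, not a
  recommendation.

## Phantom generator

The generator emulates the acquisition geometry of a routine clinical
protocol — axial slices, fixed in-plane spacing, 1.25 mm thickness at
1 mm increment, soft-tissue background of +40 HU — with geometric
inserts (axis-aligned boxes, z-axis cylinders) of known HU and
closed-form volume. Voxels take an insert's HU iff their centre lies
inside it: the same pixel-centre rule the quantifier uses, so the
ground-truth files carry both the analytic volume and an exact
voxelized-at-this-grid count. Stored pixels are written with slope 1 /
intercept −1024 so requested HU are represented exactly; unrepresentable
HU raise an error rather than clip.

Optional Gaussian HU noise (seeded, truncated at ±3 SD) supports
robustness tests: truncation guarantees a +40 HU background cannot
reach the fat range unless `noise_sd ≥ 30` is chosen deliberately, so
exact-count tests stay exact under moderate noise.

Canonical fixtures:

* **box** — 10×10×20 mm at −100 HU, voxel-aligned on a 1 mm grid with
  the ROI square on the box footprint: total and fat volume are exactly
  2.000 cm³ and the percentage 100 %.
* **cylinder** — r = 10 mm, h = 20 mm (π r² h = 6.283 cm³). Its z
  extent covers exactly the 20 slice centres, so discretization error
  is purely in-plane; the axis is shifted 0.1 mm off the grid centre so
  no voxel centre lies exactly on the circle and the lattice-counting
  error decays regularly (≈4× per halving of the pixel spacing over
  2 → 0.25 mm) instead of hitting accidental cancellations on coarse
  grids.
* **background** — no inserts; any fat count is a false positive.

What the phantoms do **not** emulate: anatomy, beam hardening, scanner
noise texture, partial-volume blur at tissue interfaces, or ROI
drawing variability. Passing tests therefore demonstrate that the
counting, calibration, geometry, and bookkeeping are correct — not that
the fat range or binary thresholding are biologically optimal for any
particular joint region.

## Independent oracle

`ctsubvol.oracle` re-implements region membership, thresholding, and
counting with plain per-pixel Python loops and a scalar ray-cast,
sharing no code with the vectorized core. Equivalence tests (hundreds
of random polygons and dozens of random phantoms, including noisy ones)
require *identical* voxel counts, not approximate agreement. Problem
sizes in tests (grids ≤ 64×64, a few slices) keep the quadratic oracle
comfortable while exercising all code paths.

## Numerical choices and edge cases

* All volume arithmetic is double precision; exactness claims in tests
  (box recovery, depth-mode ratio, scaling invariances) hold because
  the involved factors (integer counts, powers of two, 1.25) are
  exactly representable.
* Polygons overhanging the pixel grid are clipped silently (a warning
  is logged): pixels outside the image cannot be counted.
* Degenerate inputs fail loudly: < 3 vertices, repeated consecutive
  vertices (including across the implicit closure), non-finite
  coordinates, reversed HU intervals, an ROI set with no polygons,
  ROI indices beyond the series.
* Zero-area (collinear) polygons rasterize to an empty mask by the
  even–odd rule itself, with no special casing.

## Known limitations

* No multi-frame enhanced CT, compressed transfer syntaxes, gantry
  tilt, or MR support.
* Single global HU interval per run; no per-slice or adaptive ranges.
* Binary voxel classification ignores partial-volume effects at region
  and tissue boundaries; at clinical resolutions this biases small
  structures more than large ones.
* The agreement statistics treat method pairs as unpaired by default in
  `compare_groups`; the Bland–Altman analysis is inherently paired.
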