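"""The computational core: masks, HU thresholding, and volume reports.

The measurement model is deliberately simple and fully pinned down:

* a pixel belongs to the ROI iff its **centre** is inside the polygon
  under the even-odd rule (binary voxels, no partial-volume weighting);
* a pixel belongs to the sub-volume (e.g. fat) iff additionally its HU
  value lies in a **closed** interval, default [-150, -50] HU — the
  conventional adipose-tissue attenuation range;
* volume = voxel count x (pixel_spacing_row x pixel_spacing_col x depth),
  where depth is the reconstruction increment by default.  With 1.25 mm
  thick slices reconstructed every 1 mm, consecutive slices overlap;
  multiplying per-slice area by the thickness would count ~25 % of the
  tissue twice, so ``depth_mode="increment"`` is the default and
  ``"thickness"`` is available for comparison.

Pixel centres that fall exactly on a polygon edge are resolved by
perturbing the test point by (+eps, +eps) with eps = 2**-20 px, a fixed,
platform-independent tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dicom_io import CTSeries, to_hu
from .errors import EmptyRegionError
from .roi_io import Polygon2D, RoiSet

logger = logging.getLogger(__name__)

#: Sub-pixel perturbation applied to every pixel-centre test point so that
#: centres exactly on a polygon edge are classified deterministically.
EDGE_EPS = 2.0**-20

DEPTH_MODES = ("increment", "thickness")


@dataclass(frozen=True)
class HURange:
    """Closed attenuation interval in Hounsfield units.

    The default [-150, -50] HU is the conventional CT range for adipose
    tissue.  Both endpoints are inclusive: a voxel at exactly -150 or
    exactly -50 HU is counted.
    """

    lo: float = -150.0
    hi: float = -50.0

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"HURange requires lo <= hi, got [{self.lo}, {self.hi}]")


@dataclass
class VolumeReport:
    """Result of quantifying one series against one ROI set.

    ``per_slice`` lists ``(slice_index, n_roi, n_sub)`` for every slice
    that carried at least one polygon.
    """

    n_roi_voxels: int
    n_sub_voxels: int
    total_volume_cm3: float
    sub_volume_cm3: float
    sub_percentage: float
    hu_range: HURange
    depth_mode: str
    per_slice: list[tuple[int, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_roi_voxels": self.n_roi_voxels,
            "n_sub_voxels": self.n_sub_voxels,
            "total_volume_cm3": self.total_volume_cm3,
            "sub_volume_cm3": self.sub_volume_cm3,
            "sub_percentage": self.sub_percentage,
            "hu_lo": self.hu_range.lo,
            "hu_hi": self.hu_range.hi,
            "depth_mode": self.depth_mode,
            "per_slice": [
                {"slice_index": i, "n_roi": r, "n_sub": s} for i, r, s in self.per_slice
            ],
        }


def rasterize_polygon(polygon: Polygon2D, rows: int, cols: int) -> np.ndarray:
    """Rasterize one polygon to a boolean pixel mask.

    A pixel is set iff its (perturbed) centre is inside the closed
    polygon under the even-odd rule.  Parts of the polygon outside the
    grid are clipped silently (those pixels do not exist) with a logged
    warning.  Zero-area polygons yield an empty mask.
    """
    verts = np.asarray(polygon.vertices, dtype=np.float64)
    if (
        verts[:, 0].min() < -0.5
        or verts[:, 0].max() > cols - 0.5
        or verts[:, 1].min() < -0.5
        or verts[:, 1].max() > rows - 0.5
    ):
        logger.warning("polygon extends beyond the %dx%d pixel grid; clipping", rows, cols)

    px = np.arange(cols, dtype=np.float64) + EDGE_EPS  # x: along columns
    py = (np.arange(rows, dtype=np.float64) + EDGE_EPS)[:, None]  # y: along rows
    inside = np.zeros((rows, cols), dtype=bool)
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    with np.errstate(divide="ignore", invalid="ignore"):
        for ax, ay, bx, by in zip(x1, y1, x2, y2):
            crosses = (ay > py) != (by > py)  # horizontal edges never cross
            x_at = ax + (py - ay) * (bx - ax) / (by - ay)
            inside ^= crosses & (px < x_at)
    return inside


def threshold_mask(hu: np.ndarray, hu_range: HURange) -> np.ndarray:
    """Boolean mask of pixels whose HU lies in the closed interval."""
    return (hu >= hu_range.lo) & (hu <= hu_range.hi)


def roi_mask_for_slice(polygons: list[Polygon2D], rows: int, cols: int) -> np.ndarray:
    """OR-combination of all polygon masks on one slice."""
    mask = np.zeros((rows, cols), dtype=bool)
    for polygon in polygons:
        mask |= rasterize_polygon(polygon, rows, cols)
    return mask


def quantify(
    series: CTSeries,
    roiset: RoiSet,
    hu_range: HURange | None = None,
    depth_mode: str = "increment",
) -> VolumeReport:
    """Count ROI and in-range voxels and convert the counts to volumes.

    Parameters
    ----------
    series
        Sorted, calibrated slice stack.
    roiset
        Per-slice polygons; must reference valid slice indices and
        contain at least one polygon.
    hu_range
        Closed HU interval for the sub-volume; defaults to the fat range.
    depth_mode
        ``"increment"`` (default) integrates with the reconstruction
        increment as per-slice depth, ``"thickness"`` with the nominal
        slice thickness.
    """
    if hu_range is None:
        hu_range = HURange()
    if depth_mode not in DEPTH_MODES:
        raise ValueError(f"depth_mode must be one of {DEPTH_MODES}, got {depth_mode!r}")
    roiset.validate_against(series)
    if roiset.n_polygons() == 0:
        raise EmptyRegionError("empty region: the ROI set contains no polygon")

    pixel_area = series.pixel_spacing_row * series.pixel_spacing_col
    n_roi_total = 0
    n_sub_total = 0
    total_mm3 = 0.0
    sub_mm3 = 0.0
    per_slice: list[tuple[int, int, int]] = []
    for idx in sorted(roiset.polygons):
        polygons = roiset.polygons[idx]
        if not polygons:
            continue
        ct_slice = series.slices[idx]
        depth = series.slice_spacing if depth_mode == "increment" else ct_slice.slice_thickness
        roi = roi_mask_for_slice(polygons, ct_slice.rows, ct_slice.cols)
        sub = roi & threshold_mask(to_hu(ct_slice), hu_range)
        n_roi = int(roi.sum())
        n_sub = int(sub.sum())
        voxel_mm3 = pixel_area * depth
        n_roi_total += n_roi
        n_sub_total += n_sub
        total_mm3 += n_roi * voxel_mm3
        sub_mm3 += n_sub * voxel_mm3
        per_slice.append((idx, n_roi, n_sub))

    total_cm3 = total_mm3 / 1000.0
    sub_cm3 = sub_mm3 / 1000.0
    return VolumeReport(
        n_roi_voxels=n_roi_total,
        n_sub_voxels=n_sub_total,
        total_volume_cm3=total_cm3,
        sub_volume_cm3=sub_cm3,
        sub_percentage=fat_percentage(sub_cm3, total_cm3),
        hu_range=hu_range,
        depth_mode=depth_mode,
        per_slice=per_slice,
    )


def fat_percentage(sub_cm3: float, total_cm3: float) -> float:
    """Sub-volume as a percentage of the total ROI volume.

    Returns 0 (with a warning) when the total volume is zero — an ROI
    whose polygons enclose no pixel centre is legal, e.g. a sliver on
    one slice of a larger stack.
    """
    if sub_cm3 < 0 or sub_cm3 > total_cm3:
        raise ValueError(
            f"sub-volume {sub_cm3} must lie in [0, total volume {total_cm3}]"
        )
    if total_cm3 == 0:
        logger.warning("total volume is zero; percentage reported as 0")
        return 0.0
    return 100.0 * sub_cm3 / total_cm3
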