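"""Brute-force reference quantifier for equivalence testing.

Everything here is written with plain per-pixel Python loops and shares
no rasterization or counting code with :mod:`ctsubvol.volumetrics`, so
agreement between the two is a meaningful check and not a tautology.
The geometric conventions are the same by contract: pixel-centre
membership, even-odd fill, and the fixed (+eps, +eps) perturbation of
test points with eps = 2**-20 px.
"""

from __future__ import annotations

from .dicom_io import CTSeries
from .roi_io import Polygon2D, RoiSet
from .volumetrics import HURange, VolumeReport

_EPS = 2.0**-20


def point_in_polygon(x: float, y: float, vertices) -> bool:
    """Even-odd ray cast of a single point, scalar arithmetic only."""
    x += _EPS
    y += _EPS
    inside = False
    n = len(vertices)
    for i in range(n):
        ax, ay = vertices[i]
        bx, by = vertices[(i + 1) % n]
        if (ay > y) != (by > y):
            x_at = ax + (y - ay) * (bx - ax) / (by - ay)
            if x < x_at:
                inside = not inside
    return inside


def rasterize_polygon_naive(polygon: Polygon2D, rows: int, cols: int):
    """Per-pixel loop rasterization; returns a list of row-lists of bool."""
    return [
        [point_in_polygon(float(c), float(r), polygon.vertices) for c in range(cols)]
        for r in range(rows)
    ]


def reference_quantify(
    series: CTSeries,
    roiset: RoiSet,
    hu_range: HURange | None = None,
    depth_mode: str = "increment",
) -> VolumeReport:
    """Quantify with naive loops; same contract as ``volumetrics.quantify``."""
    if hu_range is None:
        hu_range = HURange()
    n_roi_total = 0
    n_sub_total = 0
    total_mm3 = 0.0
    sub_mm3 = 0.0
    per_slice = []
    pixel_area = series.pixel_spacing_row * series.pixel_spacing_col
    for idx in sorted(roiset.polygons):
        polygons = roiset.polygons[idx]
        if not polygons:
            continue
        ct_slice = series.slices[idx]
        depth = (
            series.slice_spacing if depth_mode == "increment" else ct_slice.slice_thickness
        )
        stored = ct_slice.stored_pixels
        n_roi = 0
        n_sub = 0
        for r in range(ct_slice.rows):
            for c in range(ct_slice.cols):
                in_roi = False
                for polygon in polygons:
                    if point_in_polygon(float(c), float(r), polygon.vertices):
                        in_roi = True
                        break
                if not in_roi:
                    continue
                n_roi += 1
                hu = (
                    float(stored[r, c]) * ct_slice.rescale_slope
                    + ct_slice.rescale_intercept
                )
                if hu_range.lo <= hu <= hu_range.hi:
                    n_sub += 1
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
        sub_percentage=(100.0 * sub_cm3 / total_cm3 if total_cm3 > 0 else 0.0),
        hu_range=hu_range,
        depth_mode=depth_mode,
        per_slice=per_slice,
    )
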