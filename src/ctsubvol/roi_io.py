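"""Per-slice polygon ROIs and their CSV serialization.

Regions of interest are drawn manually in a DICOM viewer (one closed
polygon — or several — per axial slice) and exported to a flat CSV.
This module defines a minimal, fully documented dialect:

    slice_index,roi_id,vertex_index,x_px,y_px

* ``slice_index`` — 0-based position of the slice in the *sorted* series
  (not the scanner's InstanceNumber, which is vendor-dependent);
* ``roi_id`` — integer distinguishing multiple polygons on one slice;
* ``vertex_index`` — order of the vertex within its polygon;
* ``x_px, y_px`` — pixel coordinates, x along columns and y along rows,
  with integer coordinates at pixel centres and the origin at the
  centre of the top-left pixel.

Polygons are implicitly closed (last vertex connects back to the first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dicom_io import CTSeries
from .errors import DegeneratePolygonError, MalformedRoiFileError, RoiMismatchError

CSV_COLUMNS = ["slice_index", "roi_id", "vertex_index", "x_px", "y_px"]


@dataclass(frozen=True)
class Polygon2D:
    """A closed polygon in pixel coordinates of one slice."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise DegeneratePolygonError(
                f"degenerate polygon: {len(self.vertices)} vertices (need >= 3)"
            )
        n = len(self.vertices)
        for i in range(n):
            x, y = self.vertices[i]
            if not (math.isfinite(x) and math.isfinite(y)):
                raise DegeneratePolygonError("degenerate polygon: non-finite vertex")
            # closure edge (last -> first) counts as consecutive too
            if self.vertices[i] == self.vertices[(i + 1) % n]:
                raise DegeneratePolygonError(
                    "degenerate polygon: identical consecutive vertices"
                )


@dataclass
class RoiSet:
    """Mapping from sorted-series slice index to its polygons.

    Slices without an entry (or with an empty list) carry no ROI and
    contribute nothing to volumes.
    """

    polygons: dict[int, list[Polygon2D]] = field(default_factory=dict)

    def n_polygons(self) -> int:
        return sum(len(v) for v in self.polygons.values())

    def validate_against(self, series: CTSeries) -> None:
        for idx in self.polygons:
            if not 0 <= idx < len(series):
                raise RoiMismatchError(
                    f"ROI/series mismatch: slice_index {idx} outside series of "
                    f"length {len(series)}"
                )


def read_roi_csv(path: str | Path, series: CTSeries) -> RoiSet:
    """Parse an ROI CSV in the dialect above and validate it against *series*."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MalformedRoiFileError(f"malformed ROI file: {exc}") from exc
    if list(frame.columns) != CSV_COLUMNS:
        raise MalformedRoiFileError(
            f"malformed ROI file: header must be {','.join(CSV_COLUMNS)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    bad |= frame.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax()) + 2  # +1 header, +1 1-based
        raise MalformedRoiFileError(f"malformed ROI file: non-numeric cell at row {row}")

    roiset = RoiSet()
    for (slice_index, roi_id), group in numeric.groupby(
        ["slice_index", "roi_id"], sort=True
    ):
        idx = int(slice_index)
        if not 0 <= idx < len(series):
            raise RoiMismatchError(
                f"ROI/series mismatch: slice_index {idx} outside series of "
                f"length {len(series)}"
            )
        group = group.sort_values("vertex_index")
        vertices = tuple(zip(group["x_px"].tolist(), group["y_px"].tolist()))
        if len(vertices) < 3:
            raise DegeneratePolygonError(
                f"degenerate polygon: roi_id {int(roi_id)} on slice {idx} has "
                f"{len(vertices)} vertices"
            )
        roiset.polygons.setdefault(idx, []).append(Polygon2D(vertices))
    return roiset


def write_roi_csv(roiset: RoiSet, path: str | Path) -> None:
    """Write *roiset* in the documented dialect, rows sorted ascending."""
    records = []
    for slice_index in sorted(roiset.polygons):
        for roi_id, polygon in enumerate(roiset.polygons[slice_index]):
            for vertex_index, (x, y) in enumerate(polygon.vertices):
                records.append((slice_index, roi_id, vertex_index, x, y))
    frame = pd.DataFrame(records, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)
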