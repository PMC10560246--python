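"""Reading DICOM CT series into a calibrated, geometry-aware slice stack.

A CT scanner stores pixel values as integers; the affine rescale
(``HU = stored * RescaleSlope + RescaleIntercept``) recovers Hounsfield
units, the calibrated attenuation scale on which tissue thresholds such
as the fat range are defined.  Volumetry additionally needs the in-plane
pixel spacing and the centre-to-centre distance between consecutive
slices (the reconstruction increment), which may be *smaller* than the
slice thickness when slices overlap — e.g. 1.25 mm thick slices
reconstructed every 1 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

from .errors import (
    DuplicateSlicePositionError,
    MixedSeriesError,
    NoDicomInputError,
    UncalibratedSeriesError,
)

logger = logging.getLogger(__name__)

#: DICOM attributes without which a slice cannot be calibrated or placed in space.
REQUIRED_ATTRIBUTES = (
    "PixelData",
    "RescaleSlope",
    "RescaleIntercept",
    "PixelSpacing",
    "ImagePositionPatient",
    "InstanceNumber",
    "SliceThickness",
)


@dataclass(frozen=True)
class CTSlice:
    """One axial CT slice: stored (uncalibrated) pixels plus geometry.

    Attributes
    ----------
    stored_pixels
        2-D integer array, ``(rows, cols)``, raw stored values.
    rescale_slope, rescale_intercept
        Affine calibration to Hounsfield units.
    pixel_spacing_row, pixel_spacing_col
        Physical size of one pixel in mm (row direction first, per the
        DICOM ``PixelSpacing`` convention).
    image_position
        Patient-coordinate position (mm) of the centre of the first pixel.
    instance_number
        Scanner-assigned slice counter; used only to break position ties.
    slice_thickness
        Nominal reconstructed thickness in mm.
    """

    stored_pixels: np.ndarray
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing_row: float
    pixel_spacing_col: float
    image_position: np.ndarray
    instance_number: int
    slice_thickness: float

    def __post_init__(self) -> None:
        if self.stored_pixels.ndim != 2:
            raise ValueError("stored_pixels must be a 2-D array")
        rows, cols = self.stored_pixels.shape
        if rows < 1 or cols < 1:
            raise ValueError("slice must have at least one row and column")
        if self.pixel_spacing_row <= 0 or self.pixel_spacing_col <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")

    @property
    def rows(self) -> int:
        return self.stored_pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.stored_pixels.shape[1]


@dataclass(frozen=True)
class CTSeries:
    """An ordered stack of congruent slices.

    ``slice_spacing`` is the centre-to-centre distance between
    consecutive slices along the stack normal (the reconstruction
    increment), in mm.  It is the depth used for volume integration in
    the default ``increment`` mode; see :mod:`ctsubvol.volumetrics`.
    """

    slices: tuple[CTSlice, ...]
    slice_spacing: float
    stack_axis: int = field(default=2)

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("series must contain at least one slice")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def rows(self) -> int:
        return self.slices[0].rows

    @property
    def cols(self) -> int:
        return self.slices[0].cols

    @property
    def pixel_spacing_row(self) -> float:
        return self.slices[0].pixel_spacing_row

    @property
    def pixel_spacing_col(self) -> float:
        return self.slices[0].pixel_spacing_col


def to_hu(ct_slice: CTSlice) -> np.ndarray:
    """Convert stored pixels to Hounsfield units.

    Returns a float array; values are not clipped or rounded, so
    threshold comparisons at interval endpoints are exact.
    """
    return (
        ct_slice.stored_pixels.astype(np.float64) * ct_slice.rescale_slope
        + ct_slice.rescale_intercept
    )


def _stack_axis(positions: np.ndarray) -> int:
    """Patient-coordinate axis with the largest positional variance."""
    if len(positions) < 2:
        return 2  # single slice: conventional axial z
    return int(np.argmax(np.var(positions, axis=0)))


def _spacing_from_positions(projected: np.ndarray, slice_thickness: float) -> float:
    """Median absolute gap between consecutive projected positions.

    Falls back to the slice thickness for a single slice.  A gap
    deviating from the median by more than 1 % logs a warning; a zero
    gap (two slices at the same position) is an error.
    """
    if len(projected) < 2:
        return float(slice_thickness)
    gaps = np.abs(np.diff(projected))
    if np.any(gaps == 0):
        raise DuplicateSlicePositionError(
            "duplicate slice position: two slices share the same location "
            "along the stack axis"
        )
    median = float(np.median(gaps))
    if np.any(np.abs(gaps - median) > 0.01 * median):
        logger.warning(
            "non-uniform slice gaps: median %.4f mm, range %.4f-%.4f mm",
            median,
            gaps.min(),
            gaps.max(),
        )
    return median


def compute_slice_spacing(series: CTSeries) -> float:
    """Recompute the reconstruction increment of an already-sorted series."""
    positions = np.array([s.image_position for s in series.slices])
    axis = _stack_axis(positions)
    return _spacing_from_positions(positions[:, axis], series.slices[0].slice_thickness)


def _read_one(path: Path) -> CTSlice | None:
    """Read one file; return None if it is not DICOM at all."""
    try:
        ds = pydicom.dcmread(path)
    except (InvalidDicomError, IsADirectoryError):
        return None
    missing = [a for a in REQUIRED_ATTRIBUTES if getattr(ds, a, None) is None]
    if missing:
        raise UncalibratedSeriesError(
            f"uncalibrated series: {path.name} is missing {', '.join(missing)}"
        )
    spacing = [float(v) for v in ds.PixelSpacing]
    return CTSlice(
        stored_pixels=np.asarray(ds.pixel_array),
        rescale_slope=float(ds.RescaleSlope),
        rescale_intercept=float(ds.RescaleIntercept),
        pixel_spacing_row=spacing[0],
        pixel_spacing_col=spacing[1],
        image_position=np.array([float(v) for v in ds.ImagePositionPatient]),
        instance_number=int(ds.InstanceNumber),
        slice_thickness=float(ds.SliceThickness),
    )


def read_series(directory: str | Path) -> CTSeries:
    """Read every DICOM file in *directory* into a sorted :class:`CTSeries`.

    Non-DICOM files (e.g. an ROI CSV living next to the slices) are
    silently skipped.  Slices are ordered by position along the dominant
    stack axis, with ties broken by ascending ``InstanceNumber``, so the
    result is independent of file names.

    Raises
    ------
    NoDicomInputError
        If the directory holds no readable DICOM file.
    UncalibratedSeriesError
        If a slice lacks a required attribute.
    MixedSeriesError
        If slices disagree on dimensions or pixel spacing.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NoDicomInputError(f"no DICOM input: {directory} is not a directory")
    slices = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        ct_slice = _read_one(path)
        if ct_slice is not None:
            slices.append(ct_slice)
    if not slices:
        raise NoDicomInputError(f"no DICOM input: no readable DICOM file in {directory}")

    first = slices[0]
    for s in slices[1:]:
        if s.stored_pixels.shape != first.stored_pixels.shape or (
            s.pixel_spacing_row,
            s.pixel_spacing_col,
        ) != (first.pixel_spacing_row, first.pixel_spacing_col):
            raise MixedSeriesError(
                "mixed series: slices disagree on image dimensions or pixel spacing"
            )

    positions = np.array([s.image_position for s in slices])
    axis = _stack_axis(positions)
    slices.sort(key=lambda s: (s.image_position[axis], s.instance_number))
    projected = np.array([s.image_position[axis] for s in slices])
    spacing = _spacing_from_positions(projected, first.slice_thickness)
    return CTSeries(slices=tuple(slices), slice_spacing=spacing, stack_axis=axis)
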