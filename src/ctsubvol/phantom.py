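"""Synthetic CT phantom generator with analytic ground truth.

No public CT dataset with matching per-slice ROI exports exists for the
sacroiliac fat-quantification workflow, so tests and examples run on
synthetic phantoms: geometric inserts (boxes, cylinders) of known HU
embedded in a soft-tissue background, written as a standard DICOM
series plus a matching ROI CSV and a ground-truth JSON.

Geometry convention: pixel ``(row r, col c)`` of slice ``i`` has its
centre at patient coordinates ``(x, y, z) = (c * ps, r * ps,
i * slice_spacing)`` mm, with ``ImagePositionPatient = (0, 0, z_i)``.
A voxel takes an insert's HU iff its centre lies inside the insert
(closed boundaries) — the same pixel-centre rule the quantifier uses,
so voxelized ground-truth counts are exact, not approximate.

The default acquisition geometry emulates a routine clinical protocol:
1.25 mm slice thickness reconstructed at a 1 mm increment (overlapping
slices), soft-tissue background of +40 HU, fat inserts at -100 HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .dicom_io import CTSeries, CTSlice
from .errors import StoredRangeError
from .oracle import point_in_polygon, reference_quantify  # noqa: F401  (re-export)
from .roi_io import Polygon2D, RoiSet, write_roi_csv

_SLOPE = 1.0
_INTERCEPT = -1024.0
_STORED_MAX = 65535


@dataclass(frozen=True)
class Insert:
    """A geometric insert of uniform HU.

    ``shape`` is ``"box"`` (axis-aligned, ``size`` = full extents in mm)
    or ``"cylinder"`` (axis along z, ``size`` = (radius, height) in mm).
    ``center`` is the shape centre in mm patient coordinates.
    """

    shape: str
    center: tuple[float, float, float]
    size: tuple[float, ...]
    hu: float

    def __post_init__(self) -> None:
        if self.shape not in ("box", "cylinder"):
            raise ValueError(f"unknown insert shape {self.shape!r}")
        n_expected = 3 if self.shape == "box" else 2
        if len(self.size) != n_expected or any(s <= 0 for s in self.size):
            raise ValueError(f"{self.shape} insert needs {n_expected} positive size values")

    @property
    def analytic_volume_cm3(self) -> float:
        if self.shape == "box":
            sx, sy, sz = self.size
            return sx * sy * sz / 1000.0
        r, h = self.size
        return float(np.pi) * r * r * h / 1000.0

    def contains(self, x: np.ndarray, y: np.ndarray, z: float) -> np.ndarray:
        """Closed-boundary membership of points (x, y) mm on the plane at z."""
        cx, cy, cz = self.center
        if self.shape == "box":
            sx, sy, sz = self.size
            if abs(z - cz) > sz / 2:
                return np.zeros(np.broadcast(x, y).shape, dtype=bool)
            return (np.abs(x - cx) <= sx / 2) & (np.abs(y - cy) <= sy / 2)
        r, h = self.size
        if abs(z - cz) > h / 2:
            return np.zeros(np.broadcast(x, y).shape, dtype=bool)
        return (x - cx) ** 2 + (y - cy) ** 2 <= r * r


@dataclass
class PhantomSpec:
    """Full generative description of a synthetic series.

    ``roi`` is a polygon template in pixel coordinates applied to every
    slice; when None, a half-integer-aligned rectangle bounding all
    inserts with a 2-pixel margin is used (or a centred rectangle for
    insert-free phantoms).  ``noise_sd`` adds zero-mean Gaussian HU
    noise truncated at +/- 3 SD, so a +40 HU background cannot reach the
    fat range unless ``noise_sd`` >= 30 is chosen deliberately.
    """

    rows: int = 64
    cols: int = 64
    pixel_spacing: float = 1.0
    n_slices: int = 20
    slice_spacing: float = 1.0
    slice_thickness: float = 1.25
    background_hu: float = 40.0
    inserts: list[Insert] = field(default_factory=list)
    roi: list[tuple[float, float]] | None = None
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.n_slices < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_spacing <= 0 or self.slice_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")


@dataclass
class GroundTruth:
    """Analytic and voxelized-at-this-grid truth for one phantom."""

    voxel_volume_mm3: float
    n_slices: int
    roi_voxel_count: int
    expected_roi_volume_cm3: float
    inserts: list[dict]

    def to_dict(self) -> dict:
        return {
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "n_slices": self.n_slices,
            "roi_voxel_count": self.roi_voxel_count,
            "expected_roi_volume_cm3": self.expected_roi_volume_cm3,
            "inserts": self.inserts,
        }


def _default_roi(spec: PhantomSpec) -> Polygon2D:
    """Half-integer rectangle bounding all inserts (2 px margin), clamped."""
    ps = spec.pixel_spacing
    if spec.inserts:
        xs, ys = [], []
        for ins in spec.inserts:
            cx, cy, _ = ins.center
            if ins.shape == "box":
                hx, hy = ins.size[0] / 2, ins.size[1] / 2
            else:
                hx = hy = ins.size[0]
            xs += [(cx - hx) / ps, (cx + hx) / ps]
            ys += [(cy - hy) / ps, (cy + hy) / ps]
        x0 = np.floor(min(xs) - 2) - 0.5
        x1 = np.ceil(max(xs) + 2) + 0.5
        y0 = np.floor(min(ys) - 2) - 0.5
        y1 = np.ceil(max(ys) + 2) + 0.5
    else:
        # no inserts: centred rectangle covering the middle half of the grid
        x0, x1 = 0.25 * spec.cols - 0.5, 0.75 * spec.cols - 0.5
        y0, y1 = 0.25 * spec.rows - 0.5, 0.75 * spec.rows - 0.5
    x0, y0 = max(x0, -0.5), max(y0, -0.5)
    x1 = min(x1, spec.cols - 0.5)
    y1 = min(y1, spec.rows - 0.5)
    return Polygon2D(((x0, y0), (x1, y0), (x1, y1), (x0, y1)))


def _hu_volume(spec: PhantomSpec) -> tuple[np.ndarray, list[int]]:
    """HU volume (n_slices, rows, cols) and per-insert voxel counts.

    Later inserts overwrite earlier ones; counts reflect the final
    labelling so overlapping inserts stay consistent with the volume.
    """
    ps = spec.pixel_spacing
    x = np.arange(spec.cols, dtype=np.float64) * ps
    y = (np.arange(spec.rows, dtype=np.float64) * ps)[:, None]
    hu = np.full((spec.n_slices, spec.rows, spec.cols), spec.background_hu)
    label = np.full((spec.n_slices, spec.rows, spec.cols), -1, dtype=np.int64)
    for i in range(spec.n_slices):
        z = i * spec.slice_spacing
        for j, ins in enumerate(spec.inserts):
            mask = ins.contains(x, y, z)
            hu[i][mask] = ins.hu
            label[i][mask] = j
    counts = [int((label == j).sum()) for j in range(len(spec.inserts))]
    return hu, counts


def build_series(spec: PhantomSpec) -> tuple[CTSeries, RoiSet, GroundTruth]:
    """Construct the phantom in memory (no files written).

    Returns the calibrated series, its ROI set, and the ground truth.
    Stored pixels are ``HU + 1024`` (slope 1, intercept -1024), rounded
    to the nearest integer when noise makes HU non-integral.
    """
    hu, insert_counts = _hu_volume(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, hu.shape)
        np.clip(noise, -3 * spec.noise_sd, 3 * spec.noise_sd, out=noise)
        hu = hu + noise
    stored = np.rint(hu - _INTERCEPT)
    if stored.min() < 0 or stored.max() > _STORED_MAX:
        raise StoredRangeError(
            f"HU outside representable stored range: stored values would span "
            f"[{stored.min():.0f}, {stored.max():.0f}], allowed [0, {_STORED_MAX}]"
        )
    stored = stored.astype(np.uint16)

    slices = tuple(
        CTSlice(
            stored_pixels=stored[i],
            rescale_slope=_SLOPE,
            rescale_intercept=_INTERCEPT,
            pixel_spacing_row=spec.pixel_spacing,
            pixel_spacing_col=spec.pixel_spacing,
            image_position=np.array([0.0, 0.0, i * spec.slice_spacing]),
            instance_number=i + 1,
            slice_thickness=spec.slice_thickness,
        )
        for i in range(spec.n_slices)
    )
    series = CTSeries(slices=slices, slice_spacing=spec.slice_spacing)

    polygon = Polygon2D(tuple(spec.roi)) if spec.roi is not None else _default_roi(spec)
    roiset = RoiSet({i: [polygon] for i in range(spec.n_slices)})

    # ROI voxel count via the naive per-pixel oracle, independent of volumetrics
    per_slice_roi = sum(
        point_in_polygon(float(c), float(r), polygon.vertices)
        for r in range(spec.rows)
        for c in range(spec.cols)
    )
    voxel_mm3 = spec.pixel_spacing**2 * spec.slice_spacing
    truth = GroundTruth(
        voxel_volume_mm3=voxel_mm3,
        n_slices=spec.n_slices,
        roi_voxel_count=per_slice_roi * spec.n_slices,
        expected_roi_volume_cm3=per_slice_roi * spec.n_slices * voxel_mm3 / 1000.0,
        inserts=[
            {
                "shape": ins.shape,
                "hu": ins.hu,
                "analytic_volume_cm3": ins.analytic_volume_cm3,
                "voxel_count": count,
                "voxelized_volume_cm3": count * voxel_mm3 / 1000.0,
            }
            for ins, count in zip(spec.inserts, insert_counts)
        ],
    )
    return series, roiset, truth


def _write_slice(ct_slice: CTSlice, spec: PhantomSpec, index: int, path: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[f"ctsubvol-{spec.seed}-{index}"]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[f"ctsubvol-study-{spec.seed}"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[f"ctsubvol-series-{spec.seed}"])
    ds.Modality = "CT"
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = "PHANTOM"
    ds.Rows = ct_slice.rows
    ds.Columns = ct_slice.cols
    ds.PixelSpacing = [ct_slice.pixel_spacing_row, ct_slice.pixel_spacing_col]
    ds.ImagePositionPatient = list(ct_slice.image_position)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.InstanceNumber = ct_slice.instance_number
    ds.SliceThickness = ct_slice.slice_thickness
    ds.SpacingBetweenSlices = spec.slice_spacing
    ds.RescaleSlope = ct_slice.rescale_slope
    ds.RescaleIntercept = ct_slice.rescale_intercept
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(ct_slice.stored_pixels, dtype=np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def generate(spec: PhantomSpec, out_dir: str | Path) -> GroundTruth:
    """Write the phantom to *out_dir*: DICOM slices, ``roi.csv``,
    ``ground_truth.json``.  Returns the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, roiset, truth = build_series(spec)
    for i, ct_slice in enumerate(series.slices):
        _write_slice(ct_slice, spec, i, out_dir / f"slice_{i:04d}.dcm")
    write_roi_csv(roiset, out_dir / "roi.csv")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return truth


# --- canonical fixtures -------------------------------------------------

def box_phantom(noise_sd: float = 0.0, seed: int = 0) -> PhantomSpec:
    """10 x 10 x 20 mm fat box (-100 HU) on a 1 mm isotropic-in-plane grid.

    The box is voxel-aligned (exactly 2000 voxel centres inside) and the
    ROI square coincides with its footprint, so total and fat volume are
    both exactly 2.000 cm^3 at 1 mm increment and the fat fraction 100 %.
    """
    return PhantomSpec(
        inserts=[Insert("box", center=(14.5, 14.5, 9.5), size=(10.0, 10.0, 20.0), hu=-100.0)],
        roi=[(9.5, 9.5), (19.5, 9.5), (19.5, 19.5), (9.5, 19.5)],
        noise_sd=noise_sd,
        seed=seed,
    )


def cylinder_phantom(pixel_spacing: float = 0.5) -> PhantomSpec:
    """Fat cylinder (r = 10 mm, h = 20 mm, -100 HU), analytic 6.283 cm^3.

    The z extent covers exactly the 20 slice centres, so discretization
    error is purely in-plane and shrinks with ``pixel_spacing``.  The
    centre is shifted 0.1 mm off the grid centre so no voxel centre
    falls exactly on the circle and coarse grids do not sit on an
    accidental cancellation of the in-plane counting error.
    """
    side_mm = 26.0
    n = int(round(side_mm / pixel_spacing))
    c = (n - 1) / 2 * pixel_spacing + 0.1
    return PhantomSpec(
        rows=n,
        cols=n,
        pixel_spacing=pixel_spacing,
        n_slices=20,
        inserts=[Insert("cylinder", center=(c, c, 9.75), size=(10.0, 20.0), hu=-100.0)],
    )


def background_phantom() -> PhantomSpec:
    """Uniform +40 HU soft tissue, no inserts: fat volume must be zero."""
    return PhantomSpec()


# --- randomized fixtures for property and equivalence testing -----------

def random_polygon(rng: np.random.Generator, rows: int, cols: int,
                   n_vertices: int | None = None) -> Polygon2D:
    """A random simple-or-self-intersecting polygon inside the grid.

    Vertices are drawn as a star-shaped perturbation around a random
    centre, which produces a mix of convex, concave, and (after
    occasional angular jitter) self-intersecting shapes — all legal
    under the even-odd fill rule.
    """
    if n_vertices is None:
        n_vertices = int(rng.integers(3, 13))
    cx = rng.uniform(0.2 * cols, 0.8 * cols)
    cy = rng.uniform(0.2 * rows, 0.8 * rows)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    angles += rng.uniform(-0.3, 0.3, n_vertices)  # jitter may self-intersect
    radii = rng.uniform(0.05, 0.45, n_vertices) * min(rows, cols)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return Polygon2D(tuple(zip(xs.tolist(), ys.tolist())))


def random_phantom_spec(rng: np.random.Generator) -> PhantomSpec:
    """A small random phantom: random grid, inserts, noise, and ROI."""
    rows = int(rng.integers(16, 40))
    cols = int(rng.integers(16, 40))
    n_slices = int(rng.integers(2, 6))
    ps = float(rng.choice([0.5, 1.0, 2.0]))
    spacing = float(rng.choice([0.5, 1.0, 1.25]))
    inserts = []
    for _ in range(int(rng.integers(0, 3))):
        shape = str(rng.choice(["box", "cylinder"]))
        cx = rng.uniform(0.3, 0.7) * cols * ps
        cy = rng.uniform(0.3, 0.7) * rows * ps
        cz = rng.uniform(0.2, 0.8) * n_slices * spacing
        hu = float(rng.uniform(-140, -60))
        if shape == "box":
            size = tuple(rng.uniform(2, 0.4 * min(rows, cols) * ps, 3))
        else:
            size = (rng.uniform(1, 0.2 * min(rows, cols) * ps), rng.uniform(2, 6))
        inserts.append(Insert(shape, (cx, cy, cz), size, hu))
    return PhantomSpec(
        rows=rows,
        cols=cols,
        pixel_spacing=ps,
        n_slices=n_slices,
        slice_spacing=spacing,
        inserts=inserts,
        roi=[tuple(v) for v in
             np.asarray(random_polygon(rng, rows, cols).vertices).tolist()],
        seed=int(rng.integers(0, 2**31 - 1)),
        noise_sd=float(rng.choice([0.0, 5.0, 12.0])),
    )
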