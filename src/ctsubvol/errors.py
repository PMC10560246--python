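"""Exception hierarchy.

Every error a user can trigger through bad input derives from
:class:`CTSubvolError`, so the CLI can distinguish data errors (exit
code 3) from programming errors (which propagate as stack traces).
"""


class CTSubvolError(Exception):
    """Base class for all user-facing errors raised by this package."""


class NoDicomInputError(CTSubvolError):
    """The input directory contains no readable DICOM file."""


class UncalibratedSeriesError(CTSubvolError):
    """A slice lacks a geometry or calibration attribute required for volumetry."""


class MixedSeriesError(CTSubvolError):
    """Slices in one directory disagree on image dimensions or pixel spacing."""


class DuplicateSlicePositionError(CTSubvolError):
    """Two distinct slices share the same position along the stack axis."""


class RoiMismatchError(CTSubvolError):
    """An ROI references a slice index outside the series."""


class DegeneratePolygonError(CTSubvolError):
    """A polygon has fewer than three vertices or repeated consecutive vertices."""


class MalformedRoiFileError(CTSubvolError):
    """The ROI CSV file violates the documented dialect."""


class EmptyRegionError(CTSubvolError):
    """The ROI set contains no polygon at all; volumes would be meaningless."""


class StoredRangeError(CTSubvolError):
    """A requested HU cannot be represented in the stored-pixel range."""
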