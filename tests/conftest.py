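import numpy as np
import pytest

from ctsubvol.dicom_io import CTSeries, CTSlice


def make_slice(z=0.0, stored=None, rows=4, cols=4, instance=1,
               slope=1.0, intercept=-1024.0, ps=(1.0, 1.0), thickness=1.25):
    """Hand-build a CTSlice without touching the DICOM layer."""
    if stored is None:
        stored = np.zeros((rows, cols), dtype=np.uint16)
    return CTSlice(
        stored_pixels=np.asarray(stored),
        rescale_slope=slope,
        rescale_intercept=intercept,
        pixel_spacing_row=ps[0],
        pixel_spacing_col=ps[1],
        image_position=np.array([0.0, 0.0, z]),
        instance_number=instance,
        slice_thickness=thickness,
    )


def make_series(z_positions, spacing=1.0, **slice_kwargs):
    slices = tuple(
        make_slice(z=z, instance=i + 1, **slice_kwargs)
        for i, z in enumerate(z_positions)
    )
    return CTSeries(slices=slices, slice_spacing=spacing)


@pytest.fixture(scope="session")
def box_dataset(tmp_path_factory):
    """Box phantom written to disk once per session: (directory, truth)."""
    from ctsubvol import phantom

    out = tmp_path_factory.mktemp("box_phantom")
    truth = phantom.generate(phantom.box_phantom(), out)
    return out, truth
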