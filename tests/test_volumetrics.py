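"""Rasterization, HU thresholding, and volume computation."""

import numpy as np
import pytest

from ctsubvol import oracle, phantom
from ctsubvol.errors import EmptyRegionError
from ctsubvol.roi_io import Polygon2D, RoiSet
from ctsubvol.volumetrics import (
    HURange,
    fat_percentage,
    quantify,
    rasterize_polygon,
    threshold_mask,
)

from .conftest import make_series

SQUARE = Polygon2D(((0.5, 0.5), (2.5, 0.5), (2.5, 2.5), (0.5, 2.5)))


class TestRasterize:
    def test_unit_square_covers_four_pixel_centres(self):
        mask = rasterize_polygon(SQUARE, 5, 5)
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:3, 1:3] = True
        assert np.array_equal(mask, expected)

    def test_collinear_triangle_is_empty(self):
        degenerate = Polygon2D(((0.0, 0.0), (2.0, 2.0), (4.0, 4.0)))
        assert not rasterize_polygon(degenerate, 8, 8).any()

    def test_out_of_grid_polygon_clipped_with_warning(self, caplog):
        huge = Polygon2D(((-5.0, -5.0), (20.0, -5.0), (20.0, 20.0), (-5.0, 20.0)))
        with caplog.at_level("WARNING", logger="ctsubvol.volumetrics"):
            mask = rasterize_polygon(huge, 4, 4)
        assert mask.all()  # grid fully inside the polygon
        assert any("clipping" in r.message for r in caplog.records)

    def test_matches_ray_casting_oracle_on_random_polygons(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            poly = phantom.random_polygon(rng, 64, 64)
            fast = rasterize_polygon(poly, 64, 64)
            naive = np.array(oracle.rasterize_polygon_naive(poly, 64, 64))
            assert np.array_equal(fast, naive)

    def test_on_edge_centres_resolved_deterministically(self):
        # square edges pass exactly through the centres of boundary pixels
        on_edge = Polygon2D(((1.0, 1.0), (3.0, 1.0), (3.0, 3.0), (1.0, 3.0)))
        mask = rasterize_polygon(on_edge, 6, 6)
        naive = np.array(oracle.rasterize_polygon_naive(on_edge, 6, 6))
        assert np.array_equal(mask, naive)
        # +eps perturbation keeps low edges in, high edges out
        assert mask.sum() == 4
        assert mask[1, 1] and mask[2, 2] and not mask[3, 3]


class TestThreshold:
    def test_closed_interval_endpoints(self):
        hu = np.array([[-150.0, -50.0], [-150.5, -49.9]])
        mask = threshold_mask(hu, HURange())
        assert mask.tolist() == [[True, True], [False, False]]

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        hu = rng.uniform(-300, 100, (32, 32))
        lo, hi = -150.0, -50.0
        mask = threshold_mask(hu, HURange(lo, hi))
        expected = np.vectorize(lambda v: lo <= v <= hi)(hu)
        assert np.array_equal(mask, expected)

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            HURange(-50.0, -150.0)


def _uniform_series(hu_value, n_slices=20, rows=64, cols=64):
    stored = np.full((rows, cols), int(hu_value + 1024), dtype=np.uint16)
    return make_series(range(n_slices), stored=stored, rows=rows, cols=cols)


TIGHT_SQUARE = Polygon2D(((9.5, 9.5), (19.5, 9.5), (19.5, 19.5), (9.5, 19.5)))


class TestQuantify:
    def test_fat_box_counts_and_volumes(self):
        series = _uniform_series(-100.0)
        roiset = RoiSet({i: [TIGHT_SQUARE] for i in range(20)})
        report = quantify(series, roiset)
        assert report.n_roi_voxels == 2000
        assert report.n_sub_voxels == 2000
        assert report.total_volume_cm3 == 2.0
        assert report.sub_volume_cm3 == 2.0
        assert report.sub_percentage == 100.0

    def test_soft_tissue_only_yields_zero_fat(self):
        series = _uniform_series(40.0)
        roiset = RoiSet({i: [TIGHT_SQUARE] for i in range(20)})
        report = quantify(series, roiset)
        assert report.sub_volume_cm3 == 0.0
        assert report.sub_percentage == 0.0
        assert report.total_volume_cm3 == 2.0

    def test_cylinder_volume_within_2pct_of_analytic(self):
        series, roiset, _ = phantom.build_series(phantom.cylinder_phantom(0.5))
        report = quantify(series, roiset)
        analytic = np.pi * 10.0**2 * 20.0 / 1000.0
        assert report.sub_volume_cm3 == pytest.approx(analytic, rel=0.02)

    def test_empty_roiset_is_an_error(self):
        with pytest.raises(EmptyRegionError):
            quantify(_uniform_series(-100.0), RoiSet())

    def test_overlapping_polygons_or_combined(self):
        series = _uniform_series(-100.0, n_slices=1)
        shifted = Polygon2D(((14.5, 9.5), (24.5, 9.5), (24.5, 19.5), (14.5, 19.5)))
        roiset = RoiSet({0: [TIGHT_SQUARE, shifted]})
        report = quantify(series, roiset)
        assert report.n_roi_voxels == 150  # 100 + 100 - 50 overlap

    def test_depth_mode_thickness_scales_by_thickness_ratio(self):
        series, roiset, _ = phantom.build_series(phantom.box_phantom())
        inc = quantify(series, roiset, depth_mode="increment")
        thick = quantify(series, roiset, depth_mode="thickness")
        assert thick.total_volume_cm3 == 1.25 * inc.total_volume_cm3
        assert thick.sub_volume_cm3 == 1.25 * inc.sub_volume_cm3
        assert thick.n_sub_voxels == inc.n_sub_voxels

    def test_unknown_depth_mode_rejected(self):
        series, roiset, _ = phantom.build_series(phantom.box_phantom())
        with pytest.raises(ValueError):
            quantify(series, roiset, depth_mode="both")


class TestInvariants:
    def test_partition_of_hu_axis_preserves_total(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rows = cols = 24
            stored = rng.integers(600, 1300, (rows, cols)).astype(np.uint16)
            series = make_series(range(3), stored=stored, rows=rows, cols=cols)
            roiset = RoiSet({i: [phantom.random_polygon(rng, rows, cols)]
                             for i in range(3)})
            lo, hi = sorted(rng.uniform(-400, 300, 2))
            inside = quantify(series, roiset, HURange(lo, hi))
            below = quantify(series, roiset,
                             HURange(-np.inf, np.nextafter(lo, -np.inf)))
            above = quantify(series, roiset,
                             HURange(np.nextafter(hi, np.inf), np.inf))
            assert (inside.n_sub_voxels + below.n_sub_voxels + above.n_sub_voxels
                    == inside.n_roi_voxels)

    def test_widening_range_never_loses_voxels(self):
        rng = np.random.default_rng(13)
        stored = rng.integers(600, 1300, (24, 24)).astype(np.uint16)
        series = make_series(range(2), stored=stored, rows=24, cols=24)
        roiset = RoiSet({i: [phantom.random_polygon(rng, 24, 24)] for i in range(2)})
        for _ in range(30):
            lo, hi = sorted(rng.uniform(-400, 300, 2))
            pad_lo, pad_hi = rng.uniform(0, 100, 2)
            narrow = quantify(series, roiset, HURange(lo, hi))
            wide = quantify(series, roiset, HURange(lo - pad_lo, hi + pad_hi))
            assert wide.n_sub_voxels >= narrow.n_sub_voxels

    def test_volume_scales_with_pixel_and_slice_spacing(self):
        rng = np.random.default_rng(17)
        stored = rng.integers(600, 1300, (24, 24)).astype(np.uint16)
        roiset = RoiSet({i: [phantom.random_polygon(rng, 24, 24)] for i in range(2)})
        base = quantify(make_series(range(2), stored=stored, rows=24, cols=24,
                                    ps=(1.0, 1.0)), roiset)
        double_px = quantify(make_series(range(2), stored=stored, rows=24, cols=24,
                                         ps=(2.0, 2.0)), roiset)
        double_z = quantify(make_series([0.0, 2.0], spacing=2.0, stored=stored,
                                        rows=24, cols=24), roiset)
        assert double_px.total_volume_cm3 == 4.0 * base.total_volume_cm3
        assert double_px.sub_volume_cm3 == 4.0 * base.sub_volume_cm3
        assert double_z.total_volume_cm3 == 2.0 * base.total_volume_cm3


class TestFatPercentage:
    @pytest.mark.parametrize("sub,total,expected", [
        (2.0, 10.0, 20.0),
        (0.0, 10.0, 0.0),
        (3.7, 3.7, 100.0),
    ])
    def test_formula(self, sub, total, expected):
        assert fat_percentage(sub, total) == pytest.approx(expected)

    def test_zero_total_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="ctsubvol.volumetrics"):
            assert fat_percentage(0.0, 0.0) == 0.0
        assert any("zero" in r.message for r in caplog.records)

    def test_sub_exceeding_total_is_contract_violation(self):
        with pytest.raises(ValueError):
            fat_percentage(11.0, 10.0)
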