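import math

import numpy as np
import pytest

from conftest import mask_from_bits, vertical_line_mask
from rhizograph.image_io import CalibrationScale
from rhizograph.root_topology import partition_root
from rhizograph.skeleton_graph import build_graph, skeletonize
from rhizograph.traits import (
    TRAIT_NAMES,
    area_traits,
    compute_all,
    count_traits,
    distribution_traits,
    extent_traits,
    length_traits,
    primary_geometry,
    _nearest_rank,
)


def pipeline_parts(mask):
    skel = skeletonize(mask)
    g = build_graph(skel)
    p = partition_root(g)
    return skel, g, p


class TestLengthTraits:
    def test_straight_line_with_calibration(self):
        mask = vertical_line_mask(100)
        skel, g, p = pipeline_parts(mask)
        tv = compute_all(mask, skel, g, p, scale=CalibrationScale(100.0))
        assert tv["PRL"] == pytest.approx(0.99)  # n-1 edges
        assert tv["SEL"] == 0.0
        assert tv["TRL"] == pytest.approx(0.99)
        assert tv.units_flag == "cm"

    def test_y_graph_total_includes_attachment_edge(self, y_graph):
        p = partition_root(y_graph)
        trl, prl, sel = length_traits(p)
        assert prl == pytest.approx(9.0)
        assert sel == pytest.approx(3.0)
        assert trl == pytest.approx(12.0)


class TestExtentTraits:
    def test_vertical_line(self):
        dep, wid, wdr = extent_traits(vertical_line_mask(50))
        assert (dep, wid) == (50.0, 1.0)
        assert wdr == pytest.approx(0.02)

    def test_square_blob_symmetric(self):
        bits = np.zeros((20, 20), dtype=bool)
        bits[5:15, 5:15] = True
        dep, wid, wdr = extent_traits(mask_from_bits(bits))
        assert wdr == pytest.approx(1.0)


class TestAreaTraits:
    def test_single_line_degenerate_hull(self):
        mask = vertical_line_mask(30)
        skel = skeletonize(mask)
        per, cva, nwa, sol = area_traits(mask, skel)
        assert per == 30.0
        assert cva == 30.0
        assert nwa == 30.0
        assert sol == pytest.approx(1.0)

    def test_filled_square_perimeter_and_hull(self):
        bits = np.zeros((14, 14), dtype=bool)
        bits[2:12, 2:12] = True
        mask = mask_from_bits(bits)
        per, cva, nwa, sol = area_traits(mask, skeletonize(mask))
        assert per == 36.0   # 4*10 - 4 corners
        assert cva == 100.0  # all pixel centers inside or on the hull
        assert sol <= 1.0

    def test_solidity_bounded_on_random_blobs(self):
        rng = np.random.default_rng(23)
        from scipy import ndimage

        bits = ndimage.binary_dilation(rng.random((40, 40)) < 0.01, iterations=4)
        bits = ndimage.label(bits, structure=np.ones((3, 3)))[0] == 1
        mask = mask_from_bits(bits)
        _, cva, nwa, sol = area_traits(mask, skeletonize(mask))
        assert 0 < sol <= 1.0


class TestCountTraits:
    def test_straight_vertical_line(self):
        mask = vertical_line_mask(40)
        skel = skeletonize(mask)
        g = build_graph(skel)
        mnr, med, tnr, bsh = count_traits(skel, g)
        assert (mnr, med, tnr, bsh) == (1.0, 1.0, 2.0, 1.0)

    def test_nearest_rank_84th_percentile(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0, 3.0])
        assert _nearest_rank(vals, 0.84) == 3.0  # ceil(0.84*5) = 5th order stat
        assert np.median(vals) == 2.0

    def test_bushiness_at_least_one(self):
        rng = np.random.default_rng(31)
        skel = rng.random((30, 30)) < 0.3
        skel[0, :] = True  # guarantee a nonempty row structure
        g = build_graph(skel)
        mnr, med, _, bsh = count_traits(skel, g)
        assert bsh >= 1.0


class TestDistributionTraits:
    def test_uniform_vertical_line_symmetry(self):
        mask = vertical_line_mask(60)
        skel, g, p = pipeline_parts(mask)
        d = distribution_traits(mask, g, p)
        assert d["COM"] == pytest.approx(0.5)
        assert d["COP"] == 0.5
        assert d["LED"] == pytest.approx(1.0 / 3.0, abs=0.04)  # row quantization
        for k in ("CMT", "CMM", "CMB", "CPT", "CPM", "CPB"):
            assert d[k] == pytest.approx(0.5, abs=0.05)

    def test_branches_in_top_third_raise_led(self):
        bits = np.zeros((70, 40), dtype=bool)
        bits[2:62, 20] = True            # vertical axis, depth 60
        for row in (5, 10, 15):          # laterals only in the top third
            bits[row, 5:20] = True
        mask = mask_from_bits(bits)
        skel, g, p = pipeline_parts(mask)
        d = distribution_traits(mask, g, p)
        assert d["COM"] < 0.45
        assert d["LED"] > 0.5

    def test_bands_degenerate_below_three_rows(self):
        bits = np.zeros((5, 10), dtype=bool)
        bits[2, 2:9] = True
        mask = mask_from_bits(bits)
        skel, g, p = pipeline_parts(mask)
        d = distribution_traits(mask, g, p)
        for k in ("CMT", "CMM", "CMB", "CPT", "CPM", "CPB"):
            assert math.isnan(d[k])

    def test_bounds_hold(self):
        rng = np.random.default_rng(37)
        from scipy import ndimage

        bits = ndimage.binary_dilation(rng.random((50, 30)) < 0.02, iterations=3)
        bits = ndimage.label(bits, structure=np.ones((3, 3)))[0] == 1
        mask = mask_from_bits(bits)
        skel, g, p = pipeline_parts(mask)
        d = distribution_traits(mask, g, p)
        for k, v in d.items():
            if not math.isnan(v):
                assert 0.0 <= v <= 1.0, k


class TestPrimaryGeometry:
    def test_bar_of_width_five_is_a_cylinder(self):
        bits = np.zeros((9, 106), dtype=bool)
        bits[2:7, 3:103] = True  # width 5, length 100
        mask = mask_from_bits(bits)
        skel, g, p = pipeline_parts(mask)
        dia, vol, sua, srl = primary_geometry(mask, p)
        assert dia == pytest.approx(5.0, rel=0.1)
        assert vol == pytest.approx(math.pi * 2.5**2 * p.primary_length, rel=0.15)
        assert sua == pytest.approx(2 * math.pi * 2.5 * p.primary_length, rel=0.15)

    def test_one_pixel_line_clamped_radius(self):
        mask = vertical_line_mask(30)
        skel, g, p = pipeline_parts(mask)
        dia, vol, sua, srl = primary_geometry(mask, p)
        assert dia == pytest.approx(1.0)

    def test_srl_vol_trl_identity(self):
        mask = vertical_line_mask(50)
        skel, g, p = pipeline_parts(mask)
        _, vol, _, srl = primary_geometry(mask, p)
        trl = p.primary_length + p.secondary_total
        assert srl * vol == pytest.approx(trl)


class TestComputeAll:
    def test_exactly_27_traits(self):
        mask = vertical_line_mask(40)
        skel, g, p = pipeline_parts(mask)
        tv = compute_all(mask, skel, g, p)
        assert len(TRAIT_NAMES) == 27
        assert set(tv.values) == set(TRAIT_NAMES)

    def test_uncalibrated_flag_and_pixel_units(self):
        mask = vertical_line_mask(40)
        skel, g, p = pipeline_parts(mask)
        tv_px = compute_all(mask, skel, g, p, scale=None)
        tv_cm = compute_all(mask, skel, g, p, scale=CalibrationScale(10.0))
        assert tv_px.units_flag == "px"
        assert tv_cm.units_flag == "cm"
        assert tv_cm["TRL"] == pytest.approx(tv_px["TRL"] / 10.0)
        assert tv_cm["VOL"] == pytest.approx(tv_px["VOL"] / 1000.0)
        # dimensionless traits identical in both unit systems
        for k in ("WDR", "SOL", "BSH", "LED", "COM"):
            assert tv_cm[k] == pytest.approx(tv_px[k])

    def test_conservation_identity(self):
        mask = vertical_line_mask(40)
        skel, g, p = pipeline_parts(mask)
        tv = compute_all(mask, skel, g, p)
        assert tv["TRL"] == pytest.approx(tv["PRL"] + tv["SEL"], rel=1e-6)

    def test_missing_fields_flagged_not_zeroed(self):
        bits = np.zeros((4, 10), dtype=bool)
        bits[1, 2:9] = True  # depth 1: band traits must be missing
        mask = mask_from_bits(bits)
        skel, g, p = pipeline_parts(mask)
        tv = compute_all(mask, skel, g, p)
        assert {"CMT", "CMM", "CMB", "CPT", "CPM", "CPB"} <= tv.missing
        assert all(math.isnan(tv[k]) for k in tv.missing)
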