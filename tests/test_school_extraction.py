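import itertools

import numpy as np
import pytest

from echofish.pixel_calibration import PixelMapping
from echofish.school_extraction import (
    AggregationRules,
    CandidateRegion,
    extract_parameters,
    filter_candidates,
    find_candidates,
    link_schools,
    make_mask,
)
from echofish.seabed_noise import SeabedPath

from conftest import make_frame
from oracles import flood_fill_components


def region_from_mask(mask, mpr=1.0, mpc=1.0):
    rr, cc = np.nonzero(np.asarray(mask, dtype=bool))
    return CandidateRegion(rr, cc, mpr, mpc)


def deep_seabed(frame, row=None):
    row = frame.n_rows if row is None else row
    return SeabedPath(np.full(frame.n_cols, min(row, frame.n_rows - 1)), 0.5, 2, 0.0)


class TestMakeMask:
    def test_blank(self, blank_frame):
        assert not make_mask(blank_frame).any()

    def test_counts_pixels(self):
        px = np.zeros((8, 8), dtype=int)
        px[2:5, 3:6] = 4
        assert make_mask(make_frame(px)).sum() == 9


class TestFindCandidates:
    def test_two_blobs_split_by_column(self):
        px = np.zeros((6, 7), dtype=int)
        px[2, 0:2] = 1
        px[2, 4:6] = 1  # two-column gap: even 8-connectivity cannot bridge
        frame = make_frame(px)
        assert len(find_candidates(make_mask(frame), frame)) == 2

    def test_single_pixel_metric_extent(self):
        px = np.zeros((4, 4), dtype=int)
        px[1, 1] = 3
        frame = make_frame(px, depth_max=2.0, metres_per_col=0.5)  # 0.5 m rows
        (cand,) = find_candidates(make_mask(frame), frame)
        assert cand.length_m == pytest.approx(0.5)
        assert cand.height_m == pytest.approx(0.5)

    def test_labelling_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            mask = rng.random((8, 8)) < 0.35
            frame = make_frame(mask.astype(int))
            got = {
                frozenset(zip(c.rows.tolist(), c.cols.tolist()))
                for c in find_candidates(mask, frame)
            }
            assert got == flood_fill_components(mask)


class TestFilterCandidates:
    def make(self, px, **kw):
        frame = make_frame(px, **kw)
        return frame, find_candidates(make_mask(frame), frame)

    def test_nearfield_rejection(self, mapping):
        px = np.zeros((30, 30), dtype=int)
        px[2:6, 5:15] = 7  # top edge at 2 m < 3 m
        frame, cands = self.make(px)
        kept, log = filter_candidates(cands, AggregationRules(), deep_seabed(frame), mapping, frame)
        assert kept == []
        assert log[0]["rule"] == "nearfield"

    def test_low_altitude_rejection(self, mapping):
        px = np.zeros((30, 30), dtype=int)
        px[20:25, 5:15] = 7
        frame, cands = self.make(px)
        seabed = deep_seabed(frame, row=25)  # zero clearance
        kept, log = filter_candidates(cands, AggregationRules(), seabed, mapping, frame)
        assert kept == []
        assert log[0]["rule"] == "altitude"

    def test_min_size_rejection(self, mapping):
        px = np.zeros((30, 30), dtype=int)
        px[10:13, 5] = 7  # 1 column wide -> L = 1.0 m is kept; use 0.5 m cols
        frame = make_frame(px, metres_per_col=0.5)
        cands = find_candidates(make_mask(frame), frame)
        kept, log = filter_candidates(cands, AggregationRules(), deep_seabed(frame), mapping, frame)
        assert kept == []
        assert log[0]["rule"] == "min_size"

    def test_sv_threshold_boundary(self):
        # one colour mapped exactly to -64.9 dB: retained; to -65.1: rejected
        px = np.zeros((30, 30), dtype=int)
        px[10:14, 5:12] = 1
        frame, cands = self.make(px)
        rules = AggregationRules()
        kept, _ = filter_candidates(
            cands, rules, deep_seabed(frame), PixelMapping(-64.9, 1.0), frame
        )
        assert len(kept) == 1
        kept, log = filter_candidates(
            cands, rules, deep_seabed(frame), PixelMapping(-65.1, 1.0), frame
        )
        assert kept == []
        assert log[0]["rule"] == "sv_threshold"

    def test_exact_threshold_retained(self):
        px = np.zeros((30, 30), dtype=int)
        px[10:14, 5:12] = 1
        frame, cands = self.make(px)
        kept, _ = filter_candidates(
            cands, AggregationRules(), deep_seabed(frame), PixelMapping(-65.0, 1.0), frame
        )
        assert len(kept) == 1


class TestLinkSchools:
    def two_blobs(self, gap_cols, mpr=1.0, mpc=1.0):
        a = np.zeros((40, 80), dtype=bool)
        a[10:20, 5:17] = True  # 12 x 10
        b = np.zeros_like(a)
        start = 17 + gap_cols
        b[10:20, start : start + 12] = True
        return (
            region_from_mask(a, mpr, mpc),
            region_from_mask(b, mpr, mpc),
        )

    def test_4m_gap_merges(self):
        cands = list(self.two_blobs(4))
        schools = link_schools(cands, AggregationRules())
        assert len(schools) == 1

    def test_6m_gap_does_not_merge(self):
        cands = list(self.two_blobs(6))
        schools = link_schools(cands, AggregationRules())
        assert len(schools) == 2

    def test_transitive_chain(self):
        a = np.zeros((40, 120), dtype=bool)
        a[10:20, 0:12] = True
        b = np.zeros_like(a)
        b[10:20, 16:28] = True  # 4 m gaps: A-B and B-C linkable
        c = np.zeros_like(a)
        c[10:20, 32:44] = True
        cands = [region_from_mask(m) for m in (a, b, c)]
        schools = link_schools(cands, AggregationRules())
        assert len(schools) == 1

    def test_vertical_gap_uses_short_axis(self):
        # 2 m vertical gap > 1 m semi-axis: no merge even though aligned
        a = np.zeros((40, 40), dtype=bool)
        a[5:11, 5:20] = True
        b = np.zeros_like(a)
        b[13:19, 5:20] = True  # rows 11,12 empty -> 2 m edge gap
        schools = link_schools(
            [region_from_mask(a), region_from_mask(b)], AggregationRules()
        )
        assert len(schools) == 2

    def test_small_aggregate_discarded(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:9, 5:11] = True  # 6 x 4 m < 10 x 5 minimum
        assert link_schools([region_from_mask(m)], AggregationRules()) == []

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        masks = []
        for i in range(5):
            m = np.zeros((60, 200), dtype=bool)
            c0 = 10 + 35 * i
            m[12:24, c0 : c0 + rng.integers(8, 16)] = True
            masks.append(m)
        cands = [region_from_mask(m) for m in masks]
        base = link_schools(cands, AggregationRules())
        base_sets = sorted(
            frozenset(zip(s.rows.tolist(), s.cols.tolist())) for s in base
        )
        for perm in itertools.permutations(range(5)):
            got = link_schools([cands[i] for i in perm], AggregationRules())
            got_sets = sorted(
                frozenset(zip(s.rows.tolist(), s.cols.tolist())) for s in got
            )
            assert got_sets == base_sets


class TestExtractParameters:
    def rect_frame(self, hole=False):
        px = np.zeros((40, 40), dtype=int)
        px[10:15, 5:15] = 4  # 10 x 5 m at 1 m/px
        if hole:
            px[12, 9] = 0
        return make_frame(px)

    def test_solid_rectangle_geometry(self):
        frame = self.rect_frame()
        (region,) = find_candidates(make_mask(frame), frame)
        s = extract_parameters(region, frame, deep_seabed(frame, row=30))
        assert s.area_m2 == pytest.approx(50.0)
        assert s.area_lv_m2 == pytest.approx(50.0)
        assert s.school_width_m == pytest.approx(10.0)
        assert s.school_height_m == pytest.approx(5.0)
        assert s.max_cal_diam_m == pytest.approx(np.sqrt(125.0))
        assert s.min_cal_diam_m <= s.max_cal_diam_m
        assert s.top_depth_m == pytest.approx(10.0)
        assert s.bot_depth_m == pytest.approx(30.0)
        assert s.mean_depth_m == pytest.approx(12.5)
        assert s.mean_altitude_m == pytest.approx(17.5)
        assert not s.truncated
        s.validate(n_mask_pixels=50)

    def test_vacuole_reduces_area_lv_only(self):
        frame = self.rect_frame(hole=True)
        (region,) = find_candidates(make_mask(frame), frame)
        s = extract_parameters(region, frame, deep_seabed(frame, row=30))
        assert s.area_m2 == pytest.approx(50.0)
        assert s.area_lv_m2 == pytest.approx(49.0)

    def test_perimeter_reasonable_on_disk(self):
        # corner-corrected boundary estimate within 8 % on a digitised disk
        r = 12
        yy, xx = np.mgrid[0:40, 0:40]
        px = (((yy - 20) ** 2 + (xx - 20) ** 2) <= r * r).astype(int) * 3
        frame = make_frame(px)
        (region,) = find_candidates(make_mask(frame), frame)
        s = extract_parameters(region, frame, deep_seabed(frame))
        assert s.perimeter_m == pytest.approx(2 * np.pi * r, rel=0.08)

    def test_feret_angle_of_diagonal_line(self):
        px = np.zeros((20, 20), dtype=int)
        for i in range(10):
            px[5 + i, 5 + i] = 2
        frame = make_frame(px)
        (region,) = find_candidates(make_mask(frame), frame)
        s = extract_parameters(region, frame, deep_seabed(frame))
        # depth axis points down: a down-right run slopes at -45 deg == 135
        assert s.max_cal_angle_deg == pytest.approx(135.0, abs=3.0)
        assert 0.0 <= s.max_cal_angle_deg < 180.0

    def test_truncated_flag_on_edge_contact(self):
        px = np.zeros((20, 20), dtype=int)
        px[0:5, 5:15] = 3
        frame = make_frame(px)
        (region,) = find_candidates(make_mask(frame), frame)
        s = extract_parameters(region, frame, deep_seabed(frame))
        assert s.truncated

    def test_pixel_counts_from_original_grid(self):
        frame = self.rect_frame()
        original = frame.pixels.copy()
        (region,) = find_candidates(make_mask(frame), frame)
        blurred = frame.copy()
        blurred.pixels[11, 6] = 1  # simulated despeckle alteration
        s = extract_parameters(region, blurred, deep_seabed(frame, row=30),
                               original_pixels=original)
        assert s.pixel_value_counts[4] == 50
        assert s.pixel_value_counts.sum() == 50

    def test_max_diameter_bounds_extents_property(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            mask = rng.random((10, 12)) < 0.4
            if not mask.any():
                continue
            frame = make_frame(mask.astype(int))
            for region in find_candidates(mask, frame):
                s = extract_parameters(region, frame, deep_seabed(frame))
                assert s.max_cal_diam_m >= max(s.school_width_m, s.school_height_m) - 1e-9
                assert s.min_cal_diam_m <= s.max_cal_diam_m + 1e-9
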