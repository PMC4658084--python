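"""Candidate detection, filtering, linking and descriptor extraction.

Connected echo-returns are grown into schools under gap-acceptance
rules: nearby candidates whose mutual gap fits inside a linking ellipse
are merged, then small aggregates are discarded.  Retained schools are
measured into the full descriptor schema (depths, altitudes, areas,
perimeter, calliper diameters, georeference, pixel histogram).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from echofish.echogram_model import EchogramFrame, School
from echofish.pixel_calibration import PixelMapping, school_mean_sv
from echofish.seabed_noise import SeabedPath


@dataclass(frozen=True)
class AggregationRules:
    """Exclusion and linking thresholds (metres / dB)."""

    link_ellipse_l_m: float = 10.0
    link_ellipse_h_m: float = 2.0
    min_school_l_m: float = 10.0
    min_school_h_m: float = 5.0
    min_candidate_l_m: float = 1.0
    min_candidate_h_m: float = 1.0
    min_depth_m: float = 3.0
    min_altitude_m: float = 0.5
    sv_threshold_db: float = -65.0

    def __post_init__(self):
        for name in (
            "link_ellipse_l_m",
            "link_ellipse_h_m",
            "min_school_l_m",
            "min_school_h_m",
            "min_candidate_l_m",
            "min_candidate_h_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CandidateRegion:
    """A connected component of the echo mask with metric geometry."""

    rows: np.ndarray
    cols: np.ndarray
    metres_per_row: float
    metres_per_col: float

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.rows.size == 0:
            raise ValueError("empty region")

    @property
    def r0(self) -> int:
        return int(self.rows.min())

    @property
    def r1(self) -> int:
        return int(self.rows.max())

    @property
    def c0(self) -> int:
        return int(self.cols.min())

    @property
    def c1(self) -> int:
        return int(self.cols.max())

    @property
    def length_m(self) -> float:
        return (self.c1 - self.c0 + 1) * self.metres_per_col

    @property
    def height_m(self) -> float:
        return (self.r1 - self.r0 + 1) * self.metres_per_row

    @property
    def n_pixels(self) -> int:
        return self.rows.size


def make_mask(frame: EchogramFrame) -> np.ndarray:
    """True where any echo is present (colour index > 0)."""
    return frame.pixels > 0


_STRUCT_8 = np.ones((3, 3), dtype=int)


def find_candidates(mask: np.ndarray, frame: EchogramFrame) -> list[CandidateRegion]:
    """Label 8-connected components and attach metric extents."""
    labels, n = ndimage.label(mask, structure=_STRUCT_8)
    out = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(labels == i)
        out.append(CandidateRegion(rr, cc, frame.metres_per_row, frame.metres_per_col))
    return out


def _min_altitude_m(region: CandidateRegion, frame: EchogramFrame, seabed: SeabedPath) -> float:
    """Smallest clearance between the region's bottom pixels and the seabed."""
    alt = np.inf
    for c in np.unique(region.cols):
        r_bot = region.rows[region.cols == c].max()
        gap_rows = seabed.row_per_col[c] - (r_bot + 1)
        alt = min(alt, gap_rows * frame.metres_per_row)
    return float(alt)


def filter_candidates(
    cands: list[CandidateRegion],
    rules: AggregationRules,
    seabed: SeabedPath,
    mapping: PixelMapping,
    frame: EchogramFrame,
) -> tuple[list[CandidateRegion], list[dict]]:
    """Apply the exclusion rules; every rejection is logged with its rule.

    Rules: top of candidate shallower than the nearfield limit; clearance
    above the seabed below the altitude floor; either metric extent below
    the candidate minimum; mean S_v below the retention threshold (values
    exactly at the threshold are retained).
    """
    kept, log = [], []
    for region in cands:
        top_depth = frame.depth_of_row_edge(region.r0)
        reason = None
        if top_depth < rules.min_depth_m:
            reason = "nearfield"
        elif _min_altitude_m(region, frame, seabed) < rules.min_altitude_m:
            reason = "altitude"
        elif region.length_m < rules.min_candidate_l_m or region.height_m < rules.min_candidate_h_m:
            reason = "min_size"
        else:
            counts = np.bincount(
                frame.pixels[region.rows, region.cols], minlength=frame.scale.n_colours
            )
            _, sv_db = school_mean_sv(counts, mapping)
            if sv_db < rules.sv_threshold_db:
                reason = "sv_threshold"
        if reason is None:
            kept.append(region)
        else:
            log.append(
                dict(rule=reason, r0=region.r0, r1=region.r1, c0=region.c0, c1=region.c1,
                     n_pixels=region.n_pixels)
            )
    return kept, log


def _gap_metric(a: CandidateRegion, b: CandidateRegion, semi_l: float, semi_h: float) -> float:
    """Minimum linking-ellipse metric over nearest pixel pairs.

    The gap between two pixels is measured edge-to-edge: adjacent pixels
    have zero gap.
    """
    mpc, mpr = a.metres_per_col, a.metres_per_row
    # bounding-box prefilter: lower bound on the metric
    dc = max(0, max(a.c0, b.c0) - min(a.c1, b.c1) - 1) * mpc
    dr = max(0, max(a.r0, b.r0) - min(a.r1, b.r1) - 1) * mpr
    lower = (dc / semi_l) ** 2 + (dr / semi_h) ** 2
    if lower > 1.0:
        return lower
    dcols = np.abs(a.cols[:, None] - b.cols[None, :]) - 1
    drows = np.abs(a.rows[:, None] - b.rows[None, :]) - 1
    gx = np.maximum(dcols, 0) * mpc / semi_l
    gz = np.maximum(drows, 0) * mpr / semi_h
    return float((gx**2 + gz**2).min())


def link_schools(
    cands: list[CandidateRegion], rules: AggregationRules
) -> list[CandidateRegion]:
    """Merge candidates whose nearest gap fits the linking ellipse.

    The stated L x H ellipse dimensions are full axis lengths; a pair
    links when  (dx/(L/2))^2 + (dz/(H/2))^2 <= 1  for the nearest pixel
    pair.  Linking is closed transitively; aggregates narrower than the
    minimum school size (either axis) are discarded.
    """
    n = len(cands)
    if n == 0:
        return []
    semi_l = rules.link_ellipse_l_m / 2.0
    semi_h = rules.link_ellipse_h_m / 2.0
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and _gap_metric(cands[i], cands[j], semi_l, semi_h) <= 1.0:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    schools = []
    for members in groups.values():
        rows = np.concatenate([cands[i].rows for i in members])
        cols = np.concatenate([cands[i].cols for i in members])
        merged = CandidateRegion(rows, cols, cands[members[0]].metres_per_row,
                                 cands[members[0]].metres_per_col)
        if merged.length_m >= rules.min_school_l_m and merged.height_m >= rules.min_school_h_m:
            schools.append(merged)
    schools.sort(key=lambda s: (s.c0, s.r0))
    return schools


# ---------------------------------------------------------------------------
# Descriptor extraction


def _pixel_corner_points(region: CandidateRegion) -> np.ndarray:
    """Metric (x, y) corner points of every pixel: x along pings, y depth-down."""
    mpc, mpr = region.metres_per_col, region.metres_per_row
    pts = []
    for dr in (0, 1):
        for dc in (0, 1):
            pts.append(
                np.column_stack(
                    [(region.cols + dc) * mpc, (region.rows + dr) * mpr]
                )
            )
    return np.unique(np.vstack(pts), axis=0)


def _feret(region: CandidateRegion) -> tuple[float, float, float]:
    """(max calliper diameter, perpendicular extent, angle deg in [0, 180))."""
    pts = _pixel_corner_points(region)
    hull_pts = pts[ConvexHull(pts).vertices]
    d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    vec = hull_pts[j] - hull_pts[i]
    dmax = float(np.sqrt(d2[i, j]))
    # angle measured from the horizontal (ping) axis; y points down, so negate
    ang = float(np.degrees(np.arctan2(-vec[1], vec[0]))) % 180.0
    perp = np.array([-vec[1], vec[0]]) / dmax
    proj = hull_pts @ perp
    return dmax, float(proj.max() - proj.min()), ang


def _perimeter_m(region: CandidateRegion, filled: np.ndarray) -> float:
    """Outer-boundary length via a sub-pixel contour of the filled mask."""
    padded = np.pad(filled, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    best = 0.0
    for c in contours:
        scaled = c * np.array([region.metres_per_row, region.metres_per_col])
        length = float(np.sqrt((np.diff(scaled, axis=0) ** 2).sum(axis=1)).sum())
        best = max(best, length)
    return best


def _fmt_time(ts: float) -> tuple[str, str]:
    t = _dt.datetime.fromtimestamp(ts, tz=_dt.timezone.utc)
    return t.strftime("%H:%M:%S"), t.strftime("%y/%m/%d")


def extract_parameters(
    region: CandidateRegion,
    frame: EchogramFrame,
    seabed: SeabedPath,
    original_pixels: np.ndarray | None = None,
) -> School:
    """Measure one aggregated school into the full descriptor schema.

    ``original_pixels`` supplies the pre-masking colour grid for the
    pixel histogram (defaults to the frame's current grid).  Schools
    touching a frame edge are flagged truncated.
    """
    mpc, mpr = frame.metres_per_col, frame.metres_per_row
    src = frame.pixels if original_pixels is None else original_pixels

    local = np.zeros((region.r1 - region.r0 + 1, region.c1 - region.c0 + 1), dtype=bool)
    local[region.rows - region.r0, region.cols - region.c0] = True
    filled = ndimage.binary_fill_holes(local)

    area_lv = region.n_pixels * mpr * mpc
    area = int(filled.sum()) * mpr * mpc

    top_depth = float(frame.depth_of_row_edge(region.r0))
    bottom_edge_depth = float(frame.depth_of_row_edge(region.r1 + 1))
    mean_depth = float(np.mean(frame.depth_of_row(region.rows)))

    centroid_col = int(round(region.cols.mean()))
    seabed_depth = float(frame.depth_of_row_edge(seabed.row_per_col[centroid_col]))

    dmax, dmin, angle = _feret(region)
    counts = np.bincount(src[region.rows, region.cols], minlength=frame.scale.n_colours)

    time_s, date_s = _fmt_time(float(frame.col_times[centroid_col]))
    truncated = (
        region.r0 == 0
        or region.r1 == frame.n_rows - 1
        or region.c0 == 0
        or region.c1 == frame.n_cols - 1
    )
    return School(
        file=frame.frame_file,
        time=time_s,
        date=date_s,
        pic_ref=frame.frame_file,
        lat_dd=float(frame.col_lats[centroid_col]),
        long_dd=float(frame.col_lons[centroid_col]),
        left_lat=float(frame.col_lats[region.c0]),
        left_lon=float(frame.col_lons[region.c0]),
        right_lat=float(frame.col_lats[region.c1]),
        right_lon=float(frame.col_lons[region.c1]),
        bot_altitude_m=seabed_depth - bottom_edge_depth,
        top_depth_m=top_depth,
        mean_altitude_m=seabed_depth - mean_depth,
        mean_depth_m=mean_depth,
        bot_depth_m=seabed_depth,
        school_height_m=region.height_m,
        school_width_m=region.length_m,
        area_m2=area,
        area_lv_m2=area_lv,
        perimeter_m=_perimeter_m(region, local | filled),
        max_cal_diam_m=dmax,
        min_cal_diam_m=dmin,
        max_cal_angle_deg=angle,
        pixel_value_counts=counts,
        truncated=truncated,
    )
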