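"""Ground-truthed synthetic surveys for closed-loop testing.

Generates echogram frames with a planted seabed, schools of known
geometry and backscatter, speckle and noise columns, plus paired
two-system school tables with a known colour mapping and saturation
ceiling.  Identical spec + seed always reproduces identical output.

Schools are rendered as corner-chamfered rectangles: that shape is
invariant under a 3x3 binary median, so despeckling does not nibble the
planted mask and pixel-exact recovery tests stay meaningful.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from echofish.echogram_model import ColourScale, EchogramFrame
from echofish.geo import EARTH_RADIUS_M, haversine_m
from echofish.pixel_calibration import (
    MatchedSchoolPair,
    PixelMapping,
    school_mean_sv,
    sv_db_to_linear,
)

KNOT_MS = 0.514444


@dataclass(frozen=True)
class SchoolSpec:
    """One planted school: position, geometry and backscatter."""

    along_m: float
    mean_depth_m: float
    length_m: float
    height_m: float
    mean_sv_db: float
    sv_spread_db: float = 0.0


@dataclass
class SurveySpec:
    seed: int = 0
    start_lat: float = -33.85
    start_lon: float = 25.70
    speed_kn: float = 7.0
    ping_interval_s: float = 0.5
    n_frames: int = 5
    frame_width_px: int = 120
    frame_height_px: int = 100
    overlap_cols: int = 0
    depth_min_m: float = 0.0
    depth_max_m: float = 50.0
    seabed_mean_m: float = 42.0
    seabed_amplitude_m: float = 3.0
    schools: list[SchoolSpec] = field(default_factory=list)
    speckle_density: float = 0.0
    noise_col_rate: float = 0.0
    noise_cols_avoid_schools: bool = True
    # 16 display colours at 2 dB/step span -65..-37 dB before saturating
    mapping: PixelMapping = field(default_factory=lambda: PixelMapping(-65.0, 2.0))
    n_colours: int = 16
    sv_max_db: float | None = None  # saturation ceiling before quantisation
    start_time: str = "2014-05-10T08:00:00+00:00"

    @property
    def metres_per_col(self) -> float:
        return self.speed_kn * KNOT_MS * self.ping_interval_s

    @property
    def metres_per_row(self) -> float:
        return (self.depth_max_m - self.depth_min_m) / self.frame_height_px

    @property
    def n_pings(self) -> int:
        return self.n_frames * self.frame_width_px - (self.n_frames - 1) * self.overlap_cols


def _chamfered_rectangle(r0: int, r1: int, c0: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a rectangle with its 4 corner pixels removed."""
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    if r1 > r0 and c1 > c0:
        corner = ((rr == r0) | (rr == r1)) & ((cc == c0) | (cc == c1))
        rr, cc = rr[~corner], cc[~corner]
    return rr, cc


def _render_school(
    grid: np.ndarray, spec: SurveySpec, school: SchoolSpec, rng: np.random.Generator
) -> dict:
    mpr, mpc = spec.metres_per_row, spec.metres_per_col
    n_rows_half = max(int(round(school.height_m / mpr)) // 2, 1)
    n_cols_half = max(int(round(school.length_m / mpc)) // 2, 1)
    rc = int(round((school.mean_depth_m - spec.depth_min_m) / mpr - 0.5))
    cc_ = int(round(school.along_m / mpc))
    r0, r1 = rc - n_rows_half, rc + n_rows_half
    c0, c1 = cc_ - n_cols_half, cc_ + n_cols_half
    if r0 < 0 or r1 >= grid.shape[0] or c0 < 0 or c1 >= grid.shape[1]:
        raise ValueError(f"school at {school.along_m} m falls outside the survey grid")
    rr, cc = _chamfered_rectangle(r0, r1, c0, c1)
    sv = rng.normal(school.mean_sv_db, school.sv_spread_db, rr.size)
    if spec.sv_max_db is not None:
        sv = np.minimum(sv, spec.sv_max_db)
    colours = spec.mapping.colour_of_sv(sv, spec.n_colours)
    grid[rr, cc] = colours
    counts = np.bincount(colours, minlength=spec.n_colours)
    return dict(
        r0=r0,
        r1=r1,
        c0=c0,
        c1=c1,
        n_pixels=rr.size,
        mean_depth_m=float(np.mean(spec.depth_min_m + (rr + 0.5) * mpr)),
        top_depth_m=spec.depth_min_m + r0 * mpr,
        height_m=(r1 - r0 + 1) * mpr,
        length_m=(c1 - c0 + 1) * mpc,
        area_lv_m2=rr.size * mpr * mpc,
        mean_sv_db=school.mean_sv_db,
        counts=counts,
    )


def _seabed_rows(spec: SurveySpec, rng: np.random.Generator) -> np.ndarray:
    mpr = spec.metres_per_row
    base = int(round((spec.seabed_mean_m - spec.depth_min_m) / mpr))
    amp_rows = max(int(round(spec.seabed_amplitude_m / mpr)), 1)
    steps = rng.choice([-1, 0, 1], size=spec.n_pings, p=[0.15, 0.7, 0.15])
    walk = np.cumsum(steps)
    walk = np.clip(walk, -amp_rows, amp_rows)
    rows = base + walk
    return np.clip(rows, 2, spec.frame_height_px - 2)


def generate_survey(
    spec: SurveySpec, out_dir: str | Path | None = None
) -> tuple[list[EchogramFrame], pd.DataFrame, pd.DataFrame, dict]:
    """Render a survey.

    Returns ``(frames, sidecar, truth, extras)`` where ``truth`` has one
    row per planted school (pixel-exact geometry in global-grid
    coordinates) and ``extras`` carries the seabed profile, noise-column
    indices and speckle coordinates.  With ``out_dir`` set, frames are
    written as palette PNGs next to a ``sidecar.csv`` so the ingestion
    path can be exercised end to end.
    """
    rng = np.random.default_rng(spec.seed)
    mpr, mpc = spec.metres_per_row, spec.metres_per_col
    grid = np.zeros((spec.frame_height_px, spec.n_pings), dtype=np.int64)

    seabed = _seabed_rows(spec, rng)
    top_colour = spec.n_colours - 1
    for c in range(spec.n_pings):
        s = seabed[c]
        grid[s : min(s + 3, spec.frame_height_px), c] = top_colour
        tail = spec.frame_height_px - min(s + 3, spec.frame_height_px)
        if tail > 0:
            # sub-bottom returns carry per-ping texture, which also keeps
            # columns unique so exact-match dedup only fires on true overlap
            grid[spec.frame_height_px - tail :, c] = rng.integers(
                1, min(4, spec.n_colours), tail
            )

    truth_rows = []
    for school in spec.schools:
        rec = _render_school(grid, spec, school, rng)
        if rec["r1"] + 1 >= seabed[rec["c0"] : rec["c1"] + 1].min():
            raise ValueError("planted school intersects the seabed")
        truth_rows.append(rec)

    # speckle: salt pixels in the water column above the seabed
    speckles = []
    if spec.speckle_density > 0:
        mask = rng.random(grid.shape) < spec.speckle_density
        rr, cc = np.nonzero(mask)
        keep = rr < seabed[cc] - 1
        rr, cc = rr[keep], cc[keep]
        keep = grid[rr, cc] == 0
        rr, cc = rr[keep], cc[keep]
        grid[rr, cc] = rng.integers(1, spec.n_colours, rr.size)
        speckles = list(zip(rr.tolist(), cc.tolist()))

    noise_cols = []
    if spec.noise_col_rate > 0:
        cand = np.flatnonzero(rng.random(spec.n_pings) < spec.noise_col_rate)
        if spec.noise_cols_avoid_schools:
            banned = np.zeros(spec.n_pings, dtype=bool)
            for rec in truth_rows:
                banned[max(rec["c0"] - 2, 0) : rec["c1"] + 3] = True
            cand = cand[~banned[cand]]
        for c in cand:
            grid[:, c] = np.maximum(grid[:, c], top_colour)
        noise_cols = cand.tolist()

    # cut into overlapping frames and georeference
    t0 = _dt.datetime.fromisoformat(spec.start_time).timestamp()
    lat0, lon0 = spec.start_lat, spec.start_lon
    dlon_per_m = 1.0 / (np.pi / 180.0 * EARTH_RADIUS_M * np.cos(np.radians(lat0)))
    col_times = t0 + np.arange(spec.n_pings) * spec.ping_interval_s
    col_lons = lon0 + np.arange(spec.n_pings) * mpc * dlon_per_m
    col_lats = np.full(spec.n_pings, lat0)

    stride = spec.frame_width_px - spec.overlap_cols
    scale = ColourScale(spec.n_colours)
    frames, sidecar_rows = [], []
    for f in range(spec.n_frames):
        g0 = f * stride
        g1 = g0 + spec.frame_width_px
        sl = slice(g0, g1)
        name = f"frame_{f:04d}.png"
        frames.append(
            EchogramFrame(
                pixels=grid[:, sl].copy(),
                depth_min_m=spec.depth_min_m,
                depth_max_m=spec.depth_max_m,
                col_times=col_times[sl].copy(),
                col_lats=col_lats[sl].copy(),
                col_lons=col_lons[sl].copy(),
                metres_per_col=mpc,
                scale=scale,
                frame_file=name,
            )
        )
        capture = _dt.datetime.fromtimestamp(col_times[g1 - 1], tz=_dt.timezone.utc)
        sidecar_rows.append(
            dict(
                frame_file=name,
                time_iso8601=capture.isoformat(),
                lat_dd=col_lats[g1 - 1],
                lon_dd=col_lons[g1 - 1],
                depth_min_m=spec.depth_min_m,
                depth_max_m=spec.depth_max_m,
            )
        )
    sidecar = pd.DataFrame(sidecar_rows)

    truth = pd.DataFrame(
        [
            dict(
                school=i,
                r0=r["r0"],
                r1=r["r1"],
                c0=r["c0"],
                c1=r["c1"],
                n_pixels=r["n_pixels"],
                mean_depth_m=r["mean_depth_m"],
                top_depth_m=r["top_depth_m"],
                height_m=r["height_m"],
                length_m=r["length_m"],
                area_lv_m2=r["area_lv_m2"],
                mean_sv_db=r["mean_sv_db"],
                lat=col_lats[int(round((r["c0"] + r["c1"]) / 2))],
                lon=col_lons[int(round((r["c0"] + r["c1"]) / 2))],
            )
            for i, r in enumerate(truth_rows)
        ]
    )
    extras = dict(
        seabed_rows=seabed,
        noise_cols=noise_cols,
        speckles=speckles,
        grid=grid,
        col_lats=col_lats,
        col_lons=col_lons,
        col_times=col_times,
        truth_counts=[r["counts"] for r in truth_rows],
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        palette = np.zeros((256, 3), dtype=np.uint8)
        shades = np.linspace(0, 255, spec.n_colours).astype(np.uint8)
        palette[: spec.n_colours] = shades[:, None]
        for fr in frames:
            img = Image.fromarray(fr.pixels.astype(np.uint8), mode="P")
            img.putpalette(palette.ravel().tolist())
            img.save(out_dir / fr.frame_file)
        sidecar.to_csv(out_dir / "sidecar.csv", index=False)
        truth.to_csv(out_dir / "truth.csv", index=False)
    return frames, sidecar, truth, extras


def default_school_field(
    spec: SurveySpec,
    n_schools: int,
    rng: np.random.Generator,
    sv_db_range: tuple[float, float] = (-58.0, -40.0),
) -> list[SchoolSpec]:
    """Non-overlapping schools spread along the survey, clear of the
    nearfield, the seabed and frame edges."""
    mpc = spec.metres_per_col
    usable = spec.n_pings * mpc
    slots = np.linspace(0.1, 0.9, n_schools) * usable
    schools = []
    for along in slots:
        length = float(rng.uniform(12.0, 25.0))
        height = float(rng.uniform(5.0, 9.0))
        max_depth = spec.seabed_mean_m - spec.seabed_amplitude_m - 2.0 - height / 2
        depth = float(rng.uniform(6.0 + height / 2, max_depth))
        schools.append(
            SchoolSpec(
                along_m=float(along),
                mean_depth_m=depth,
                length_m=length,
                height_m=height,
                mean_sv_db=float(rng.uniform(*sv_db_range)),
            )
        )
    return schools


# ---------------------------------------------------------------------------
# Paired two-system school tables


def generate_matched_pairs(
    seed: int,
    n_pairs: int = 36,
    mapping: PixelMapping | None = None,
    n_colours: int = 16,
    ceiling_db: float | None = None,
    sv_db_range: tuple[float, float] = (-54.0, -31.0),
    pixel_spread_db: float = 3.0,
    n_pixels_range: tuple[int, int] = (60, 400),
    relation: tuple[float, float] | None = None,
    relation_noise_sd: float = 0.0,
) -> list[MatchedSchoolPair]:
    """Paired reference/fish-finder schools with known generating process.

    School-level S_v is drawn normal in dB (lognormal in linear units)
    across ``sv_db_range``; per-pixel S_v scatters around it and is
    clipped at ``ceiling_db`` before quantisation through ``mapping``
    (hard clipping emulates display saturation).  The reference system
    records the unclipped linear mean.  With ``relation=(beta0, beta1)``
    the reference value is instead planted on the exponential curve
    log10(sv_ref) = beta0 + beta1 * sv_rff for regression-recovery tests.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    mapping = mapping or PixelMapping(-65.0, 1.3)
    rng = np.random.default_rng(seed)
    lo, hi = sv_db_range
    mid, spread = (lo + hi) / 2.0, (hi - lo) / 4.0
    pairs = []
    base = _dt.datetime.fromisoformat("2014-05-10T08:00:00+00:00").timestamp()
    for i in range(n_pairs):
        sv_school = float(np.clip(rng.normal(mid, spread), lo, hi))
        n_pix = int(rng.integers(*n_pixels_range))
        pix = rng.normal(sv_school, pixel_spread_db, n_pix)
        ses_lin = float(np.mean(sv_db_to_linear(pix)))
        if ceiling_db is not None:
            pix = np.minimum(pix, ceiling_db)
        colours = mapping.colour_of_sv(pix, n_colours)
        counts = np.bincount(colours, minlength=n_colours)
        if relation is not None:
            rff_lin, _ = school_mean_sv(counts, mapping)
            log10_ses = relation[0] + relation[1] * rff_lin
            if relation_noise_sd > 0:
                log10_ses += rng.normal(0.0, relation_noise_sd)
            ses_lin = float(10.0**log10_ses)
        t = _dt.datetime.fromtimestamp(base + 120.0 * i, tz=_dt.timezone.utc)
        pairs.append(
            MatchedSchoolPair(
                match_id=f"m{i:03d}",
                time=t.strftime("%H:%M:%S"),
                ses_sv_db=float(10.0 * np.log10(ses_lin)),
                rff_counts=counts,
                ses_mean_depth_m=float(rng.uniform(5.0, 55.0)),
                rff_mean_depth_m=np.nan,
                ses_area_m2=float(rng.uniform(25.0, 800.0)),
                rff_area_m2=np.nan,
            )
        )
    # paired descriptors track the reference values with mild noise
    for p in pairs:
        p.rff_mean_depth_m = p.ses_mean_depth_m + float(rng.normal(0.0, 1.0))
        p.rff_area_m2 = p.ses_area_m2 * float(np.exp(rng.normal(0.0, 0.2)))
    return pairs


def matched_pairs_to_tables(pairs: list[MatchedSchoolPair]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialise pairs into the matched-values and matched-parameters
    table dialects (per-colour count columns, ``SES_``/``RFF_`` prefixes)."""
    n_col = max(p.rff_counts.size for p in pairs)
    s5_rows, s6_rows = [], []
    for p in pairs:
        counts = np.zeros(n_col, dtype=int)
        counts[: p.rff_counts.size] = p.rff_counts
        row = dict(Match=p.match_id, Time=p.time, SES_Sv=p.ses_sv_db)
        row.update({f"PV{c}": int(counts[c]) for c in range(n_col)})
        s5_rows.append(row)
        s6_rows.append(
            dict(
                Match=p.match_id,
                Time=p.time,
                SES_MeanDepth=p.ses_mean_depth_m,
                RFF_MeanDepth=p.rff_mean_depth_m,
                SES_Area=p.ses_area_m2,
                RFF_Area=p.rff_area_m2,
                SES_Sv=p.ses_sv_db,
            )
        )
    return pd.DataFrame(s5_rows), pd.DataFrame(s6_rows)
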