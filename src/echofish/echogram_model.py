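"""Data model and I/O for echogram frames, tracks and the school table.

An echogram frame is a depth-by-ping grid of display colour indices
captured from a fish-finder screen, georeferenced per column through a
sidecar log.  Schools extracted from frames are serialised to a fixed
CSV schema (one column per descriptor plus one count column per colour
index).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from echofish.geo import haversine_m

#: Descriptor column headers of the school table, in file order.
SCHOOL_COLUMNS = [
    "File",
    "Time",
    "Date",
    "PicRef",
    "Lat_dd",
    "Long_dd",
    "LeftLat",
    "LeftLon",
    "RightLat",
    "RightLon",
    "BotAltitude",
    "TopDepth",
    "MeanAltitude",
    "MeanDepth",
    "BotDepth",
    "SchoolHeight",
    "SchoolWidth",
    "Area",
    "AreaLV",
    "Perimeter",
    "MaxCalDiam",
    "MinCalDiam",
    "MaxCalAngle",
]

SIDECAR_COLUMNS = [
    "frame_file",
    "time_iso8601",
    "lat_dd",
    "lon_dd",
    "depth_min_m",
    "depth_max_m",
]


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


@dataclass(frozen=True)
class ColourScale:
    """Sequential display colour scale: index 0 weakest, n_colours-1 strongest."""

    n_colours: int

    def __post_init__(self):
        if self.n_colours < 2:
            raise ValueError(f"need at least 2 colours, got {self.n_colours}")

    @property
    def max_index(self) -> int:
        return self.n_colours - 1


@dataclass(frozen=True, order=True)
class TrackFix:
    """One timestamped position fix."""

    time: float  # seconds since the Unix epoch
    lat: float
    lon: float

    def __post_init__(self):
        if not (abs(self.lat) <= 90.0 and abs(self.lon) <= 180.0):
            raise ValueError(f"fix out of range: lat={self.lat} lon={self.lon}")


@dataclass
class EchogramFrame:
    """One screen frame: colour-index grid plus per-column geometry.

    Row 0 is the shallowest depth sample, column 0 the oldest ping.
    """

    pixels: np.ndarray  # (rows, cols) integer colour indices
    depth_min_m: float
    depth_max_m: float
    col_times: np.ndarray  # (cols,) seconds since epoch, non-decreasing
    col_lats: np.ndarray
    col_lons: np.ndarray
    metres_per_col: float
    scale: ColourScale
    frame_file: str = ""
    dedup_removed_cols: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D (rows x cols)")
        if not self.depth_max_m > self.depth_min_m >= 0:
            raise ValueError(
                f"invalid depth range [{self.depth_min_m}, {self.depth_max_m}]"
            )
        for name in ("col_times", "col_lats", "col_lons"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.pixels.shape[1],):
                raise ValueError(f"{name} must have one entry per column")
            setattr(self, name, arr)
        if np.any(np.diff(self.col_times) < 0):
            raise ValueError("col_times must be non-decreasing")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def metres_per_row(self) -> float:
        return (self.depth_max_m - self.depth_min_m) / self.n_rows

    def depth_of_row(self, row) -> np.ndarray | float:
        """Depth at the pixel centre of ``row`` (pixel-centre convention)."""
        return self.depth_min_m + (np.asarray(row) + 0.5) * self.metres_per_row

    def depth_of_row_edge(self, row) -> np.ndarray | float:
        """Depth of the upper edge of ``row``."""
        return self.depth_min_m + np.asarray(row) * self.metres_per_row

    def copy(self) -> "EchogramFrame":
        return replace(
            self,
            pixels=self.pixels.copy(),
            col_times=self.col_times.copy(),
            col_lats=self.col_lats.copy(),
            col_lons=self.col_lons.copy(),
        )


@dataclass
class School:
    """One extracted school record (fixed descriptor schema)."""

    file: str
    time: str  # HH:MM:SS
    date: str  # YY/MM/DD
    pic_ref: str
    lat_dd: float
    long_dd: float
    left_lat: float
    left_lon: float
    right_lat: float
    right_lon: float
    bot_altitude_m: float
    top_depth_m: float
    mean_altitude_m: float
    mean_depth_m: float
    bot_depth_m: float
    school_height_m: float
    school_width_m: float
    area_m2: float
    area_lv_m2: float
    perimeter_m: float
    max_cal_diam_m: float
    min_cal_diam_m: float
    max_cal_angle_deg: float
    pixel_value_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    truncated: bool = False  # touches a frame edge; not serialised

    def validate(self, n_mask_pixels: int | None = None, atol: float = 1e-6) -> None:
        """Raise ValueError on any violated internal consistency rule."""
        if not (
            self.top_depth_m
            <= self.mean_depth_m + atol
            and self.mean_depth_m
            <= self.top_depth_m + self.school_height_m + atol
            and self.top_depth_m + self.school_height_m <= self.bot_depth_m + atol
        ):
            raise ValueError("depth ordering violated")
        if abs(self.mean_altitude_m - (self.bot_depth_m - self.mean_depth_m)) > atol:
            raise ValueError("mean altitude inconsistent with depths")
        if not (0 < self.area_lv_m2 <= self.area_m2 + atol):
            raise ValueError("area ordering violated")
        if self.min_cal_diam_m > self.max_cal_diam_m + atol:
            raise ValueError("diameter ordering violated")
        if self.max_cal_diam_m + atol < max(self.school_width_m, self.school_height_m):
            raise ValueError("max diameter smaller than bounding extents")
        if n_mask_pixels is not None and int(self.pixel_value_counts.sum()) != n_mask_pixels:
            raise ValueError("pixel counts do not sum to mask size")


# ---------------------------------------------------------------------------
# Frame ingestion


def _quantise_image(path: Path, scale: ColourScale, palette: np.ndarray | None) -> np.ndarray:
    img = Image.open(path)
    if img.mode == "P":
        idx = np.asarray(img, dtype=np.int64)
    elif palette is not None:
        rgb = np.asarray(img.convert("RGB"), dtype=np.int64)
        pal = np.asarray(palette, dtype=np.int64)
        d2 = ((rgb[:, :, None, :] - pal[None, None, :, :]) ** 2).sum(axis=-1)
        idx = d2.argmin(axis=-1)
    else:
        # single-channel rasters carry the index directly
        arr = np.asarray(img.convert("L"), dtype=np.int64)
        idx = arr
    bad = idx[(idx < 0) | (idx > scale.max_index)]
    if bad.size:
        raise ValueError(
            f"{path.name}: pixel value {int(bad[0])} outside palette of "
            f"{scale.n_colours} colours"
        )
    return idx


def _overlap_width(prev: np.ndarray, next: np.ndarray) -> int:
    """Longest k with prev[:, -k:] == next[:, :k] (exact column match)."""
    if prev.shape[0] != next.shape[0]:
        raise ValueError("frames have different row counts")
    for k in range(min(prev.shape[1], next.shape[1]), 0, -1):
        if np.array_equal(prev[:, prev.shape[1] - k :], next[:, :k]):
            return k
    return 0


def read_frames(
    image_paths: Sequence[str | Path],
    sidecar: str | Path | pd.DataFrame,
    scale: ColourScale,
    palette: np.ndarray | None = None,
    dedup: bool = True,
) -> list[EchogramFrame]:
    """Load echogram frames and georeference their columns.

    ``sidecar`` holds one row per frame (``frame_file, time_iso8601,
    lat_dd, lon_dd, depth_min_m, depth_max_m``) giving the capture fix,
    anchored at the frame's last (newest) column.  With ``dedup`` on,
    columns repeating the tail of the previous frame are stripped first,
    so per-column times/positions interpolate exactly between frame
    fixes regardless of screen overlap.  The first frame extrapolates
    backwards at the second frame's rate.
    """
    if isinstance(sidecar, (str, Path)):
        sidecar = pd.read_csv(sidecar)
    missing = set(SIDECAR_COLUMNS) - set(sidecar.columns)
    if missing:
        raise SchemaError(f"sidecar missing columns: {sorted(missing)}")
    rows = sidecar.set_index("frame_file")

    metas = []
    for p in map(Path, image_paths):
        if p.name not in rows.index:
            raise ValueError(f"no sidecar row for frame {p.name!r}")
        rec = rows.loc[p.name]
        t = _dt.datetime.fromisoformat(str(rec["time_iso8601"]))
        if t.tzinfo is None:
            t = t.replace(tzinfo=_dt.timezone.utc)
        metas.append(
            dict(
                path=p,
                time=t.timestamp(),
                fix=TrackFix(t.timestamp(), float(rec["lat_dd"]), float(rec["lon_dd"])),
                depth_min=float(rec["depth_min_m"]),
                depth_max=float(rec["depth_max_m"]),
            )
        )
    times = [m["time"] for m in metas]
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")

    grids = [_quantise_image(m["path"], scale, palette) for m in metas]
    removed = [0] * len(grids)
    if dedup:
        for i in range(1, len(grids)):
            k = _overlap_width(grids[i - 1], grids[i])
            removed[i] = k
            grids[i] = grids[i][:, k:]

    # per-frame column spacing between consecutive capture fixes
    dts, dlats, dlons, speeds = [], [], [], []
    for i, meta in enumerate(metas):
        ncols = grids[i].shape[1]
        if ncols == 0:
            raise ValueError(f"frame {meta['path'].name} fully duplicated")
        if i > 0:
            prev = metas[i - 1]
            span = meta["time"] - prev["time"]
            dts.append(span / ncols)
            dlats.append((meta["fix"].lat - prev["fix"].lat) / ncols)
            dlons.append((meta["fix"].lon - prev["fix"].lon) / ncols)
            speeds.append(
                haversine_m(prev["fix"].lat, prev["fix"].lon, meta["fix"].lat, meta["fix"].lon)
                / span
            )
        else:
            dts.append(np.nan)
            dlats.append(np.nan)
            dlons.append(np.nan)
            speeds.append(np.nan)
    if len(metas) > 1:
        dts[0], dlats[0], dlons[0], speeds[0] = dts[1], dlats[1], dlons[1], speeds[1]
    else:
        dts[0], dlats[0], dlons[0], speeds[0] = 1.0, 0.0, 0.0, 0.0

    frames: list[EchogramFrame] = []
    for i, meta in enumerate(metas):
        ncols = grids[i].shape[1]
        # anchor at the last column; step back dt per column
        j = np.arange(ncols) - (ncols - 1)
        frames.append(
            EchogramFrame(
                pixels=grids[i],
                depth_min_m=meta["depth_min"],
                depth_max_m=meta["depth_max"],
                col_times=meta["time"] + j * dts[i],
                col_lats=meta["fix"].lat + j * dlats[i],
                col_lons=meta["fix"].lon + j * dlons[i],
                metres_per_col=float(speeds[i] * dts[i]),
                scale=scale,
                frame_file=meta["path"].name,
                dedup_removed_cols=removed[i],
            )
        )
    return frames


def dedup_overlap(prev: EchogramFrame, next: EchogramFrame) -> EchogramFrame:
    """Strip from ``next`` its leading columns that exactly repeat the
    trailing columns of ``prev`` (longest exact match wins)."""
    if (prev.depth_min_m, prev.depth_max_m) != (next.depth_min_m, next.depth_max_m):
        raise ValueError("frames have different depth ranges; rescale first")
    if prev.scale != next.scale:
        raise ValueError("frames use different colour scales")
    k = _overlap_width(prev.pixels, next.pixels)
    if k == 0:
        out = next.copy()
        out.dedup_removed_cols = 0
        return out
    return replace(
        next,
        pixels=next.pixels[:, k:].copy(),
        col_times=next.col_times[k:].copy(),
        col_lats=next.col_lats[k:].copy(),
        col_lons=next.col_lons[k:].copy(),
        dedup_removed_cols=k,
    )


# ---------------------------------------------------------------------------
# School table serialisation


def _pixel_columns(n: int) -> list[str]:
    return [f"PV{c}" for c in range(n)]


def write_school_table(schools: Iterable[School], path: str | Path, n_colours: int | None = None) -> None:
    schools = list(schools)
    if n_colours is None:
        n_colours = max((s.pixel_value_counts.size for s in schools), default=0)
    recs = []
    for s in schools:
        rec = dict(
            File=s.file,
            Time=s.time,
            Date=s.date,
            PicRef=s.pic_ref,
            Lat_dd=s.lat_dd,
            Long_dd=s.long_dd,
            LeftLat=s.left_lat,
            LeftLon=s.left_lon,
            RightLat=s.right_lat,
            RightLon=s.right_lon,
            BotAltitude=s.bot_altitude_m,
            TopDepth=s.top_depth_m,
            MeanAltitude=s.mean_altitude_m,
            MeanDepth=s.mean_depth_m,
            BotDepth=s.bot_depth_m,
            SchoolHeight=s.school_height_m,
            SchoolWidth=s.school_width_m,
            Area=s.area_m2,
            AreaLV=s.area_lv_m2,
            Perimeter=s.perimeter_m,
            MaxCalDiam=s.max_cal_diam_m,
            MinCalDiam=s.min_cal_diam_m,
            MaxCalAngle=s.max_cal_angle_deg,
        )
        counts = np.zeros(n_colours, dtype=int)
        counts[: s.pixel_value_counts.size] = s.pixel_value_counts
        rec.update(dict(zip(_pixel_columns(n_colours), counts)))
        recs.append(rec)
    df = pd.DataFrame(recs, columns=SCHOOL_COLUMNS + _pixel_columns(n_colours))
    df.to_csv(path, index=False)


def read_school_table(path: str | Path) -> list[School]:
    df = pd.read_csv(path)
    pv_cols = sorted(
        (c for c in df.columns if c.startswith("PV") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    expected = set(SCHOOL_COLUMNS)
    got = set(df.columns) - set(pv_cols)
    if got != expected:
        missing, extra = sorted(expected - got), sorted(got - expected)
        raise SchemaError(f"school table schema mismatch: missing={missing} extra={extra}")
    out = []
    for _, r in df.iterrows():
        out.append(
            School(
                file=str(r["File"]),
                time=str(r["Time"]),
                date=str(r["Date"]),
                pic_ref=str(r["PicRef"]),
                lat_dd=float(r["Lat_dd"]),
                long_dd=float(r["Long_dd"]),
                left_lat=float(r["LeftLat"]),
                left_lon=float(r["LeftLon"]),
                right_lat=float(r["RightLat"]),
                right_lon=float(r["RightLon"]),
                bot_altitude_m=float(r["BotAltitude"]),
                top_depth_m=float(r["TopDepth"]),
                mean_altitude_m=float(r["MeanAltitude"]),
                mean_depth_m=float(r["MeanDepth"]),
                bot_depth_m=float(r["BotDepth"]),
                school_height_m=float(r["SchoolHeight"]),
                school_width_m=float(r["SchoolWidth"]),
                area_m2=float(r["Area"]),
                area_lv_m2=float(r["AreaLV"]),
                perimeter_m=float(r["Perimeter"]),
                max_cal_diam_m=float(r["MaxCalDiam"]),
                min_cal_diam_m=float(r["MinCalDiam"]),
                max_cal_angle_deg=float(r["MaxCalAngle"]),
                pixel_value_counts=r[pv_cols].to_numpy(dtype=int) if pv_cols else np.zeros(0, int),
            )
        )
    return out


def schools_to_frame(schools: Iterable[School]) -> pd.DataFrame:
    """Tabular view of a school list (descriptor columns only)."""
    return pd.DataFrame(
        [
            {
                "File": s.file,
                "Time": s.time,
                "Date": s.date,
                "PicRef": s.pic_ref,
                "Lat_dd": s.lat_dd,
                "Long_dd": s.long_dd,
                "MeanDepth": s.mean_depth_m,
                "SchoolHeight": s.school_height_m,
                "SchoolWidth": s.school_width_m,
                "Area": s.area_m2,
            }
            for s in schools
        ]
    )
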