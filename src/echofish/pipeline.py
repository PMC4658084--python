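"""End-to-end frame processing: noise mitigation through school tables."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from echofish.echogram_model import EchogramFrame, School, dedup_overlap
from echofish.pixel_calibration import PixelMapping
from echofish.school_extraction import (
    AggregationRules,
    extract_parameters,
    filter_candidates,
    find_candidates,
    link_schools,
    make_mask,
)
from echofish.seabed_noise import (
    DEFAULT_COLUMN_Z,
    DEFAULT_EDGE_THRESHOLD,
    DEFAULT_LAMBDA,
    DEFAULT_P,
    despeckle,
    detect_upper_edges,
    mask_below_seabed,
    remove_noise_columns,
    trace_seabed,
)


@dataclass
class PipelineConfig:
    edge_threshold: int = DEFAULT_EDGE_THRESHOLD
    lam: float = DEFAULT_LAMBDA
    P: int = DEFAULT_P
    seabed_margin_m: float = 0.0
    despeckle_kernel: int | None = 3
    column_z: float | None = DEFAULT_COLUMN_Z
    rules: AggregationRules = field(default_factory=AggregationRules)
    mapping: PixelMapping = field(default_factory=lambda: PixelMapping(-65.0, 1.3))


def concat_frames(frames: list[EchogramFrame]) -> EchogramFrame:
    """Mosaic deduplicated contiguous frames into one wide frame so that
    schools straddling frame boundaries are segmented whole."""
    if not frames:
        raise ValueError("no frames")
    f0 = frames[0]
    for f in frames[1:]:
        if (f.depth_min_m, f.depth_max_m) != (f0.depth_min_m, f0.depth_max_m):
            raise ValueError("frames have different depth ranges")
        if f.scale != f0.scale:
            raise ValueError("frames use different colour scales")
    return replace(
        f0,
        pixels=np.hstack([f.pixels for f in frames]),
        col_times=np.concatenate([f.col_times for f in frames]),
        col_lats=np.concatenate([f.col_lats for f in frames]),
        col_lons=np.concatenate([f.col_lons for f in frames]),
        metres_per_col=float(np.mean([f.metres_per_col for f in frames])),
        frame_file=f0.frame_file,
    )


def apply_exclusions(regions, frame: EchogramFrame, exclusions: pd.DataFrame | None):
    """Drop regions intersecting any declared exclusion box.

    ``exclusions`` columns: frame, col_min, col_max, row_min, row_max
    (pixel coordinates, inclusive).  Replaces the interactive review
    deletion of anomalies.
    """
    if exclusions is None or exclusions.empty:
        return list(regions), []
    kept, dropped = [], []
    boxes = exclusions[exclusions["frame"].isin([frame.frame_file, "*"])]
    for reg in regions:
        hit = False
        for _, b in boxes.iterrows():
            inter = (
                reg.c1 >= b["col_min"]
                and reg.c0 <= b["col_max"]
                and reg.r1 >= b["row_min"]
                and reg.r0 <= b["row_max"]
            )
            if inter:
                hit = True
                break
        if hit:
            dropped.append(reg)
        else:
            kept.append(reg)
    return kept, dropped


def process_frame(
    frame: EchogramFrame,
    config: PipelineConfig | None = None,
    exclusions: pd.DataFrame | None = None,
) -> tuple[list[School], list[dict], list[int]]:
    """Run the full processing chain on one (possibly mosaicked) frame.

    Order: upper edges -> seabed trace -> sub-seabed mask -> despeckle ->
    noise-column removal -> mask -> candidates -> exclusion boxes ->
    filters -> linking -> descriptor extraction.  Returns (schools,
    rejection log, removed column indices).
    """
    config = config or PipelineConfig()
    edges = detect_upper_edges(frame, config.edge_threshold)
    seabed = trace_seabed(edges, config.lam, config.P)
    cleaned = mask_below_seabed(frame, seabed, config.seabed_margin_m)
    original = cleaned.pixels.copy()  # pre-despeckle colours for histograms
    if config.despeckle_kernel is not None:
        cleaned = despeckle(cleaned, config.despeckle_kernel)
        # despeckling must not reach below the seabed
        cleaned = mask_below_seabed(cleaned, seabed, config.seabed_margin_m)
    removed_cols: list[int] = []
    if config.column_z is not None and cleaned.n_cols >= 3:
        cleaned, removed_cols = remove_noise_columns(cleaned, config.column_z)
    mask = make_mask(cleaned)
    cands = find_candidates(mask, cleaned)
    cands, excluded = apply_exclusions(cands, frame, exclusions)
    log = [
        dict(rule="exclusion_box", r0=r.r0, r1=r.r1, c0=r.c0, c1=r.c1, n_pixels=r.n_pixels)
        for r in excluded
    ]
    kept, rej = filter_candidates(cands, config.rules, seabed, config.mapping, cleaned)
    log.extend(rej)
    schools = []
    for reg in link_schools(kept, config.rules):
        schools.append(extract_parameters(reg, cleaned, seabed, original_pixels=original))
    return schools, log, removed_cols


def process_survey(
    frames: list[EchogramFrame],
    config: PipelineConfig | None = None,
    exclusions: pd.DataFrame | None = None,
    mosaic: bool = True,
) -> tuple[list[School], list[dict], list[int]]:
    """Process a contiguous frame sequence (mosaicked by default).

    Overlapping duplicate columns between consecutive frames are removed
    first.
    """
    deduped = frames[:1]
    for f in frames[1:]:
        deduped.append(dedup_overlap(deduped[-1], f))
    frames = deduped
    if mosaic:
        return process_frame(concat_frames(frames), config, exclusions)
    schools, log, cols = [], [], []
    for f in frames:
        s, l, c = process_frame(f, config, exclusions)
        schools.extend(s)
        log.extend(l)
        cols.extend(c)
    return schools, log, cols
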