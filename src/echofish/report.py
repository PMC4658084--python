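"""Headline summary statistics recomputed from deposited school tables.

Each function recomputes one published quantity from the survey's
deposited CSVs: the per-system school tables (full descriptor schema
plus per-colour count columns, and a mean S_v column for the reference
system), the matched-values table (``Match, Time, SES_Sv, PV*``) and the
matched-parameters table (``SES_``/``RFF_`` prefixed descriptors).
``compute_all`` runs whatever the supplied directory contains.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from echofish.abundance import (
    SchoolDensity,
    assign_edsus,
    detection_table,
    matched_descriptor_fit,
    rolling_scale_concordance,
)
from echofish.pixel_calibration import (
    BASELINE_START_DB,
    MatchedSchoolPair,
    PixelMapping,
    apply_correction,
    fit_correction,
    grid_search_mapping,
    pixel_skewness,
    school_mean_sv,
    select_scenarios,
    sv_db_to_linear,
)

SES_SV_COLUMN = "Sv_mean"


def load_matched_pairs(s5: pd.DataFrame, s6: pd.DataFrame | None = None) -> list[MatchedSchoolPair]:
    """Build matched pairs from the matched-values table (optionally
    joined with the matched-parameters table on ``Match``)."""
    pv_cols = sorted(
        (c for c in s5.columns if c.startswith("PV") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    if not pv_cols:
        raise ValueError("matched-values table has no PV pixel-count columns")
    s6_idx = s6.set_index("Match") if s6 is not None else None
    pairs = []
    for _, r in s5.iterrows():
        extra = {}
        if s6_idx is not None and r["Match"] in s6_idx.index:
            row6 = s6_idx.loc[r["Match"]]
            extra = dict(
                ses_mean_depth_m=float(row6.get("SES_MeanDepth", np.nan)),
                rff_mean_depth_m=float(row6.get("RFF_MeanDepth", np.nan)),
                ses_area_m2=float(row6.get("SES_Area", np.nan)),
                rff_area_m2=float(row6.get("RFF_Area", np.nan)),
            )
        pairs.append(
            MatchedSchoolPair(
                match_id=str(r["Match"]),
                time=str(r.get("Time", "")),
                ses_sv_db=float(r["SES_Sv"]),
                rff_counts=r[pv_cols].to_numpy(dtype=int),
                **extra,
            )
        )
    return pairs


def scenario_mappings(pairs: list[MatchedSchoolPair]) -> list[PixelMapping]:
    """Optimal baseline-start mapping per skewness scenario (min/zero/max)."""
    idx = select_scenarios(pairs)
    out = []
    for i in idx:
        _, step = grid_search_mapping(pairs[i])
        out.append(PixelMapping(BASELINE_START_DB, step))
    return out


# --- matched-school descriptor agreement -----------------------------------


def depth_regression_r2(s6: pd.DataFrame) -> float:
    _, _, r2 = matched_descriptor_fit(s6["RFF_MeanDepth"], s6["SES_MeanDepth"])
    return r2


def area_regression_r2(s6: pd.DataFrame) -> float:
    _, _, r2 = matched_descriptor_fit(s6["RFF_Area"], s6["SES_Area"], log_transform=True)
    return r2


def mean_reference_depth(s6: pd.DataFrame) -> float:
    return float(np.mean(s6["SES_MeanDepth"]))


# --- calibration chain ------------------------------------------------------


def scenario_step(pairs: list[MatchedSchoolPair], scenario: int) -> float:
    """Optimal colour step at the baseline start for scenario 1, 2 or 3."""
    idx = select_scenarios(pairs)[scenario - 1]
    _, step = grid_search_mapping(pairs[idx])
    return step


def corrected_sv_median(pairs: list[MatchedSchoolPair], mapping: PixelMapping) -> float:
    model = fit_correction(pairs, mapping)
    sv_rff = np.array([school_mean_sv(p.rff_counts, mapping)[0] for p in pairs])
    _, sv_db = apply_correction(model, sv_rff)
    return float(np.median(sv_db))


def depth_dependence_r2_pct(pairs: list[MatchedSchoolPair], mapping: PixelMapping) -> float:
    from echofish.pixel_calibration import depth_dependence

    sv = np.array([school_mean_sv(p.rff_counts, mapping)[0] for p in pairs])
    depth = np.array([p.rff_mean_depth_m for p in pairs])
    _, _, r2 = depth_dependence(sv, depth)
    return 100.0 * r2


def max_skewness(pairs: list[MatchedSchoolPair]) -> float:
    from echofish.pixel_calibration import skewness_or_nan

    vals = [skewness_or_nan(p.rff_counts) for p in pairs]
    return float(np.nanmax(vals))


# --- abundance chain --------------------------------------------------------


def _school_sort_key(df: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(
        df["Date"].astype(str) + " " + df["Time"].astype(str),
        format="%y/%m/%d %H:%M:%S",
    )


def build_track(*tables: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Survey track approximated by the time-ordered union of school fixes."""
    merged = pd.concat(
        [t[["Date", "Time", "Lat_dd", "Long_dd"]] for t in tables], ignore_index=True
    )
    merged = merged.assign(_t=_school_sort_key(merged)).sort_values("_t")
    return merged["Lat_dd"].to_numpy(float), merged["Long_dd"].to_numpy(float)


def school_densities(
    table: pd.DataFrame,
    mapping: PixelMapping | None = None,
    correction=None,
    sv_column: str = SES_SV_COLUMN,
) -> list[SchoolDensity]:
    """Per-school echo-integration inputs from a deposited school table.

    Reference-system tables carry mean S_v directly (``sv_column``);
    fish-finder tables are mapped from their pixel histograms and
    optionally passed through the saturation correction.
    """
    pv_cols = sorted(
        (c for c in table.columns if c.startswith("PV") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    out = []
    for _, r in table.iterrows():
        if mapping is None:
            sv_lin = float(sv_db_to_linear(float(r[sv_column])))
        else:
            sv_lin, _ = school_mean_sv(r[pv_cols].to_numpy(dtype=int), mapping)
            if correction is not None:
                sv_lin = float(correction.predict_sv_linear(sv_lin))
        out.append(
            SchoolDensity(
                lat=float(r["Lat_dd"]),
                lon=float(r["Long_dd"]),
                sv_linear=sv_lin,
                height_m=float(r["SchoolHeight"]),
                width_m=float(r["SchoolWidth"]),
            )
        )
    return out


def survey_edsus(
    ses_table: pd.DataFrame,
    rff_table: pd.DataFrame,
    mapping: PixelMapping,
    correction,
):
    track_lats, track_lons = build_track(ses_table, rff_table)
    return assign_edsus(
        {
            "ses": school_densities(ses_table),
            "rff": school_densities(rff_table, mapping=mapping, correction=correction),
        },
        track_lats,
        track_lons,
    )


def fish_bearing_sa_median(edsus, system: str) -> float:
    vals = [e.sa(system) for e in edsus if e.present(system)]
    if not vals:
        raise ValueError(f"no fish-bearing units for {system}")
    return float(np.median(vals))


# --- orchestration ----------------------------------------------------------

SUPPLEMENTARY_FILES = {
    "s3": "S3_File.csv",
    "s4": "S4_File.csv",
    "s5": "S5_File.csv",
    "s6": "S6_File.csv",
}


def compute_all(data_dir: str | Path) -> tuple[dict, list[str]]:
    """Compute every available headline quantity from ``data_dir``.

    Returns ``(results, notes)``: results keyed t1..t11 as
    ``{"value": ..., "n": ...}``; notes list what was skipped and why.
    """
    data_dir = Path(data_dir)
    tables: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    for key, fname in SUPPLEMENTARY_FILES.items():
        path = data_dir / fname
        if path.exists():
            tables[key] = pd.read_csv(path)
        else:
            notes.append(f"{fname} not found under {data_dir}")

    results: dict[str, dict] = {}

    def put(tid, value, n):
        results[tid] = {"value": float(value), "n": int(n)}

    if "s6" in tables:
        s6 = tables["s6"]
        put("t1", round(depth_regression_r2(s6), 2), len(s6))
        put("t2", round(area_regression_r2(s6), 2), len(s6))
        put("t3", round(mean_reference_depth(s6), 1), len(s6))
    if "s5" in tables:
        pairs = load_matched_pairs(tables["s5"], tables.get("s6"))
        put("t4", scenario_step(pairs, 2), len(pairs))
        step1 = scenario_step(pairs, 1)
        put("t5", round(corrected_sv_median(pairs, PixelMapping(BASELINE_START_DB, step1)), 1), len(pairs))
        put("t11", round(max_skewness(pairs), 1), len(pairs))
        if "s6" in tables:
            step2 = scenario_step(pairs, 2)
            put(
                "t6",
                round(depth_dependence_r2_pct(pairs, PixelMapping(BASELINE_START_DB, step2))),
                len(pairs),
            )
    if {"s3", "s4", "s5"} <= tables.keys():
        pairs = load_matched_pairs(tables["s5"], tables.get("s6"))
        step2 = scenario_step(pairs, 2)
        mapping2 = PixelMapping(BASELINE_START_DB, step2)
        model = fit_correction(pairs, mapping2)
        edsus = survey_edsus(tables["s3"], tables["s4"], mapping2, model)
        put("t7", round(fish_bearing_sa_median(edsus, "rff"), 1), len(edsus))
        put("t8", round(fish_bearing_sa_median(edsus, "ses"), 1), len(edsus))
        fits = rolling_scale_concordance(edsus, scales_km=[12.5])
        if fits:
            put("t9", round(100.0 * fits[0].r2), fits[0].n_windows)
        table, _, _ = detection_table(edsus)
        put("t10", table.loc["no rff", "ses"], len(edsus))
    return results, notes
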