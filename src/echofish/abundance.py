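"""Echo-integration per 500 m track unit and multi-scale concordance.

Schools from both systems are assigned to elementary distance sampling
units (EDSUs) by along-track position; each unit is summarised as a
nautical area scattering coefficient  s_A = 4 pi 1852^2 s_a  where
s_a = sum_i sv_i * H_i * W_i / unit length.  Concordance between systems
is assessed through presence contingency and rolling-window regressions
over increasing spatial scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from echofish.geo import cumulative_track_m, project_to_track

EDSU_LENGTH_M = 500.0
MIN_PARTIAL_EDSU_M = 250.0
NMI_SCALING = 4.0 * np.pi * 1852.0**2
DEFAULT_SCALES_KM = tuple(np.arange(0.5, 18.0, 1.0))  # 0.5, 1.5, ..., 17.5
OFFTRACK_WARN_M = 1000.0


@dataclass
class SchoolDensity:
    """Minimal per-school input to echo-integration."""

    lat: float
    lon: float
    sv_linear: float  # mean volume backscattering coefficient (m^-1)
    height_m: float
    width_m: float


@dataclass
class EDSU:
    """One elementary distance sampling unit along the survey track."""

    index: int
    start_dist_m: float
    end_dist_m: float
    schools: dict[str, list[SchoolDensity]] = field(default_factory=dict)

    @property
    def length_m(self) -> float:
        return self.end_dist_m - self.start_dist_m

    def present(self, system: str) -> bool:
        return bool(self.schools.get(system))

    def sa(self, system: str) -> float:
        return edsu_sa(self, system)


@dataclass
class ScaleFit:
    scale_km: float
    r2: float
    n_windows: int


def assign_edsus(
    schools_by_system: dict[str, Sequence[SchoolDensity]],
    track_lats: Sequence[float],
    track_lons: Sequence[float],
    edsu_length_m: float = EDSU_LENGTH_M,
    min_partial_m: float = MIN_PARTIAL_EDSU_M,
) -> list[EDSU]:
    """Tile the track into half-open units [k*L, (k+1)*L) and assign each
    school by the along-track distance of its centroid fix.

    A trailing partial unit shorter than ``min_partial_m`` is merged into
    the previous unit.  Schools more than 1 km off-track trigger a
    warning and are assigned to the nearest along-track point.
    """
    cum = cumulative_track_m(track_lats, track_lons)
    total = float(cum[-1])
    n_full = int(total // edsu_length_m)
    remainder = total - n_full * edsu_length_m
    bounds = [k * edsu_length_m for k in range(n_full + 1)]
    if remainder > 0:
        if remainder >= min_partial_m or n_full == 0:
            bounds.append(total)
        else:
            bounds[-1] = total
    edsus = [
        EDSU(index=k, start_dist_m=bounds[k], end_dist_m=bounds[k + 1],
             schools={s: [] for s in schools_by_system})
        for k in range(len(bounds) - 1)
    ]
    for system, schools in schools_by_system.items():
        for sc in schools:
            along, off = project_to_track(sc.lat, sc.lon, track_lats, track_lons, cum)
            along = round(along, 6)  # boundary fixes land in the later unit
            if off > OFFTRACK_WARN_M:
                warnings.warn(
                    f"school at ({sc.lat:.4f}, {sc.lon:.4f}) is {off:.0f} m off-track"
                )
            k = min(int(along // edsu_length_m), len(edsus) - 1)
            # half-open tiling, adjusted for the merged/partial last unit
            while k > 0 and along < edsus[k].start_dist_m:
                k -= 1
            while k < len(edsus) - 1 and along >= edsus[k].end_dist_m:
                k += 1
            edsus[k].schools[system].append(sc)
    return edsus


def edsu_sa(edsu: EDSU, system: str) -> float:
    """Nautical area scattering coefficient of one unit (m^2 nmi^-2)."""
    schools = edsu.schools.get(system, [])
    s_a = sum(s.sv_linear * s.height_m * s.width_m for s in schools) / edsu.length_m
    return NMI_SCALING * s_a


def detection_table(
    edsus: Sequence[EDSU], system_a: str = "rff", system_b: str = "ses"
) -> tuple[pd.DataFrame, float, float]:
    """2x2 presence contingency, odds ratio and Wald p-value.

    Association is the log-odds from the contingency table (equivalent to
    a binary-predictor logistic regression); zero cells get the Haldane
    0.5 continuity correction.
    """
    if not edsus:
        raise ValueError("need at least one EDSU")
    a = sum(e.present(system_a) and e.present(system_b) for e in edsus)
    b = sum(e.present(system_a) and not e.present(system_b) for e in edsus)
    c = sum(not e.present(system_a) and e.present(system_b) for e in edsus)
    d = sum(not e.present(system_a) and not e.present(system_b) for e in edsus)
    table = pd.DataFrame(
        {system_b: [a, c], f"no {system_b}": [b, d]},
        index=[system_a, f"no {system_a}"],
    )
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate margin: association undefined")
        return table, np.nan, np.nan
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt((1.0 / cells).sum())
    p = 2.0 * stats.norm.sf(abs(log_or / se))
    return table, float(np.exp(log_or)), float(p)


def matched_descriptor_fit(
    rff_values, ses_values, log_transform: bool = False
) -> tuple[float, float, float]:
    """OLS of reference-system on fish-finder descriptor values.

    Returns (slope, intercept, r2); with ``log_transform`` both sides are
    log10-transformed first (used for school areas).
    """
    x = np.asarray(rff_values, dtype=float)
    y = np.asarray(ses_values, dtype=float)
    if log_transform:
        x, y = np.log10(x), np.log10(y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.params[0]), float(res.rsquared)


def rolling_scale_concordance(
    edsus: Sequence[EDSU],
    scales_km: Sequence[float] = DEFAULT_SCALES_KM,
    system_a: str = "rff",
    system_b: str = "ses",
    edsu_length_m: float = EDSU_LENGTH_M,
    offset: float = 0.1,
) -> list[ScaleFit]:
    """R^2 between systems of rolling-window s_A densities per scale.

    Windows advance one EDSU at a time; the window sum is divided by the
    scale length and both series are log(x + offset)-transformed before
    the regression.  Scales longer than the track are skipped.
    """
    sa_a = np.array([e.sa(system_a) for e in edsus])
    sa_b = np.array([e.sa(system_b) for e in edsus])
    fits = []
    for scale in scales_km:
        w = max(int(round(scale * 1000.0 / edsu_length_m)), 1)
        if w > len(edsus):
            warnings.warn(f"scale {scale} km exceeds track length; skipped")
            continue
        kern = np.ones(w)
        ra = np.convolve(sa_a, kern, mode="valid") / scale
        rb = np.convolve(sa_b, kern, mode="valid") / scale
        xa, xb = np.log(ra + offset), np.log(rb + offset)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            r2 = 1.0 if np.allclose(xa, xb) else 0.0
        else:
            res = sm.OLS(xb, sm.add_constant(xa)).fit()
            r2 = float(res.rsquared)
        fits.append(ScaleFit(scale_km=float(scale), r2=r2, n_windows=ra.size))
    return fits


def edsu_table(edsus: Sequence[EDSU], systems: Sequence[str] = ("rff", "ses")) -> pd.DataFrame:
    """Per-EDSU summary: bounds, presence and s_A per system."""
    rows = []
    for e in edsus:
        rec = dict(index=e.index, start_m=e.start_dist_m, end_m=e.end_dist_m)
        for s in systems:
            rec[f"{s}_present"] = int(e.present(s))
            rec[f"{s}_sa"] = e.sa(s)
        rows.append(rec)
    return pd.DataFrame(rows)
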