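"""Colour-index to backscatter calibration against a reference sounder.

A display colour index c >= 1 is mapped to a volume backscattering
strength  S_v(c) = start_db + step_db * (c - 1)  (dB re 1 m^-1); colour 0
is background and never contributes to means.  The mapping is tuned by a
grid search against matched reference-system schools, and a log10
regression de-saturates the fish-finder's compressed dynamic range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

GRID_STARTS = np.round(np.arange(-70.0, -59.9, 0.5), 6)
GRID_STEPS = np.round(np.arange(0.1, 2.01, 0.1), 6)
BASELINE_START_DB = -65.0
SV_BIN_WIDTH_DB = 4.0
SV_BIN_ANCHOR_DB = -68.0


def sv_db_to_linear(sv_db):
    return 10.0 ** (np.asarray(sv_db, dtype=float) / 10.0)


def sv_linear_to_db(sv_lin):
    return 10.0 * np.log10(np.asarray(sv_lin, dtype=float))


@dataclass(frozen=True)
class PixelMapping:
    """Affine colour-index -> S_v map.

    ``start_db`` is the S_v of the weakest retained colour (index 1);
    each further index adds ``step_db``.
    """

    start_db: float
    step_db: float

    def __post_init__(self):
        if self.step_db <= 0:
            raise ValueError("step_db must be positive")

    def sv_db(self, colour_index):
        """S_v (dB) of raw colour index/indices >= 1."""
        c = np.asarray(colour_index)
        return self.start_db + self.step_db * (c - 1)

    def colour_of_sv(self, sv_db, n_colours: int) -> np.ndarray:
        """Nearest colour index for an S_v value, clipped to the display range."""
        c = 1 + np.rint((np.asarray(sv_db, dtype=float) - self.start_db) / self.step_db)
        return np.clip(c, 1, n_colours - 1).astype(int)


@dataclass
class MatchedSchoolPair:
    """One visually matched school insonified by both systems."""

    match_id: str
    time: str
    ses_sv_db: float
    rff_counts: np.ndarray  # per colour index, index 0 = background
    ses_mean_depth_m: float = np.nan
    rff_mean_depth_m: float = np.nan
    ses_area_m2: float = np.nan
    rff_area_m2: float = np.nan

    @property
    def ses_sv_linear(self) -> float:
        return float(sv_db_to_linear(self.ses_sv_db))


@dataclass
class CorrectionModel:
    """log10(sv_ref) = beta0 + beta1 * sv_rff, fitted by OLS."""

    beta0: float
    beta1: float
    r2: float

    def predict_sv_linear(self, sv_rff_linear):
        return 10.0 ** (self.beta0 + self.beta1 * np.asarray(sv_rff_linear, dtype=float))

    def predict_sv_db(self, sv_rff_linear):
        return sv_linear_to_db(self.predict_sv_linear(sv_rff_linear))


# ---------------------------------------------------------------------------


def school_mean_sv(pixel_value_counts, mapping: PixelMapping) -> tuple[float, float]:
    """Mean volume backscattering of a school pixel histogram.

    Returns ``(sv_linear, sv_db)`` where the mean is taken in the linear
    domain over colours >= 1.
    """
    counts = np.asarray(pixel_value_counts, dtype=float)
    n = counts[1:].sum()
    if n <= 0:
        raise ValueError("school has no retained (non-background) pixels")
    colours = np.arange(1, counts.size)
    sv_lin = float((counts[1:] * sv_db_to_linear(mapping.sv_db(colours))).sum() / n)
    return sv_lin, float(sv_linear_to_db(sv_lin))


def pixel_skewness(pixel_value_counts) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) of the colour-index distribution."""
    counts = np.asarray(pixel_value_counts, dtype=float)
    n = counts.sum()
    if n < 3:
        raise ValueError("need at least 3 pixels")
    c = np.arange(counts.size)
    mean = (counts * c).sum() / n
    m2 = (counts * (c - mean) ** 2).sum() / n
    if m2 == 0:
        raise ValueError("zero variance: skewness undefined")
    m3 = (counts * (c - mean) ** 3).sum() / n
    return float(m3 / m2**1.5)


def skewness_or_nan(pixel_value_counts) -> float:
    """``pixel_skewness`` with undefined cases flagged as NaN."""
    try:
        return pixel_skewness(pixel_value_counts)
    except ValueError:
        return float("nan")


def select_scenarios(pairs: Sequence[MatchedSchoolPair]) -> tuple[int, int, int]:
    """Indices of the minimum-, nearest-zero- and maximum-skewness schools.

    Schools with undefined skewness (zero variance) are ignored.  Ties
    are resolved towards the earlier survey time.  The three indices
    must be distinct.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched pairs")
    g1 = np.array([skewness_or_nan(p.rff_counts) for p in pairs])
    if np.isfinite(g1).sum() < 3:
        raise ValueError("fewer than 3 schools with defined skewness")
    order = np.argsort([p.time for p in pairs], kind="stable")

    def pick(key):
        vals = key(g1)
        best = np.nanmin(vals)
        cands = np.flatnonzero(vals == best)
        for i in order:
            if i in cands:
                return int(i)
        return int(cands[0])

    lo = pick(lambda g: g)
    zero = pick(np.abs)
    hi = pick(lambda g: -g)
    if len({lo, zero, hi}) < 3:
        raise ValueError("scenario schools are not distinct")
    return lo, zero, hi


def grid_search_mapping(
    pair: MatchedSchoolPair,
    starts: np.ndarray = GRID_STARTS,
    steps: np.ndarray = GRID_STEPS,
    baseline_start_db: float = BASELINE_START_DB,
) -> tuple[pd.DataFrame, float]:
    """Evaluate dS_v = S_v(ref) - S_v(mapped) over the (start, step) grid.

    Returns the full surface and the step minimising |dS_v| at the
    baseline starting value.
    """
    recs = []
    for start in starts:
        for step in steps:
            _, sv_db = school_mean_sv(pair.rff_counts, PixelMapping(start, step))
            recs.append((float(start), float(step), pair.ses_sv_db - sv_db))
    surface = pd.DataFrame(recs, columns=["start_db", "step_db", "dsv_db"])
    at_base = surface[np.isclose(surface["start_db"], baseline_start_db)]
    if at_base.empty:
        raise ValueError("baseline start value not on the grid")
    best = at_base.loc[at_base["dsv_db"].abs().idxmin()]
    return surface, float(best["step_db"])


def fit_correction(pairs: Sequence[MatchedSchoolPair], mapping: PixelMapping) -> CorrectionModel:
    """OLS of log10(reference sv) on fish-finder sv (linear predictor)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs to fit")
    x = np.array([school_mean_sv(p.rff_counts, mapping)[0] for p in pairs])
    y = np.log10([p.ses_sv_linear for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("singular design: predictor has no variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CorrectionModel(float(res.params[0]), float(res.params[1]), float(res.rsquared))


def apply_correction(model: CorrectionModel, sv_rff_linear) -> tuple[np.ndarray, np.ndarray]:
    """Corrected (sv_linear, S_v dB) for fish-finder sv values."""
    sv = model.predict_sv_linear(sv_rff_linear)
    return sv, sv_linear_to_db(sv)


def bin_sv(
    values_db,
    width_db: float = SV_BIN_WIDTH_DB,
    anchor_db: float = SV_BIN_ANCHOR_DB,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of S_v values over half-open bins [edge, edge + width)."""
    v = np.asarray(values_db, dtype=float)
    if v.size == 0:
        return np.zeros(0, int), np.array([anchor_db])
    lo = anchor_db + width_db * np.floor((v.min() - anchor_db) / width_db)
    hi = anchor_db + width_db * (np.floor((v.max() - anchor_db) / width_db) + 1)
    edges = np.arange(lo, hi + width_db / 2, width_db)
    idx = np.floor((v - anchor_db) / width_db).astype(int)
    idx -= int(round((lo - anchor_db) / width_db))
    counts = np.bincount(idx, minlength=edges.size - 1)
    return counts, edges


def paired_rank_test(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties take mid-ranks.  The exact null
    distribution is used when free of ties/zeros, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=True, method="auto")
    return float(res.statistic), float(res.pvalue)


def depth_dependence(
    sv_linear: np.ndarray, mean_depth_m: np.ndarray
) -> tuple[float, float, float]:
    """OLS of log10(sv) on mean school depth: (slope, intercept, r2)."""
    y = np.log10(np.asarray(sv_linear, dtype=float))
    x = np.asarray(mean_depth_m, dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.params[0]), float(res.rsquared)
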