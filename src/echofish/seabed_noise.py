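"""Seabed tracing and noise suppression.

The seabed is found as the horizontal path through the frame that covers
as many detected upper edges as possible while penalising vertical
jumps, solved exactly by dynamic programming over (row, column) states.
Speckle is removed with a median filter and anomalously strong pings are
dropped as whole columns using a robust (median/MAD) peak test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from echofish.echogram_model import EchogramFrame

DEFAULT_LAMBDA = 0.5
DEFAULT_P = 2
DEFAULT_EDGE_THRESHOLD = 1
DEFAULT_COLUMN_Z = 5.0


@dataclass
class SeabedPath:
    """Seabed row per column, with the smoothness settings that produced it."""

    row_per_col: np.ndarray
    lam: float
    P: int
    score: float
    no_evidence: bool = False

    def __post_init__(self):
        self.row_per_col = np.asarray(self.row_per_col, dtype=int)
        if self.P >= 0 and np.any(np.abs(np.diff(self.row_per_col)) > self.P):
            raise ValueError("path exceeds the per-column transition bound")


def detect_upper_edges(frame: EchogramFrame, threshold: int = DEFAULT_EDGE_THRESHOLD) -> np.ndarray:
    """Binary map of pixels whose colour reaches ``threshold`` while the
    pixel directly above does not (upper-edge semantics)."""
    strong = frame.pixels >= threshold
    above = np.zeros_like(strong)
    above[1:, :] = strong[:-1, :]
    return strong & ~above


def trace_seabed(
    edges: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    P: int = DEFAULT_P,
) -> SeabedPath:
    """Maximise  sum_i edge(d(i), i) - lam * sum_i |d(i+1)-d(i)|  subject to
    |d(i+1)-d(i)| <= P.

    Ties are broken towards the deeper (larger) row, then the straighter
    transition, so flat seabeds under schools are not traced through the
    school.  An edge map with no set pixel yields the deepest-row path
    flagged ``no_evidence``.
    """
    edges = np.asarray(edges)
    if edges.size == 0:
        raise ValueError("empty edge map")
    if lam < 0 or P < 0:
        raise ValueError("lam and P must be non-negative")
    R, N = edges.shape
    e = edges.astype(float)
    if not edges.any():
        return SeabedPath(np.full(N, R - 1), lam, P, 0.0, no_evidence=True)

    # V[r, c]: best achievable score over columns c..N-1 entering at row r.
    V = np.empty((R, N))
    V[:, -1] = e[:, -1]
    shifts = np.arange(-P, P + 1)
    for c in range(N - 2, -1, -1):
        best = np.full(R, -np.inf)
        for s in shifts:
            # transition r -> r+s into column c+1
            lo, hi = max(0, -s), min(R, R - s)
            if lo >= hi:
                continue
            cand = V[lo + s : hi + s, c + 1] - lam * abs(s)
            np.maximum(best[lo:hi], cand, out=best[lo:hi])
        V[:, c] = e[:, c] + best

    # Greedy reconstruction; ties resolved to the deepest row, then the
    # smallest |transition|.
    path = np.empty(N, dtype=int)
    path[0] = int(np.flatnonzero(V[:, 0] == V[:, 0].max())[-1])
    for c in range(1, N):
        r = path[c - 1]
        lo, hi = max(0, r - P), min(R - 1, r + P)
        rows = np.arange(lo, hi + 1)
        vals = V[lo : hi + 1, c] - lam * np.abs(rows - r)
        keys = sorted(
            zip(vals, rows, -np.abs(rows - r)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        path[c] = int(keys[-1][1])
    score = float(e[path, np.arange(N)].sum() - lam * np.abs(np.diff(path)).sum())
    return SeabedPath(path, lam, P, score)


def mask_below_seabed(
    frame: EchogramFrame, path: SeabedPath, margin_m: float = 0.0
) -> EchogramFrame:
    """Clear every pixel at or below the seabed path (raised by ``margin_m``)."""
    if path.row_per_col.size != frame.n_cols:
        raise ValueError("seabed path does not match frame width")
    margin_rows = int(round(margin_m / frame.metres_per_row))
    cutoff = np.maximum(path.row_per_col - margin_rows, 0)
    rows = np.arange(frame.n_rows)[:, None]
    out = frame.copy()
    out.pixels[rows >= cutoff[None, :]] = 0
    return out


def despeckle(frame: EchogramFrame, kernel: int = 3) -> EchogramFrame:
    """Median-filter the colour grid (reflected borders)."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
    out = frame.copy()
    out.pixels = ndimage.median_filter(frame.pixels, size=kernel, mode="reflect")
    return out


def remove_noise_columns(
    frame: EchogramFrame,
    z_threshold: float = DEFAULT_COLUMN_Z,
    baseline_window: int = 5,
) -> tuple[EchogramFrame, list[int]]:
    """Blank columns whose echo sum spikes above the local baseline.

    Column sums are compared against a rolling-median baseline (width
    ``baseline_window``), so multi-column schools raise the baseline with
    them and only narrow full-height pings stand out.  A column is
    removed when its residual exceeds ``z_threshold`` robust standard
    deviations (1.4826 * MAD of the residuals) and, as an absolute floor,
    one full column of the weakest colour — a genuine column-spanning
    ping cannot sum to less.  Removed columns keep their georeference.
    """
    if frame.n_cols < 3:
        raise ValueError("need at least 3 columns")
    sums = frame.pixels.sum(axis=0).astype(float)
    baseline = ndimage.median_filter(sums, size=baseline_window, mode="reflect")
    resid = sums - baseline
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    removed = np.flatnonzero(resid > max(z_threshold * scale, float(frame.n_rows)))
    out = frame.copy()
    out.pixels[:, removed] = 0
    return out, [int(c) for c in removed]
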