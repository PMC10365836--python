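"""Chemotaxis quantification from cell-position tables.

Given per-frame cell positions across the observation channel width, this
module computes the standard population-level readouts of a stop-flow
assay:

* the kymograph P(y|t) -- per-frame conditional probability density of cell
  position across the channel;
* the accumulation index

      β(t) = (Np(t) − Nn(t)) / (Np(T) + Nn(T)),

  where Np and Nn count cells inside wall-adjacent accumulation regions
  (200 μm wide by default) on the chemostimulus (high-y) and buffer (low-y)
  sides, and the denominator is fixed at the final frame T;
* scalar response summaries: βmax = ±max|β(t)| (signed by the direction of
  the response) and the maximal response rate max(dβ/dt) evaluated strictly
  before the time of βmax;
* the abundance-based Sørensen similarity between two kymographs,
  2·Σ min(P₁,P₂) / (Σ P₁ + Σ P₂) per frame, averaged over time (equal to
  1 − Bray–Curtis dissimilarity).

A central band (250 μm by default) containing non-motile cells may be
masked in kymograph *displays*; it never enters β(t), which depends only on
the wall-adjacent regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoDataError, UndefinedIndexError

__all__ = [
    "Kymograph",
    "AccumulationSeries",
    "ResponseSummary",
    "kymograph",
    "accumulation_index",
    "response_summary",
    "sorensen_similarity",
]

DEFAULT_BIN_WIDTH = 25.0       # μm; 40 bins across a 1-mm channel
DEFAULT_REGION_WIDTH = 200.0   # μm accumulation regions at each wall
DEFAULT_CENTRAL_EXCLUSION = 250.0  # μm display-only central band
DEFAULT_SMOOTH_WINDOW = 5      # frames (40 s at the 8-s effective period)


@dataclass
class Kymograph:
    """P(y|t) on a fixed bin grid; rows with no cells are NaN-flagged."""

    y_edges: np.ndarray        # (nb+1,)
    times: np.ndarray          # (nt,)
    density: np.ndarray        # (nt, nb), ∫P dy = 1 per frame with cells
    counts: np.ndarray         # (nt,) cells per frame
    central_exclusion_um: float = DEFAULT_CENTRAL_EXCLUSION

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def display_density(self) -> np.ndarray:
        """Density with the central band masked to NaN (visualisation only;
        the stored density is untouched and is what every metric uses)."""
        w = self.y_edges[-1]
        lo = (w - self.central_exclusion_um) / 2.0
        hi = (w + self.central_exclusion_um) / 2.0
        centers = self.y_centers
        out = self.density.copy()
        out[:, (centers > lo) & (centers < hi)] = np.nan
        return out


@dataclass
class AccumulationSeries:
    times: np.ndarray
    beta: np.ndarray
    n_pos: np.ndarray
    n_neg: np.ndarray
    region_width_um: float = DEFAULT_REGION_WIDTH


@dataclass
class ResponseSummary:
    beta_max: float
    t_max_s: float
    max_rate_per_s: float | None   # None when βmax occurs at the first frame
    smoothing_window: int = DEFAULT_SMOOTH_WINDOW


def kymograph(table: pd.DataFrame, bin_width_um: float = DEFAULT_BIN_WIDTH,
              W_um: float = 1000.0,
              central_exclusion_um: float = DEFAULT_CENTRAL_EXCLUSION,
              ) -> Kymograph:
    """Per-frame histogram of y positions, normalised to unit integral.

    The last bin is truncated when ``bin_width_um`` does not divide ``W_um``.
    Frames with zero cells yield NaN density rows (flagged missing rather
    than zero-filled).
    """
    if table.empty:
        raise NoDataError("empty position table")
    edges = np.arange(0.0, W_um + bin_width_um, bin_width_um)
    edges = edges[edges < W_um + 1e-9]
    if edges[-1] < W_um:
        edges = np.append(edges, W_um)

    times = np.sort(table["time_s"].unique())
    nb = edges.size - 1
    dens = np.full((times.size, nb), np.nan)
    counts = np.zeros(times.size, dtype=int)
    widths = np.diff(edges)
    grouped = table.groupby("time_s")["y_um"]
    for i, t in enumerate(times):
        y = grouped.get_group(t).to_numpy()
        counts[i] = y.size
        if y.size:
            hist, _ = np.histogram(y, bins=edges)
            dens[i] = hist / (y.size * widths)
    return Kymograph(edges, times, dens, counts, central_exclusion_um)


def accumulation_index(table: pd.DataFrame, W_um: float = 1000.0,
                       region_width_um: float = DEFAULT_REGION_WIDTH,
                       ) -> AccumulationSeries:
    """β(t) with counts in [W−region, W] (positive) and [0, region]
    (negative), normalised by the final-frame total in those regions."""
    if table.empty or table["time_s"].nunique() < 2:
        raise NoDataError("need at least two frames")
    times = np.sort(table["time_s"].unique())
    y = table["y_um"]
    pos = table.loc[y >= W_um - region_width_um].groupby("time_s").size()
    neg = table.loc[y <= region_width_um].groupby("time_s").size()
    n_pos = pos.reindex(times, fill_value=0).to_numpy()
    n_neg = neg.reindex(times, fill_value=0).to_numpy()
    denom = n_pos[-1] + n_neg[-1]
    if denom == 0:
        raise UndefinedIndexError(
            "no cells in the accumulation regions at the final frame")
    beta = (n_pos - n_neg) / denom
    return AccumulationSeries(times, beta, n_pos, n_neg, region_width_um)


def _smooth(beta: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; near the ends the window shrinks
    symmetrically (it stays centred), which keeps the smoother unbiased for
    locally linear β(t) right up to the boundary frames."""
    if window <= 1:
        return beta.astype(float)
    n = beta.size
    half = window // 2
    out = np.empty(n, dtype=float)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = beta[i - k:i + k + 1].mean()
    return out


def response_summary(series: AccumulationSeries,
                     window: int = DEFAULT_SMOOTH_WINDOW) -> ResponseSummary:
    """βmax and the maximal pre-peak response rate from a β(t) series.

    β is smoothed with a centred moving average before the extremum search;
    the rate is the extreme central-difference dβ/dt (in the direction of
    the response) over times strictly before t(βmax), or None when βmax
    falls on the first frame.
    """
    if series.times.size < 3:
        raise NoDataError("need at least three frames")
    sm = _smooth(series.beta, window)
    # ties broken toward the latest frame, so a plateau (e.g. constant β)
    # peaks at its end and the pre-peak rate is well defined
    absm = np.abs(sm)
    i_max = int(absm.size - 1 - np.argmax(absm[::-1]))
    beta_max = float(sm[i_max])
    if i_max == 0:
        return ResponseSummary(beta_max, float(series.times[0]), None, window)
    rate = np.gradient(sm, series.times)
    pre = rate[:i_max]
    best = float(np.max(pre)) if beta_max >= 0 else float(np.min(pre))
    return ResponseSummary(beta_max, float(series.times[i_max]), best, window)


def sorensen_similarity(a: Kymograph, b: Kymograph) -> float:
    """Time-averaged quantitative Sørensen similarity of two kymographs.

    Per shared frame, S(t) = 2·Σ min(p_A, p_B) / (Σ p_A + Σ p_B) on the
    per-frame probability masses; frames missing in either kymograph are
    skipped.  Kymographs must share the bin grid; B's frames are matched to
    A's by exact time.
    """
    if not np.array_equal(a.y_edges, b.y_edges):
        raise ValueError("kymographs must share the y bin grid")
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if common.size == 0:
        raise NoDataError("kymographs share no time points")
    widths = np.diff(a.y_edges)
    vals = []
    for i, j in zip(ia, ib):
        pa = a.density[i] * widths
        pb = b.density[j] * widths
        if np.any(np.isnan(pa)) or np.any(np.isnan(pb)):
            continue
        denom = pa.sum() + pb.sum()
        vals.append(2.0 * np.minimum(pa, pb).sum() / denom)
    if not vals:
        raise NoDataError("no frame present in both kymographs")
    return float(np.mean(vals))
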