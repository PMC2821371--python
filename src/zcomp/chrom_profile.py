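"""Positional profiles along a chromosome.

The trend of M:F ratios along a chromosome is summarized by a boxcar
running average of 30 consecutive log2 ratios (probesets ordered by
position, step 1), each window plotted at the median position of its
probesets.  The *amplitude* profile applies the same windowing to
|log2 ratio|, which distinguishes genuine compensation (amplitude near 0)
from ratios that merely average out.  A region of interest (e.g. the MHM
window) can be contrasted against the rest of the chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage_classify import rank_sum_compare
from .overlap_perm import overlap_significance

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 30
DEFAULT_BIN_WIDTH = 0.1


def _sorted_by_position(
    positions: np.ndarray, values: np.ndarray, ids: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values differ in length")
    ok = np.isfinite(positions)
    if not ok.all():
        logger.info("dropping %d probesets without positions", int((~ok).sum()))
        positions, values = positions[ok], values[ok]
        if ids is not None:
            ids = np.asarray(ids, dtype=object)[ok]
    if ids is not None:
        order = np.lexsort((np.asarray(ids, dtype=object), positions))
    else:
        order = np.argsort(positions, kind="stable")
    return positions[order], values[order]


def running_average(
    positions: np.ndarray,
    values: np.ndarray,
    window: int = DEFAULT_WINDOW,
    ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Boxcar running mean over consecutive position-sorted values.

    Returns a frame with columns ``position_bp`` (median position of the
    window; mean of the two central positions for even windows), ``value``
    (window mean) and ``window_index``; length is n - window + 1.  Position
    ties are broken by probeset id when ``ids`` is given, making the
    profile deterministic.
    """
    pos, val = _sorted_by_position(positions, values, ids)
    n = len(pos)
    if window < 1:
        raise ValueError("window must be positive")
    if n < window:
        raise ValueError(
            f"only {n} positioned probesets; choose a window <= {n} (got {window})"
        )
    kernel = np.ones(window) / window
    means = np.convolve(val, kernel, mode="valid")
    # median position per window, vectorized over the sliding view
    view = np.lib.stride_tricks.sliding_window_view(pos, window)
    med_pos = np.median(view, axis=1)
    return pd.DataFrame(
        {
            "position_bp": med_pos,
            "value": means,
            "window_index": np.arange(n - window + 1),
        }
    )


def amplitude_profile(
    positions: np.ndarray,
    log2_ratios: np.ndarray,
    window: int = DEFAULT_WINDOW,
    ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Running average of |log2 ratio| along the chromosome."""
    return running_average(
        positions, np.abs(np.asarray(log2_ratios, dtype=float)), window, ids
    )


@dataclass
class RatioDistribution:
    """Histogram of log2 ratios in percent, with local-maximum modes."""

    bin_centers: np.ndarray
    percent_per_bin: np.ndarray
    modes: np.ndarray  # bin centers that exceed both neighbors

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_log2": self.bin_centers, "percent": self.percent_per_bin}
        )


def ratio_distribution(
    log2_ratios: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> RatioDistribution:
    """Percent distribution of log2 ratios on a fixed-width grid.

    Bin edges are aligned to multiples of ``bin_width``.  Modes are bins
    strictly higher than both neighbors (edge bins compare against their
    single neighbor).
    """
    x = np.asarray(log2_ratios, dtype=float)
    if x.size == 0:
        raise ValueError("no ratios supplied")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    percent = 100.0 * counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    modes = []
    for i, p in enumerate(percent):
        left = percent[i - 1] if i > 0 else -np.inf
        right = percent[i + 1] if i < len(percent) - 1 else -np.inf
        if p > left and p > right:
            modes.append(centers[i])
    return RatioDistribution(
        bin_centers=centers, percent_per_bin=percent, modes=np.array(modes)
    )


@dataclass
class RegionContrast:
    inside_mean: float
    outside_mean: float
    n_inside: int
    n_outside: int
    p_value: float
    method: str


def region_contrast(
    positions: np.ndarray,
    values: np.ndarray,
    region: tuple[float, float],
    method: str = "ranksum",
    n_sims: int = 10000,
    seed: int = 0,
    min_inside: int = 5,
) -> RegionContrast:
    """Compare values inside a positional window against the rest.

    ``method='ranksum'`` treats *values* as continuous (e.g. |log2 M:F|)
    and applies the Wilcoxon rank-sum test.  ``method='overlap'`` treats
    *values* as a binary class indicator (e.g. compensated yes/no) and runs
    the Monte-Carlo overlap test between the in-region set and the
    indicated set, over the universe of all supplied probesets.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = region
    if hi <= lo:
        raise ValueError("empty region")
    inside = (positions >= lo) & (positions <= hi)
    n_in, n_out = int(inside.sum()), int((~inside).sum())
    if n_in < min_inside:
        raise ValueError(f"only {n_in} probesets inside region (need >= {min_inside})")
    if n_out == 0:
        raise ValueError("region covers the whole chromosome; nothing outside")
    inside_mean = float(values[inside].mean())
    outside_mean = float(values[~inside].mean())
    if method == "ranksum":
        _, p = rank_sum_compare(values[inside], values[~inside])
    elif method == "overlap":
        universe = [str(i) for i in range(len(values))]
        set_region = {str(i) for i in np.flatnonzero(inside)}
        set_class = {str(i) for i in np.flatnonzero(values > 0)}
        res = overlap_significance(
            set_region, set_class, universe, n_sims=n_sims, seed=seed
        )
        p = res.empirical_p
    else:
        raise ValueError(f"unknown method {method!r}")
    return RegionContrast(
        inside_mean=inside_mean,
        outside_mean=outside_mean,
        n_inside=n_in,
        n_outside=n_out,
        p_value=float(p),
        method=method,
    )
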