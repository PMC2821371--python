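"""Two-class unpaired SAM: moderated d statistic, permutation FDR, q-values.

The statistic for probeset *i* is

    d_i = (mean_male_i - mean_female_i) / (s_i + s0)

with s_i the pooled standard-error scatter

    s_i = sqrt[ (1/n_M + 1/n_F) * (SS_M + SS_F) / (n_M + n_F - 2) ]

and s0 a small shared "fudge factor" that damps variance-driven outliers at
low expression.  Significance comes from permuting the sex labels: the
observed order statistics d_(i) are compared with their permutation
averages d-bar_(i), genes beyond a threshold delta are called, and the FDR
at each delta is the median (or mean) number of permuted scores falling
beyond the cutoffs divided by the number of calls.  A gene's q-value is the
smallest FDR among the deltas at which it is called.

Permutations are distinct label arrangements, enumerated exhaustively when
their total count is small enough (18 arrays split 9/9 give C(18,9) = 48620,
under the default cap) and otherwise sampled uniformly without replacement.

The test statistic is computed on log2 intensities (clipped at a positive
floor); fold changes are reported as ratios of linear means to match the
M:F ratio convention used elsewhere in the package.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, SamSettings
from .preprocess import DEFAULT_FLOOR

logger = logging.getLogger(__name__)

_S0_CANDIDATE_PERCENTILES = np.arange(0, 100, 5)  # 0, 5, ..., 95
_N_S_WINDOWS = 100


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------

def pooled_scatter(x_male: np.ndarray, x_female: np.ndarray) -> np.ndarray:
    """Per-row pooled standard-error scatter s (rows = probesets)."""
    n_m, n_f = x_male.shape[1], x_female.shape[1]
    if n_m < 2 or n_f < 2:
        raise ValueError("need at least 2 samples per group for the scatter")
    ss = ((x_male - x_male.mean(1, keepdims=True)) ** 2).sum(1) + (
        (x_female - x_female.mean(1, keepdims=True)) ** 2
    ).sum(1)
    return np.sqrt((1.0 / n_m + 1.0 / n_f) * ss / (n_m + n_f - 2))


def relative_difference(
    mean_male: np.ndarray, mean_female: np.ndarray, s: np.ndarray, s0: float
) -> np.ndarray:
    """SAM relative difference d = (mean_M - mean_F) / (s + s0)."""
    denom = s + s0
    if np.any(denom <= 0):
        raise ZeroDivisionError(
            "zero denominator in d: identical values with s0 = 0"
        )
    return (np.asarray(mean_male) - np.asarray(mean_female)) / denom


# ---------------------------------------------------------------------------
# fudge factor
# ---------------------------------------------------------------------------

def choose_s0(
    numerator: np.ndarray,
    s: np.ndarray,
    strategy: str = "cv_minimization",
    percentile: float = 5.0,
) -> float:
    """Select the shared fudge factor s0.

    ``cv_minimization`` (the standard SAM tuning): candidate s0 values are
    the {0, 5, ..., 95} percentiles of s; for each candidate the spread
    (median absolute deviation) of d = numerator/(s + s0) is computed within
    100 s-quantile windows, and the candidate minimizing the coefficient of
    variation of those spreads wins (ties -> smallest candidate).

    ``fixed_percentile``: s0 is simply the given percentile of s.
    """
    s = np.asarray(s, dtype=float)
    if strategy == "fixed_percentile":
        return float(np.percentile(s, percentile))
    if strategy != "cv_minimization":
        raise ValueError(f"unknown s0 strategy {strategy!r}")
    if s.size < 100:
        raise ValueError("cv_minimization needs at least 100 probesets")
    if np.allclose(s, s[0]):
        logger.warning("degenerate scatter (all s equal); falling back to s0 = 0")
        return 0.0

    candidates = np.percentile(s, _S0_CANDIDATE_PERCENTILES)
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, _N_S_WINDOWS)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        d = np.asarray(numerator) / (s + cand)
        spreads = np.array([_mad(d[w]) for w in windows if w.size])
        mean_spread = spreads.mean()
        if mean_spread == 0:
            continue
        cv = spreads.std(ddof=0) / mean_spread
        if cv < best_cv - 1e-15:  # strict improvement; ties keep smaller cand
            best_cv, best_s0 = cv, float(cand)
    if not np.isfinite(best_cv):
        logger.warning("cv minimization degenerate; falling back to s0 = 0")
        return 0.0
    return best_s0


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def label_arrangements(
    n_samples: int,
    male_indices: np.ndarray,
    settings: SamSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Boolean masks (one row per arrangement, True = 'male' group).

    Returns ``(masks, exhaustive)``.  All C(n, n_male) arrangements are
    enumerated when their count is at most ``settings.exhaustive_cap``;
    otherwise ``settings.n_permutations`` distinct arrangements are sampled
    uniformly without replacement (the original labeling force-included when
    ``settings.include_original``).
    """
    n_male = len(male_indices)
    total = comb(n_samples, n_male)
    original = tuple(sorted(int(i) for i in male_indices))
    if total <= settings.exhaustive_cap or settings.n_permutations >= total:
        combos = list(itertools.combinations(range(n_samples), n_male))
        if not settings.include_original:
            combos = [c for c in combos if c != original]
        masks = np.zeros((len(combos), n_samples), dtype=bool)
        for i, c in enumerate(combos):
            masks[i, list(c)] = True
        return masks, True

    chosen: set[tuple[int, ...]] = set()
    if settings.include_original:
        chosen.add(original)
    while len(chosen) < settings.n_permutations:
        draw = tuple(sorted(rng.choice(n_samples, size=n_male, replace=False).tolist()))
        if not settings.include_original and draw == original:
            continue
        chosen.add(draw)
    masks = np.zeros((len(chosen), n_samples), dtype=bool)
    for i, c in enumerate(sorted(chosen)):
        masks[i, list(c)] = True
    return masks, False


def d_for_arrangements(
    x: np.ndarray, masks: np.ndarray, s0: float, chunk: int = 512
) -> np.ndarray:
    """d statistics for every arrangement: result shape (n_masks, n_probesets).

    Group sizes are constant across arrangements, so group sums reduce to a
    single matrix product per chunk.
    """
    n = x.shape[1]
    n_m = int(masks[0].sum())
    n_f = n - n_m
    tot = x.sum(1)
    totsq = (x * x).sum(1)
    inv = 1.0 / n_m + 1.0 / n_f
    dof = n_m + n_f - 2
    out = np.empty((masks.shape[0], x.shape[0]))
    for start in range(0, masks.shape[0], chunk):
        b = masks[start : start + chunk].T.astype(float)  # n x k
        s1 = x @ b
        ss1 = (x * x) @ b
        s2 = tot[:, None] - s1
        ss2 = totsq[:, None] - ss1
        m1 = s1 / n_m
        m2 = s2 / n_f
        within = (ss1 - n_m * m1 * m1) + (ss2 - n_f * m2 * m2)
        s = np.sqrt(np.clip(inv * within / dof, 0.0, None))
        out[start : start + chunk] = ((m1 - m2) / (s + s0)).T
    return out


def permutation_null(
    x: np.ndarray,
    masks: np.ndarray,
    s0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted permutation d matrix and expected order statistics d-bar.

    Each row of the returned matrix is one arrangement's d values in
    ascending order; d-bar_(i) is the mean of the i-th smallest d across
    arrangements.
    """
    d_perm = d_for_arrangements(x, masks, s0)
    d_perm.sort(axis=1)
    return d_perm, d_perm.mean(axis=0)


# ---------------------------------------------------------------------------
# thresholding and FDR
# ---------------------------------------------------------------------------

def call_at_delta(
    d_sorted: np.ndarray, d_bar: np.ndarray, delta: float
) -> tuple[float, float]:
    """Cutoffs (cut_low, cut_up) at threshold delta.

    cut_up is the smallest observed d whose excess over its expected order
    statistic reaches delta; every d >= cut_up is called positive.  cut_low
    is the symmetric negative-tail cutoff.  Missing crossings give +/-inf
    (no calls in that tail).
    """
    if d_sorted.shape != d_bar.shape:
        raise ValueError("d and d-bar must have equal length")
    diff = d_sorted - d_bar
    up = d_sorted[diff >= delta]
    low = d_sorted[diff <= -delta]
    cut_up = float(up.min()) if up.size else np.inf
    cut_low = float(low.max()) if low.size else -np.inf
    return cut_low, cut_up


@dataclass
class SamResult:
    """Output of :func:`sam_test`.

    ``table`` is indexed by probeset id with columns ``d``, ``s``,
    ``fold_change`` (linear M:F of means), ``q_value`` and
    ``called_direction`` in {male, female, none}.  ``delta_table`` records
    per-delta call counts and FDR estimates; ``chosen_delta`` is the
    smallest delta achieving the target FDR (NaN when none does).
    """

    table: pd.DataFrame
    delta_table: pd.DataFrame
    s0: float
    chosen_delta: float
    target_fdr: float
    exhaustive: bool
    n_arrangements: int

    @property
    def called_male(self) -> pd.Index:
        return self.table.index[self.table["called_direction"] == "male"]

    @property
    def called_female(self) -> pd.Index:
        return self.table.index[self.table["called_direction"] == "female"]


def sam_test(
    ds: ExpressionDataset,
    settings: SamSettings | None = None,
    floor_intensity: float = DEFAULT_FLOOR,
) -> SamResult:
    """Run the full SAM pipeline on a dataset (male vs female)."""
    settings = settings or SamSettings()
    ds.require_both_sexes(min_per_sex=2)
    rng = np.random.default_rng(settings.seed)

    lin = np.clip(ds.intensities.to_numpy(dtype=float), floor_intensity, None)
    x = np.log2(lin)
    male = ds.intensities.columns.isin(ds.male_samples)
    male_idx = np.flatnonzero(male)

    x_m, x_f = x[:, male], x[:, ~male]
    mean_m, mean_f = x_m.mean(1), x_f.mean(1)
    s = pooled_scatter(x_m, x_f)
    s0 = choose_s0(
        mean_m - mean_f, s, settings.s0_strategy, settings.s0_percentile
    )
    d = relative_difference(mean_m, mean_f, s, s0)

    masks, exhaustive = label_arrangements(
        ds.n_samples, male_idx, settings, rng
    )
    d_perm_sorted, d_bar = permutation_null(x, masks, s0)

    # deterministic observed ordering: d ascending, ties by probeset id
    ids = ds.probeset_ids.to_numpy(dtype=object)
    order = np.lexsort((ids, d))
    d_sorted = d[order]

    max_diff = float(np.abs(d_sorted - d_bar).max())
    if max_diff <= 0:
        deltas = np.array([1e-9])
    else:
        deltas = np.linspace(max_diff / settings.n_deltas, max_diff, settings.n_deltas)

    stat = np.median if settings.fdr_statistic == "median" else np.mean
    n_probesets = len(d)
    q = np.ones(n_probesets)
    rows = []
    chosen_delta = np.nan
    chosen_cuts = (-np.inf, np.inf)
    for delta in deltas:
        cut_low, cut_up = call_at_delta(d_sorted, d_bar, float(delta))
        called = (d >= cut_up) | (d <= cut_low)
        n_called = int(called.sum())
        if n_called == 0:
            rows.append((float(delta), 0, np.nan, cut_low, cut_up))
            continue
        false_per_perm = (d_perm_sorted >= cut_up).sum(1) + (
            d_perm_sorted <= cut_low
        ).sum(1)
        fdr = min(1.0, float(stat(false_per_perm)) / n_called)
        rows.append((float(delta), n_called, fdr, cut_low, cut_up))
        q[called] = np.minimum(q[called], fdr)
        if np.isnan(chosen_delta) and fdr <= settings.target_fdr:
            chosen_delta = float(delta)
            chosen_cuts = (cut_low, cut_up)

    direction = np.full(n_probesets, "none", dtype=object)
    if not np.isnan(chosen_delta):
        direction[d >= chosen_cuts[1]] = "male"
        direction[d <= chosen_cuts[0]] = "female"
    else:
        logger.info("no delta achieves FDR <= %.3g; no calls", settings.target_fdr)

    lin_m = lin[:, male].mean(1)
    lin_f = lin[:, ~male].mean(1)
    table = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "fold_change": lin_m / lin_f,
            "q_value": q,
            "called_direction": direction,
        },
        index=ds.probeset_ids.copy(),
    )
    delta_table = pd.DataFrame(
        rows, columns=["delta", "n_called", "fdr", "cut_low", "cut_up"]
    )
    return SamResult(
        table=table,
        delta_table=delta_table,
        s0=s0,
        chosen_delta=chosen_delta,
        target_fdr=settings.target_fdr,
        exhaustive=exhaustive,
        n_arrangements=masks.shape[0],
    )
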