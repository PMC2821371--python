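"""Detection-call filtering and male:female expression ratios."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset

logger = logging.getLogger(__name__)

#: intensities below this are clipped up before computing means/ratios, so
#: near-zero MAS5 values cannot blow up M:F ratios.
DEFAULT_FLOOR = 1.0


def present_threshold(n_samples: int, min_present_fraction: float) -> int:
    """Number of Present calls required: ceil(fraction * n), compared >=.

    With 18 samples and fraction 0.5 this is the 9-of-18 rule.
    """
    if not 0 < min_present_fraction <= 1:
        raise ValueError("min_present_fraction must lie in (0, 1]")
    return math.ceil(min_present_fraction * n_samples)


def detection_filter(
    ds: ExpressionDataset, min_present_fraction: float = 0.5
) -> ExpressionDataset:
    """Keep probesets called Present in at least the given fraction of samples.

    Marginal calls do not count as Present.  Row order is preserved.  An
    empty result is allowed (with a warning), since downstream stages treat
    it as "nothing expressed".
    """
    thresh = present_threshold(ds.n_samples, min_present_fraction)
    n_present = (ds.detection.to_numpy() == "P").sum(axis=1)
    keep = ds.probeset_ids[n_present >= thresh]
    if len(keep) == 0:
        logger.warning("detection filter retained no probesets")
    logger.info(
        "detection filter: %d/%d probesets retained (threshold %d Present of %d)",
        len(keep), ds.n_probesets, thresh, ds.n_samples,
    )
    return ds.subset(keep)


@dataclass(frozen=True)
class SexRatioTable:
    """Per-probeset sex means and M:F ratios (linear ratio of means)."""

    table: pd.DataFrame  # columns: mean_male, mean_female, mf_ratio, log2_mf, fm_ratio
    floor_intensity: float

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    @property
    def probeset_ids(self) -> pd.Index:
        return self.table.index

    @property
    def mf_ratio(self) -> pd.Series:
        return self.table["mf_ratio"]

    @property
    def log2_mf(self) -> pd.Series:
        return self.table["log2_mf"]


def sex_ratios(
    ds: ExpressionDataset, floor_intensity: float = DEFAULT_FLOOR
) -> SexRatioTable:
    """Compute per-probeset M:F as the ratio of linear-scale sex means.

    This is the ratio of means, not the mean of per-sample ratios.
    Intensities below ``floor_intensity`` are clipped up to it first, which
    bounds every ratio by floor/max and keeps logs finite.
    """
    if floor_intensity <= 0:
        raise ValueError("floor_intensity must be positive")
    ds.require_both_sexes(min_per_sex=1)
    clipped = np.clip(ds.intensities.to_numpy(dtype=float), floor_intensity, None)
    male = ds.intensities.columns.isin(ds.male_samples)
    mean_m = clipped[:, male].mean(axis=1)
    mean_f = clipped[:, ~male].mean(axis=1)
    mf = mean_m / mean_f
    table = pd.DataFrame(
        {
            "mean_male": mean_m,
            "mean_female": mean_f,
            "mf_ratio": mf,
            "log2_mf": np.log2(mf),
            "fm_ratio": 1.0 / mf,
        },
        index=ds.probeset_ids.copy(),
    )
    return SexRatioTable(table=table, floor_intensity=floor_intensity)
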