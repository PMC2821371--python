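"""Ratio-band classification and per-chromosome summaries.

Two classifications are produced from the M:F ratios:

* **bias calls** — a two-stage funnel: a probeset must first be significant
  in the SAM test (5% FDR by default) and then pass a ratio band
  (M:F strictly between 1.5 and 3.2 for male bias; F:M above 1.5 for female
  bias, with no upper bound since female excesses can be enormous for
  W-linked genes).
* **compensation calls** — a pure ratio banding of (typically Z-linked)
  probesets: compensated for M:F in [0.8, 1.3], non-compensated for
  M:F >= 1.5, intermediate otherwise.  Band endpoints are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BandsConfig, ExpressionDataset, ProbesetAnnotation
from .preprocess import DEFAULT_FLOOR, SexRatioTable
from .sam_stats import SamResult

logger = logging.getLogger(__name__)

COMPENSATED = "compensated"
NON_COMPENSATED = "non_compensated"
INTERMEDIATE = "intermediate"

#: chromosomes excluded from per-chromosome mean summaries: 32 is not
#: annotated, W is female-specific and swamps ratio plots.
SUMMARY_EXCLUDED = ("32", "W", "Un_random", "unknown")


@dataclass
class BiasFunnel:
    """Stage counts of the FDR -> ratio funnel, per direction."""

    n_significant_male: int
    n_ratio_male: int
    n_significant_female: int
    n_ratio_female: int


def classify_bias(
    sam: SamResult, ratios: SexRatioTable, bands: BandsConfig | None = None
) -> tuple[pd.DataFrame, BiasFunnel]:
    """Two-stage sex-bias calls.

    Returns a table indexed by probeset id with columns ``direction``
    ({male, female, none}), ``passed_fdr``, ``passed_ratio`` and
    ``mf_ratio``, plus the funnel stage counts.  The ratio-stage list is by
    construction a subset of the FDR-stage list.
    """
    bands = bands or BandsConfig()
    if not sam.table.index.equals(ratios.probeset_ids):
        raise ValueError("SAM result and ratio table cover different probesets")
    mf = ratios.mf_ratio.to_numpy()
    fm = 1.0 / mf
    sig_male = (sam.table["called_direction"] == "male").to_numpy()
    sig_female = (sam.table["called_direction"] == "female").to_numpy()
    ratio_male = sig_male & (mf > bands.biased_min) & (mf < bands.biased_max)
    ratio_female = sig_female & (fm > bands.biased_min)
    direction = np.full(len(mf), "none", dtype=object)
    direction[ratio_male] = "male"
    direction[ratio_female] = "female"
    table = pd.DataFrame(
        {
            "direction": direction,
            "passed_fdr": sig_male | sig_female,
            "passed_ratio": ratio_male | ratio_female,
            "mf_ratio": mf,
        },
        index=ratios.probeset_ids.copy(),
    )
    funnel = BiasFunnel(
        n_significant_male=int(sig_male.sum()),
        n_ratio_male=int(ratio_male.sum()),
        n_significant_female=int(sig_female.sum()),
        n_ratio_female=int(ratio_female.sum()),
    )
    return table, funnel


def classify_compensation(
    ratios: SexRatioTable,
    bands: BandsConfig | None = None,
    probesets: pd.Index | None = None,
) -> pd.DataFrame:
    """Three-way compensated / non-compensated / intermediate banding.

    When *probesets* is given (e.g. the expressed Z-linked subset) only
    those rows are classified.  Every ratio maps to exactly one class.
    """
    bands = bands or BandsConfig()
    table = ratios.table if probesets is None else ratios.table.loc[probesets]
    mf = table["mf_ratio"].to_numpy()
    cls = np.full(len(mf), INTERMEDIATE, dtype=object)
    cls[(mf >= bands.comp_lo) & (mf <= bands.comp_hi)] = COMPENSATED
    cls[mf >= bands.noncomp_min] = NON_COMPENSATED
    return pd.DataFrame({"class": cls, "mf_ratio": mf}, index=table.index.copy())


def chromosome_distribution(
    probesets: pd.Index, annotation: ProbesetAnnotation
) -> pd.Series:
    """Count probesets per chromosome (unknown stratum for unannotated ids)."""
    chrom = annotation.chromosome_of(probesets)
    counts = chrom.value_counts()
    counts.name = "n_probesets"
    return counts


def rank_sum_compare(
    values_a: np.ndarray, values_b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    The p-value is exact (full enumeration of rank arrangements) for small
    tie-free inputs (n_a + n_b <= 12); otherwise the normal approximation
    with tie and continuity corrections is used.  Returns (U of the first
    sample, p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ChromosomeSummary:
    """Per-chromosome ratio means and per-sex stratum expression means."""

    per_chromosome: pd.DataFrame  # index chromosome; n, mean_log2_mf
    strata_expression: pd.DataFrame  # index stratum; n, mean_log2_male, mean_log2_female
    z_vs_autosome_p: float
    z_vs_autosome_u: float


def chromosome_summary(
    ds: ExpressionDataset,
    ratios: SexRatioTable,
    annotation: ProbesetAnnotation,
    compensation: pd.DataFrame | None = None,
    floor_intensity: float = DEFAULT_FLOOR,
) -> ChromosomeSummary:
    """Mean log2(M:F) per chromosome plus stratified per-sex expression means.

    Chromosome 32 (unannotated), W, and the unplaced strata are excluded
    from the per-chromosome table.  Expression strata are: autosomes, all
    expressed Z probesets, and (when compensation calls are supplied)
    compensated and non-compensated Z probesets; means are of per-probeset
    log2 mean intensities within each sex.
    """
    chrom = annotation.chromosome_of(ratios.probeset_ids)
    log2_mf = ratios.log2_mf

    rows = []
    for name, grp in log2_mf.groupby(chrom):
        if name in SUMMARY_EXCLUDED:
            continue
        rows.append({"chromosome": name, "n": len(grp), "mean_log2_mf": grp.mean()})
    per_chrom = pd.DataFrame(rows).set_index("chromosome")

    autosomal = ~chrom.isin(["Z", "W", "Un_random", "unknown", "32"])
    on_z = chrom == "Z"
    if autosomal.sum() == 0 or on_z.sum() == 0:
        raise ValueError("need both autosomal and Z probesets for the comparison")
    u, p = rank_sum_compare(
        log2_mf[on_z].to_numpy(), log2_mf[autosomal].to_numpy()
    )

    lin = np.clip(ds.intensities.to_numpy(dtype=float), floor_intensity, None)
    male = ds.intensities.columns.isin(ds.male_samples)
    log2_mean_m = pd.Series(
        np.log2(lin[:, male].mean(1)), index=ds.probeset_ids
    ).reindex(ratios.probeset_ids)
    log2_mean_f = pd.Series(
        np.log2(lin[:, ~male].mean(1)), index=ds.probeset_ids
    ).reindex(ratios.probeset_ids)

    strata: dict[str, pd.Index] = {
        "autosomes": ratios.probeset_ids[autosomal.to_numpy()],
        "Z": ratios.probeset_ids[on_z.to_numpy()],
    }
    if compensation is not None:
        z_comp = compensation.index[compensation["class"] == COMPENSATED]
        z_noncomp = compensation.index[compensation["class"] == NON_COMPENSATED]
        strata["Z_compensated"] = z_comp
        strata["Z_non_compensated"] = z_noncomp
    srows = []
    for name, idx in strata.items():
        if len(idx) == 0:
            logger.warning("stratum %s is empty; omitted from summary", name)
            continue
        srows.append(
            {
                "stratum": name,
                "n": len(idx),
                "mean_log2_male": float(log2_mean_m.loc[idx].mean()),
                "mean_log2_female": float(log2_mean_f.loc[idx].mean()),
            }
        )
    strata_df = pd.DataFrame(srows).set_index("stratum")
    return ChromosomeSummary(
        per_chromosome=per_chrom,
        strata_expression=strata_df,
        z_vs_autosome_p=p,
        z_vs_autosome_u=u,
    )
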