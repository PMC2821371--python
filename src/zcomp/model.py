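"""End-to-end dosage-compensation analysis as a model/results pair.

:class:`DosageCompensationModel` bundles an expression dataset, its probeset
annotation and a :class:`~zcomp.io_formats.RunConfig`; :meth:`fit` runs the
full pipeline — detection filtering, SAM differential testing, ratio-band
classification, chromosome summaries and Z-chromosome positional profiles —
and returns a :class:`DosageCompensationResults` carrying every intermediate
table plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chrom_profile, dosage_classify, preprocess, sam_stats
from .io_formats import (
    ExpressionDataset,
    ProbesetAnnotation,
    RunConfig,
    read_annotation,
    read_expression,
)


class DosageCompensationModel:
    """Sex-dimorphism / Z-dosage analysis of one expression experiment."""

    def __init__(
        self,
        dataset: ExpressionDataset,
        annotation: ProbesetAnnotation,
        config: RunConfig | None = None,
    ) -> None:
        self.dataset = dataset
        self.annotation = annotation
        self.config = config or RunConfig()
        self.dataset.require_both_sexes(min_per_sex=2)

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        calls_path: str | Path,
        sex_path: str | Path,
        annotation_path: str | Path,
        config: RunConfig | None = None,
    ) -> "DosageCompensationModel":
        ds = read_expression(matrix_path, calls_path, sex_path)
        ann = read_annotation(annotation_path)
        return cls(ds, ann, config)

    def fit(self) -> "DosageCompensationResults":
        cfg = self.config
        filtered = preprocess.detection_filter(
            self.dataset, cfg.filter.min_present_fraction
        )
        ratios = preprocess.sex_ratios(filtered)
        sam = sam_stats.sam_test(filtered, cfg.sam)
        bias, funnel = dosage_classify.classify_bias(sam, ratios, cfg.bands)

        z_ids = ratios.probeset_ids.intersection(self.annotation.on_chromosome("Z"))
        compensation = dosage_classify.classify_compensation(
            ratios, cfg.bands, probesets=z_ids
        )
        summary = dosage_classify.chromosome_summary(
            filtered, ratios, self.annotation, compensation
        )

        z_profile = z_amplitude = z_distribution = None
        region = None
        if len(z_ids) >= cfg.profile.window:
            z_pos = (
                self.annotation.table.loc[z_ids, "position_bp"]
                .astype(float)
                .to_numpy()
            )
            z_log2 = ratios.log2_mf.loc[z_ids].to_numpy()
            z_idarr = z_ids.to_numpy(dtype=object)
            z_profile = chrom_profile.running_average(
                z_pos, z_log2, cfg.profile.window, ids=z_idarr
            )
            z_amplitude = chrom_profile.amplitude_profile(
                z_pos, z_log2, cfg.profile.window, ids=z_idarr
            )
            z_distribution = chrom_profile.ratio_distribution(z_log2)
            if (
                cfg.profile.region_start_bp is not None
                and cfg.profile.region_end_bp is not None
            ):
                region = chrom_profile.region_contrast(
                    z_pos,
                    np.abs(z_log2),
                    (cfg.profile.region_start_bp, cfg.profile.region_end_bp),
                )

        return DosageCompensationResults(
            model=self,
            filtered=filtered,
            ratios=ratios,
            sam=sam,
            bias_calls=bias,
            bias_funnel=funnel,
            compensation_calls=compensation,
            chromosome=summary,
            z_ratio_profile=z_profile,
            z_amplitude_profile=z_amplitude,
            z_ratio_distribution=z_distribution,
            mhm_contrast=region,
        )


@dataclass
class DosageCompensationResults:
    """Fitted pipeline output; every stage's table is an attribute."""

    model: DosageCompensationModel
    filtered: ExpressionDataset
    ratios: preprocess.SexRatioTable
    sam: sam_stats.SamResult
    bias_calls: pd.DataFrame
    bias_funnel: dosage_classify.BiasFunnel
    compensation_calls: pd.DataFrame
    chromosome: dosage_classify.ChromosomeSummary
    z_ratio_profile: pd.DataFrame | None = None
    z_amplitude_profile: pd.DataFrame | None = None
    z_ratio_distribution: chrom_profile.RatioDistribution | None = None
    mhm_contrast: chrom_profile.RegionContrast | None = field(default=None)

    # -- headline quantities -------------------------------------------------

    @property
    def n_retained(self) -> int:
        return self.filtered.n_probesets

    @property
    def male_biased(self) -> pd.Index:
        return self.bias_calls.index[self.bias_calls["direction"] == "male"]

    @property
    def female_biased(self) -> pd.Index:
        return self.bias_calls.index[self.bias_calls["direction"] == "female"]

    def z_mean_log2_mf(self) -> float:
        return float(self.chromosome.per_chromosome.loc["Z", "mean_log2_mf"])

    def autosome_mean_log2_mf(self) -> float:
        per = self.chromosome.per_chromosome
        autosomes = per.index[per.index != "Z"]
        weights = per.loc[autosomes, "n"]
        vals = per.loc[autosomes, "mean_log2_mf"]
        return float((vals * weights).sum() / weights.sum())

    def compensation_counts(self) -> pd.Series:
        return self.compensation_calls["class"].value_counts()

    def summary(self) -> str:
        comp = self.compensation_counts()
        lines = [
            "Dosage compensation analysis",
            "=" * 60,
            f"samples: {len(self.filtered.male_samples)} male / "
            f"{len(self.filtered.female_samples)} female",
            f"probesets retained by Present filter: {self.n_retained} of "
            f"{self.model.dataset.n_probesets}",
            "",
            "SAM (FDR target "
            f"{self.sam.target_fdr:.0%}, s0={self.sam.s0:.4g}, "
            f"{self.sam.n_arrangements} permutations"
            f"{', exhaustive' if self.sam.exhaustive else ''}):",
            f"  male-significant probesets:   {self.bias_funnel.n_significant_male}",
            f"  male-biased (ratio band):     {self.bias_funnel.n_ratio_male}",
            f"  female-significant probesets: {self.bias_funnel.n_significant_female}",
            f"  female-biased (ratio band):   {self.bias_funnel.n_ratio_female}",
            "",
            "Z chromosome:",
            f"  expressed Z probesets: {len(self.compensation_calls)}",
            f"  compensated (M:F 0.8-1.3):    {int(comp.get('compensated', 0))}",
            f"  non-compensated (M:F >= 1.5): {int(comp.get('non_compensated', 0))}",
            f"  mean log2(M:F) on Z:        {self.z_mean_log2_mf():.3f}",
            f"  mean log2(M:F) on autosomes: {self.autosome_mean_log2_mf():.3f}",
            f"  Z vs autosome rank-sum p:    {self.chromosome.z_vs_autosome_p:.3g}",
        ]
        if self.mhm_contrast is not None:
            c = self.mhm_contrast
            lines += [
                "",
                "Region contrast (|log2 M:F|, region vs rest of Z):",
                f"  inside mean {c.inside_mean:.3f} (n={c.n_inside}), "
                f"outside mean {c.outside_mean:.3f} (n={c.n_outside}), "
                f"p = {c.p_value:.3g}",
            ]
        return "\n".join(lines)
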