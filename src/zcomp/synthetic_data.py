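"""Synthetic expression datasets with a known dosage-compensation structure.

The generator emulates an 18-array (9 male ZZ / 9 female ZW) MAS5-style
experiment: autosomal probesets with M:F near 1, Z-linked probesets that are
a mixture of compensated (M:F ~ 1) and non-compensated (M:F ~ 2, realized by
attenuating the female channel — males never receive a boost), W-linked
probesets expressed in females only, log-normal intensity noise, and an
intensity-dependent logistic Present/Absent detection model.  Compensated
Z probesets cluster preferentially inside a designated MHM-like window so
that valley detection along the chromosome is testable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, ProbesetAnnotation, FEMALE, MALE

CLASS_AUTOSOMAL = "autosomal"
CLASS_Z_COMP = "z_compensated"
CLASS_Z_NONCOMP = "z_noncompensated"
CLASS_W = "w_female"


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated experiment.

    Counts give probesets per compartment; ``frac_z_compensated`` is the
    fraction of Z probesets with M:F equal to ``compensated_mf`` (the rest
    sit at ``noncompensated_mf``, realized via reduced female expression).
    Log-scale parameters are in log2 units of linear MAS5-like intensity.
    """

    seed: int = 0
    n_per_sex: int = 9
    n_autosomal: int = 3000
    n_z: int = 689
    n_w: int = 30
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    frac_z_compensated: float = 0.3
    noncompensated_mf: float = 2.0
    compensated_mf: float = 1.0
    mhm_window: Tuple[float, float] = (25_000_000, 30_000_000)
    mhm_compensated_boost: float = 0.5
    w_fm_log2: float = 6.0
    z_length_bp: int = 75_000_000
    autosome_length_bp: int = 50_000_000
    detection_floor: float = 1.0
    detection_midpoint: float = 3.0
    detection_slope: float = 1.5
    #: optional per-probeset extra log2 male-minus-female effects keyed by
    #: probeset id (e.g. to plant female-biased autosomal genes); applied by
    #: attenuating whichever sex is lower.
    extra_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_autosomal, self.n_z, self.n_w) < 0:
            raise ValueError("probeset counts must be non-negative")
        if self.n_per_sex <= 0:
            raise ValueError("need at least one sample per sex")
        if not 0 <= self.frac_z_compensated <= 1:
            raise ValueError("frac_z_compensated must lie in [0, 1]")
        if self.noncompensated_mf <= self.compensated_mf:
            raise ValueError("noncompensated_mf must exceed compensated_mf")
        lo, hi = self.mhm_window
        if not (0 <= lo < hi <= self.z_length_bp):
            raise ValueError("mhm_window must lie inside the simulated Z chromosome")


@dataclass
class SimTruth:
    """Per-probeset ground truth emitted alongside a simulated dataset."""

    table: pd.DataFrame  # columns: true_class, true_mf_ratio, chromosome, position_bp
    config: SimulationConfig

    @property
    def classes(self) -> pd.Series:
        return self.table["true_class"]


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ProbesetAnnotation, SimTruth]:
    """Draw one experiment from the generative model.

    Per probeset, a true log2 abundance (the male expectation) is drawn from
    N(baseline_log2_mean, baseline_log2_sd); the female expectation is the
    male one minus log2(true M:F).  Observations add N(0, noise_log2_sd) on
    the log2 scale and are exponentiated, with ``detection_floor`` added so
    linear values stay positive.  Detection is Present with logistic
    probability in the true (noise-free) log2 intensity of that sex.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_autosomal + config.n_z + config.n_w

    ids = np.array(
        [f"SIMA.{i}" for i in range(config.n_autosomal)]
        + [f"SIMZ.{i}" for i in range(config.n_z)]
        + [f"SIMW.{i}" for i in range(config.n_w)]
    )
    chromosome = np.array(
        ["1"] * config.n_autosomal + ["Z"] * config.n_z + ["W"] * config.n_w
    )

    # positions first (independent of class), then class assignment with the
    # compensated count fixed exactly and membership weighted toward the MHM
    # window.
    positions = np.empty(n_total, dtype=np.int64)
    a_sl = slice(0, config.n_autosomal)
    z_sl = slice(config.n_autosomal, config.n_autosomal + config.n_z)
    w_sl = slice(config.n_autosomal + config.n_z, n_total)
    positions[a_sl] = rng.integers(1, config.autosome_length_bp + 1, config.n_autosomal)
    positions[z_sl] = rng.integers(1, config.z_length_bp + 1, config.n_z)
    positions[w_sl] = rng.integers(1, config.z_length_bp // 10 + 1, config.n_w)

    true_class = np.array([CLASS_AUTOSOMAL] * n_total, dtype=object)
    true_class[w_sl] = CLASS_W
    z_pos = positions[z_sl]
    n_comp = int(round(config.frac_z_compensated * config.n_z))
    comp_idx = _pick_compensated(rng, z_pos, n_comp, config)
    z_classes = np.array([CLASS_Z_NONCOMP] * config.n_z, dtype=object)
    z_classes[comp_idx] = CLASS_Z_COMP
    true_class[z_sl] = z_classes

    true_mf = np.ones(n_total)
    true_mf[z_sl] = np.where(
        z_classes == CLASS_Z_COMP, config.compensated_mf, config.noncompensated_mf
    )
    true_mf[w_sl] = 2.0 ** (-config.w_fm_log2)  # female excess => M:F << 1

    # expectations per sex on log2 scale; dosage acts by attenuation of the
    # lower-expressed sex, never by boosting the higher one.
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_total)
    log2_mf = np.log2(true_mf)
    male_mu = baseline.copy()
    female_mu = baseline - log2_mf
    # W probesets: female channel at baseline, male channel attenuated.
    female_mu[w_sl] = baseline[w_sl]
    male_mu[w_sl] = baseline[w_sl] - config.w_fm_log2
    for pid, eff in config.extra_effects.items():
        where = np.flatnonzero(ids == pid)
        if where.size == 0:
            raise ValueError(f"extra_effects references unknown probeset {pid!r}")
        i = where[0]
        if eff >= 0:
            female_mu[i] -= eff
        else:
            male_mu[i] += eff  # negative effect: attenuate the male channel
        true_mf[i] *= 2.0 ** (male_mu[i] - female_mu[i] - log2_mf[i])

    n_m = n_f = config.n_per_sex
    noise_m = rng.normal(0.0, config.noise_log2_sd, (n_total, n_m))
    noise_f = rng.normal(0.0, config.noise_log2_sd, (n_total, n_f))
    lin_m = 2.0 ** (male_mu[:, None] + noise_m) + config.detection_floor
    lin_f = 2.0 ** (female_mu[:, None] + noise_f) + config.detection_floor

    p_present_m = _logistic(male_mu, config)[:, None] * np.ones((1, n_m))
    p_present_f = _logistic(female_mu, config)[:, None] * np.ones((1, n_f))
    calls_m = np.where(rng.random((n_total, n_m)) < p_present_m, "P", "A")
    calls_f = np.where(rng.random((n_total, n_f)) < p_present_f, "P", "A")

    sample_ids = [f"M{i+1}" for i in range(n_m)] + [f"F{i+1}" for i in range(n_f)]
    intensities = pd.DataFrame(
        np.hstack([lin_m, lin_f]), index=pd.Index(ids, name="probeset_id"),
        columns=sample_ids,
    )
    detection = pd.DataFrame(
        np.hstack([calls_m, calls_f]), index=intensities.index, columns=sample_ids
    )
    sex = pd.Series([MALE] * n_m + [FEMALE] * n_f, index=sample_ids, name="sex")
    dataset = ExpressionDataset(intensities, detection, sex)

    annotation = ProbesetAnnotation(
        pd.DataFrame(
            {
                "chromosome": chromosome,
                "position_bp": pd.array(positions, dtype="Int64"),
                "gene_id": [f"GENE.{pid}" for pid in ids],
                "quality": np.round(rng.uniform(0.5, 1.0, n_total), 3),
            },
            index=intensities.index,
        )
    )
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "true_class": true_class,
                "true_mf_ratio": true_mf,
                "chromosome": chromosome,
                "position_bp": positions,
            },
            index=intensities.index,
        ),
        config=config,
    )
    return dataset, annotation, truth


def _logistic(log2_mu: np.ndarray, config: SimulationConfig) -> np.ndarray:
    z = config.detection_slope * (log2_mu - config.detection_midpoint)
    return 1.0 / (1.0 + np.exp(-z))


def _pick_compensated(
    rng: np.random.Generator,
    z_positions: np.ndarray,
    n_comp: int,
    config: SimulationConfig,
) -> np.ndarray:
    """Choose exactly ``n_comp`` compensated Z probesets, spatially biased.

    Sampling is without replacement with weights elevated inside the MHM
    window by ``(p0 + boost) / p0`` where p0 = frac_z_compensated, so the
    within-window compensated probability is raised toward p0 + boost while
    the overall compensated count stays exact.
    """
    n_z = z_positions.size
    if n_comp == 0:
        return np.empty(0, dtype=int)
    if n_comp >= n_z:
        return np.arange(n_z)
    lo, hi = config.mhm_window
    inside = (z_positions >= lo) & (z_positions <= hi)
    p0 = max(config.frac_z_compensated, 1e-12)
    p_in = min(config.frac_z_compensated + config.mhm_compensated_boost, 1.0)
    weights = np.where(inside, p_in / p0, 1.0).astype(float)
    weights /= weights.sum()
    return rng.choice(n_z, size=n_comp, replace=False, p=weights)


def truth_summary(truth: SimTruth) -> pd.DataFrame:
    """Per-class tally with the expected mean log2 M:F of each class.

    The Z-wide expectation is the mixture value
    frac_comp * log2(comp_mf) + (1 - frac_comp) * log2(noncomp_mf),
    computed from realized class counts (which match the config exactly).
    """
    cls = truth.table["true_class"]
    log2_mf = np.log2(truth.table["true_mf_ratio"].to_numpy(dtype=float))
    rows = []
    for name in (CLASS_AUTOSOMAL, CLASS_Z_COMP, CLASS_Z_NONCOMP, CLASS_W):
        mask = (cls == name).to_numpy()
        rows.append(
            {
                "class": name,
                "n": int(mask.sum()),
                "expected_mean_log2_mf": float(log2_mf[mask].mean()) if mask.any() else np.nan,
            }
        )
    z_mask = cls.isin([CLASS_Z_COMP, CLASS_Z_NONCOMP]).to_numpy()
    rows.append(
        {
            "class": "z_all",
            "n": int(z_mask.sum()),
            "expected_mean_log2_mf": float(log2_mf[z_mask].mean()) if z_mask.any() else np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("class")
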