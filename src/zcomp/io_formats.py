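"""Tabular input/output and run configuration.

All artifacts are UTF-8, tab-separated text with '.' decimal separators.
Expression matrices carry probesets in rows and samples in columns; the
first header cell is ignored.  Detection calls use the MAS5 vocabulary
{Present, Marginal, Absent}, accepted either spelled out or as single
letters {P, M, A}, case-insensitively, and stored internally as P/M/A.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
SEX_LABELS = frozenset({MALE, FEMALE})

#: canonical chromosome names: assembled autosomes, sex chromosomes, and
#: the two catch-all strata used for unplaced/unannotated probesets.
CANONICAL_CHROMOSOMES = frozenset(
    {str(i) for i in range(1, 29)} | {"32", "Z", "W", "Un_random", "unknown"}
)

_CALL_ALIASES = {
    "p": "P", "present": "P",
    "m": "M", "marginal": "M",
    "a": "A", "absent": "A",
}


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Normalized expression matrix with detection calls and sample sexes.

    Parameters
    ----------
    intensities
        Probeset x sample matrix of linear-scale, non-negative normalized
        expression values (MAS5-style units).
    detection
        Matrix of detection calls, same shape/labels as ``intensities``,
        values in {"P", "M", "A"}.
    sex
        Per-sample label in {"male", "female"}, indexed by sample id.
    """

    intensities: pd.DataFrame
    detection: pd.DataFrame
    sex: pd.Series

    def __post_init__(self) -> None:
        if self.intensities.shape != self.detection.shape:
            raise FormatError(
                f"intensity matrix {self.intensities.shape} and call matrix "
                f"{self.detection.shape} have different dimensions"
            )
        if list(self.intensities.index) != list(self.detection.index) or list(
            self.intensities.columns
        ) != list(self.detection.columns):
            raise FormatError("intensity and call matrices are labeled differently")
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise FormatError(f"duplicate probeset ids: {sorted(set(dups))[:5]}")
        vals = self.intensities.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("intensity matrix contains missing or non-finite values")
        if (vals < 0).any():
            raise FormatError("intensity matrix contains negative values")
        bad_calls = set(np.unique(self.detection.to_numpy(dtype=str))) - {"P", "M", "A"}
        if bad_calls:
            raise FormatError(f"invalid detection calls: {sorted(bad_calls)}")
        missing = [s for s in self.intensities.columns if s not in self.sex.index]
        if missing:
            raise FormatError(f"samples missing from sex file: {missing}")
        self.sex = self.sex.loc[self.intensities.columns]
        bad_sex = set(self.sex) - SEX_LABELS
        if bad_sex:
            raise FormatError(f"invalid sex labels: {sorted(bad_sex)}")

    # -- convenience views --------------------------------------------------

    @property
    def probeset_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_probesets(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def male_samples(self) -> pd.Index:
        return self.sex.index[self.sex == MALE]

    @property
    def female_samples(self) -> pd.Index:
        return self.sex.index[self.sex == FEMALE]

    def require_both_sexes(self, min_per_sex: int = 2) -> None:
        n_m, n_f = len(self.male_samples), len(self.female_samples)
        if n_m < min_per_sex or n_f < min_per_sex:
            raise ValueError(
                f"need at least {min_per_sex} samples of each sex "
                f"(got {n_m} male, {n_f} female)"
            )

    def subset(self, probesets: Iterable[str]) -> "ExpressionDataset":
        """Row-subset preserving order of *probesets*."""
        idx = pd.Index(probesets)
        return ExpressionDataset(
            intensities=self.intensities.loc[idx],
            detection=self.detection.loc[idx],
            sex=self.sex.copy(),
        )

    def swap_sexes(self) -> "ExpressionDataset":
        """Relabel every male as female and vice versa (for symmetry checks)."""
        flipped = self.sex.map({MALE: FEMALE, FEMALE: MALE})
        return ExpressionDataset(self.intensities, self.detection, flipped)


@dataclass
class ProbesetAnnotation:
    """Probeset -> (chromosome, position, gene, annotation quality) table.

    ``table`` is indexed by probeset id with columns ``chromosome`` (str,
    canonical name), ``position_bp`` (nullable integer, 1-based), ``gene_id``
    (nullable str) and ``quality`` (float, higher = better annotated).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()]
            raise FormatError(f"duplicate probeset annotation rows: {sorted(set(dups))[:5]}")
        bad = set(self.table["chromosome"]) - CANONICAL_CHROMOSOMES
        if bad:
            raise FormatError(f"non-canonical chromosome names: {sorted(bad)}")
        assembled = ~self.table["chromosome"].isin(["Un_random", "unknown"])
        if self.table.loc[assembled, "position_bp"].isna().any():
            missing = self.table.index[assembled & self.table["position_bp"].isna()]
            raise FormatError(
                f"probesets on assembled chromosomes lack positions: {list(missing[:5])}"
            )

    @property
    def probeset_ids(self) -> pd.Index:
        return self.table.index

    def chromosome_of(self, probesets: Iterable[str]) -> pd.Series:
        """Chromosome per probeset; ids absent from the table map to 'unknown'."""
        idx = pd.Index(probesets)
        out = self.table["chromosome"].reindex(idx)
        return out.fillna("unknown")

    def on_chromosome(self, chromosome: str) -> pd.Index:
        return self.table.index[self.table["chromosome"] == chromosome]


def normalize_chromosome(name: object) -> str:
    """Map a raw chromosome field onto the canonical naming.

    Strips an optional ``chr`` prefix, so e.g. ``chrUn_random`` becomes
    ``Un_random`` and ``chrZ`` becomes ``Z``.  Blank or unrecognized names
    fall back to ``unknown``.
    """
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return "unknown"
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in ("", "NA", "na", "nan", "-"):
        return "unknown"
    if s.lower() == "un_random":
        return "Un_random"
    s_up = s.upper() if s.upper() in ("Z", "W") else s
    if s_up in CANONICAL_CHROMOSOMES:
        return s_up
    logger.warning("unrecognized chromosome name %r mapped to 'unknown'", name)
    return "unknown"


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    min_present_fraction: float = 0.5


@dataclass
class SamSettings:
    """Settings for the SAM permutation test (see :mod:`zcomp.sam_stats`)."""

    n_permutations: int = 1000
    seed: int = 0
    s0_strategy: str = "cv_minimization"  # or "fixed_percentile"
    s0_percentile: float = 5.0
    target_fdr: float = 0.05
    n_deltas: int = 60
    fdr_statistic: str = "median"  # or "mean"
    exhaustive_cap: int = 50000
    include_original: bool = True


@dataclass
class BandsConfig:
    """Ratio bands for bias and compensation calls (linear M:F scale)."""

    biased_min: float = 1.5
    biased_max: float = 3.2
    comp_lo: float = 0.8
    comp_hi: float = 1.3
    noncomp_min: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.comp_lo < self.comp_hi < self.noncomp_min):
            raise ValueError("require 0 < comp_lo < comp_hi < noncomp_min")
        if self.biased_min <= 0 or self.biased_max <= self.biased_min:
            raise ValueError("require 0 < biased_min < biased_max")


@dataclass
class ProfileConfig:
    window: int = 30
    region_start_bp: int | None = None
    region_end_bp: int | None = None


@dataclass
class OverlapConfig:
    n_sims: int = 10000
    seed: int = 0


@dataclass
class EnrichConfig:
    background_mode: str = "transcriptome"  # or "genome"
    seed: int = 0


@dataclass
class RunConfig:
    """Bundle of every stage's thresholds and seeds."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    sam: SamSettings = field(default_factory=SamSettings)
    bands: BandsConfig = field(default_factory=BandsConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    enrichment: EnrichConfig = field(default_factory=EnrichConfig)

    def __post_init__(self) -> None:
        if not 0 < self.filter.min_present_fraction <= 1:
            raise ValueError("min_present_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {
            "filter": FilterConfig,
            "sam": SamSettings,
            "bands": BandsConfig,
            "profile": ProfileConfig,
            "overlap": OverlapConfig,
            "enrichment": EnrichConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            kwargs[name] = klass(**raw.get(name, {}))
        unknown = set(raw) - set(sections)
        if unknown:
            raise FormatError(f"unknown config sections: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def digest(self) -> str:
        """Short stable hash of the full configuration, for output headers."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def read_expression(
    matrix_path: str | Path,
    calls_path: str | Path,
    sex_path: str | Path,
) -> ExpressionDataset:
    """Read an intensity matrix, its detection-call matrix and sex labels.

    The call matrix is re-ordered to match the intensity matrix by probeset
    and sample id; a mismatch in either id set is an error.
    """
    intensities = _read_table(matrix_path).astype(float)
    calls = _read_table(calls_path)
    for name, df in (("intensity", intensities), ("call", calls)):
        if df.index.has_duplicates:
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise FormatError(f"duplicate probeset ids in {name} matrix: {dups[:5]}")
    if set(calls.index) != set(intensities.index) or set(calls.columns) != set(
        intensities.columns
    ):
        raise FormatError(
            f"call matrix ids do not match intensity matrix "
            f"({calls.shape[0]}x{calls.shape[1]} calls vs "
            f"{intensities.shape[0]}x{intensities.shape[1]} intensities)"
        )
    calls = calls.loc[intensities.index, intensities.columns]
    calls = calls.map(_normalize_call)

    sex_df = pd.read_csv(
        sex_path, sep="\t", header=None, names=["sample_id", "sex"], comment="#"
    )
    if sex_df["sample_id"].astype(str).iloc[0].lower() in ("sample_id", "sample"):
        sex_df = sex_df.iloc[1:]
    sex = pd.Series(
        sex_df["sex"].astype(str).str.strip().str.lower().to_numpy(),
        index=sex_df["sample_id"].astype(str).str.strip(),
        name="sex",
    )
    return ExpressionDataset(intensities=intensities, detection=calls, sex=sex)


def _normalize_call(value: object) -> str:
    key = str(value).strip().lower()
    if key not in _CALL_ALIASES:
        raise FormatError(f"unrecognized detection call {value!r}")
    return _CALL_ALIASES[key]


def write_expression(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    calls_path: str | Path,
    sex_path: str | Path,
) -> None:
    ds.intensities.to_csv(matrix_path, sep="\t", index_label="probeset_id")
    ds.detection.to_csv(calls_path, sep="\t", index_label="probeset_id")
    ds.sex.to_csv(sex_path, sep="\t", header=False)


def read_annotation(path: str | Path) -> ProbesetAnnotation:
    """Read the probeset annotation table.

    Expected columns: probeset_id, chromosome, position_bp, gene_id, quality.
    Positions and gene ids may be blank; chromosome names are normalized to
    the canonical set.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"probeset_id": str, "gene_id": str},
        comment="#",
    )
    required = ["probeset_id", "chromosome", "position_bp", "gene_id", "quality"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file lacks columns: {missing}")
    pos = pd.to_numeric(df["position_bp"], errors="coerce")
    stated = df["position_bp"].notna() & (df["position_bp"].astype(str).str.strip() != "")
    bad_pos = stated & pos.isna()
    if bad_pos.any():
        raise FormatError(
            f"non-numeric position_bp for probesets: "
            f"{list(df.loc[bad_pos, 'probeset_id'][:5])}"
        )
    if ((pos.dropna() % 1) != 0).any():
        raise FormatError("position_bp must be integer base pairs")
    gene = df["gene_id"].where(df["gene_id"].notna() & (df["gene_id"] != ""))
    table = pd.DataFrame(
        {
            "chromosome": df["chromosome"].map(normalize_chromosome).to_numpy(),
            "position_bp": pd.array(pos.to_numpy(), dtype="Int64"),
            "gene_id": gene.to_numpy(),
            "quality": pd.to_numeric(df["quality"], errors="coerce").to_numpy(dtype=float),
        },
        index=pd.Index(df["probeset_id"].astype(str), name="probeset_id"),
    )
    return ProbesetAnnotation(table)


def write_annotation(ann: ProbesetAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="probeset_id")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read term -> gene-set definitions from GMT or two-column text.

    GMT lines are ``term <TAB> description <TAB> gene1 <TAB> gene2 ...``;
    two-column lines are ``term <TAB> gene``.  The format is auto-detected
    from the first data line.  Duplicate genes within a term collapse.
    """
    lines = [
        ln.rstrip("\n")
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty gene-set file: {path}")
    n_fields = len(lines[0].split("\t"))
    sets: dict[str, set[str]] = {}
    if n_fields >= 3:  # GMT
        for i, ln in enumerate(lines, 1):
            parts = ln.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: GMT line has fewer than 3 fields")
            term = parts[0].strip()
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not term:
                raise FormatError(f"{path}:{i}: empty term id")
            if not genes:
                raise FormatError(f"{path}:{i}: term {term!r} has no genes")
            sets.setdefault(term, set()).update(genes)
    elif n_fields == 2:
        for i, ln in enumerate(lines, 1):
            term, gene = (p.strip() for p in ln.split("\t"))
            if not term or not gene:
                raise FormatError(f"{path}:{i}: empty term or gene")
            sets.setdefault(term, set()).add(gene)
    else:
        raise FormatError(f"{path}: cannot detect gene-set format (1 column)")
    return sets


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def write_table(df: pd.DataFrame, path: str | Path, *, config: RunConfig | None = None,
                seed: int | None = None, index: bool = False) -> None:
    """Write a result table with a commented provenance header."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash: {config.digest()}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=index)
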