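"""Term over-representation: probeset->gene collapsing, hypergeometric test,
Benjamini-Hochberg correction.

Probesets map many-to-one onto genes; before gene-level statistics the
multiplicity is removed by keeping, per gene, the probeset with the best
annotation-quality score (full ties broken uniformly at random under a
seed).  Over-representation of a term in a query gene list against a
background (genome or transcriptome) uses the exact hypergeometric right
tail P(X >= k); raw p-values are corrected with the Benjamini-Hochberg
step-up over all terms represented in the background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ProbesetAnnotation

logger = logging.getLogger(__name__)


def collapse_probesets_to_genes(
    probesets: list[str] | pd.Index,
    annotation: ProbesetAnnotation,
    seed: int = 0,
) -> set[str]:
    """Map a probeset list to a de-duplicated gene set.

    Per gene, the highest-quality probeset represents it; exact quality
    ties are broken uniformly at random (reproducibly under *seed*).  The
    resulting gene set is identical whichever tied probeset wins.
    Probesets without a gene assignment are dropped (count logged).
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index(probesets)
    sub = annotation.table.reindex(idx)
    has_gene = sub["gene_id"].notna()
    n_dropped = int((~has_gene).sum())
    if n_dropped:
        logger.info("%d probesets without gene assignment dropped", n_dropped)
    sub = sub[has_gene]
    genes: set[str] = set()
    for gene, grp in sub.groupby("gene_id"):
        best = grp["quality"].max()
        winners = grp.index[grp["quality"] == best]
        _ = winners[rng.integers(len(winners))]  # representative probeset
        genes.add(str(gene))
    return genes


def hypergeometric_enrichment(
    query_genes: set[str],
    term_map: dict[str, set[str]],
    background_genes: set[str],
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term over-representation of the query within the background.

    For each term with at least one background gene, with N = |background|,
    K = background genes carrying the term, n = |query| and k = query genes
    carrying the term, the raw p-value is the exact hypergeometric tail
    P(X >= k).  Returns records sorted by raw p with BH-adjusted p.
    """
    query = set(query_genes)
    background = set(background_genes)
    stray = query - background
    if stray:
        raise ValueError(
            f"query genes absent from background: {sorted(stray)[:5]}"
        )
    n_bg, n_query = len(background), len(query)
    rows = []
    for term, genes in sorted(term_map.items()):
        in_bg = genes & background
        if not in_bg:
            continue
        k = len(in_bg & query)
        big_k = len(in_bg)
        # P(X >= k); sf(k-1) is the exact right tail.  Extreme tails can
        # underflow to 0 in double precision; clip to the smallest normal
        # float so raw_p stays in (0, 1].
        raw_p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_query))
        raw_p = max(raw_p, float(np.finfo(float).tiny))
        rows.append(
            {
                "term_id": term,
                "term_description": (descriptions or {}).get(term, ""),
                "k": k,
                "K": big_k,
                "n": n_query,
                "N": n_bg,
                "raw_p": min(raw_p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_description", "k", "K", "n", "N", "raw_p", "adjusted_p"]
        )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = benjamini_hochberg(df["raw_p"].to_numpy())
    return df.sort_values("raw_p", kind="stable").reset_index(drop=True)


def benjamini_hochberg(raw_p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values, in the input order.

    Equivalent to adjusted_(i) = min_{j >= i} (m * p_(j) / j) on the sorted
    p-values, capped at 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted
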