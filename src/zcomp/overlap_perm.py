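"""Monte-Carlo significance of the overlap between two gene/probeset sets.

Within a declared universe, both sets are re-drawn uniformly at random
(without replacement, keeping their observed sizes) in each simulation and
the overlap recorded; the empirical p-value is the add-one right-tail
estimate (#{simulated overlap >= observed} + 1) / (n_sims + 1).  The
distribution of the simulated overlap is hypergeometric, which provides an
independent closed-form check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

import numpy as np


@dataclass(frozen=True)
class OverlapTestResult:
    n_universe: int
    n_a: int
    n_b: int
    observed_overlap: int
    expected_overlap: float
    empirical_p: float
    n_sims: int
    seed: int


def overlap_significance(
    set_a: Collection[str],
    set_b: Collection[str],
    universe: Iterable[str],
    n_sims: int = 10000,
    seed: int = 0,
) -> OverlapTestResult:
    """Right-tail Monte-Carlo test of |A intersect B| within a universe."""
    universe = list(dict.fromkeys(universe))  # dedupe, keep order
    uni = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= uni:
        raise ValueError(f"set A has {len(a - uni)} elements outside the universe")
    if not b <= uni:
        raise ValueError(f"set B has {len(b - uni)} elements outside the universe")
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    n, n_a, n_b = len(universe), len(a), len(b)
    observed = len(a & b)

    rng = np.random.default_rng(seed)
    # membership via random ranks: the n_a smallest of n iid uniforms are a
    # uniform random subset of size n_a; same independently for B.
    hits = 0
    chunk = max(1, min(n_sims, int(2e7) // max(n, 1)))
    done = 0
    while done < n_sims:
        k = min(chunk, n_sims - done)
        ranks_a = rng.random((k, n)).argpartition(n_a - 1, axis=1)[:, :n_a] if n_a else None
        ranks_b = rng.random((k, n)).argpartition(n_b - 1, axis=1)[:, :n_b] if n_b else None
        if n_a and n_b:
            in_a = np.zeros((k, n), dtype=bool)
            in_b = np.zeros((k, n), dtype=bool)
            rows = np.arange(k)[:, None]
            in_a[rows, ranks_a] = True
            in_b[rows, ranks_b] = True
            sims = (in_a & in_b).sum(axis=1)
        else:
            sims = np.zeros(k, dtype=int)
        hits += int((sims >= observed).sum())
        done += k
    p = (hits + 1) / (n_sims + 1)
    return OverlapTestResult(
        n_universe=n,
        n_a=n_a,
        n_b=n_b,
        observed_overlap=observed,
        expected_overlap=n_a * n_b / n if n else 0.0,
        empirical_p=p,
        n_sims=n_sims,
        seed=seed,
    )
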