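"""Subsampling stability of phenotype assignment as a function of sample size.

Group-mean normalization makes phenotype labels depend on who else is in
the cohort.  This module quantifies that dependence with a permutated
resampling test: for each subsample size k, draw k subjects without
replacement, redetermine the normalization and labels within the
subsample, and compare each sampled subject's label to its full-cohort
label.  The per-subject mismatch probability (disagreements pooled over
subjects and iterations) is the primary statistic; the per-iteration
any-mismatch probability is also reported.  An exhaustive-enumeration
variant over all C(N, k) subsets serves as an exact oracle at small N,
and a recommender returns the smallest k at which the curve stays below
a tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import CombinatorialBoundError
from .phenotype import LABELS, IntakeTable, label_codes

__all__ = [
    "StabilityConfig",
    "StabilityCurve",
    "subsample_assignments",
    "mismatch_curve",
    "exact_mismatch",
    "recommend_min_n",
]

_ENUMERATION_BOUND = 10**6


@dataclass
class StabilityConfig:
    """Parameters of the resampling protocol.

    Defaults follow the standard protocol: every size from 2 up to the
    full cohort, 100 iterations per size, stability tolerance 0.05.
    """

    k_min: int = 2
    k_max: int | None = None
    iterations: int = 100
    tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class StabilityCurve:
    """Empirical phenotype-mismatch probability per subsample size."""

    sizes: np.ndarray
    iterations: int
    mismatch_prob: np.ndarray  # per sampled subject, pooled over iterations
    per_size_se: np.ndarray  # Monte-Carlo SE of the per-iteration fractions
    any_mismatch_prob: np.ndarray  # fraction of iterations with >= 1 mismatch
    seed: int
    tolerance: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.sizes,
                "mismatch_prob": self.mismatch_prob,
                "se": self.per_size_se,
                "any_mismatch_prob": self.any_mismatch_prob,
                "iterations": self.iterations,
            }
        )


def _full_codes(table: IntakeTable) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    subs, a, q = table.subject_means()
    codes = label_codes(a / a.mean() * 100.0, q / q.mean() * 100.0)
    return subs, a, q, codes


def _subset_codes(a: np.ndarray, q: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Labels within subsample(s); idx may be (k,) or (iters, k)."""
    a_s, q_s = a[idx], q[idx]
    a_pct = a_s / a_s.mean(axis=-1, keepdims=True) * 100.0
    q_pct = q_s / q_s.mean(axis=-1, keepdims=True) * 100.0
    return label_codes(a_pct, q_pct)


def subsample_assignments(
    table: IntakeTable, k: int, rng: np.random.Generator
) -> dict[str, str]:
    """Labels for one random k-subset, normalized within the subsample."""
    n = len(table)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    subs, a, q, _ = _full_codes(table)
    idx = rng.choice(n, size=k, replace=False)
    codes = _subset_codes(a, q, idx)
    return {subs[i]: LABELS[c] for i, c in zip(idx, codes)}


def mismatch_curve(table: IntakeTable, cfg: StabilityConfig | None = None) -> StabilityCurve:
    """Monte-Carlo mismatch probability for each subsample size.

    Each (size, iteration) pair gets its own RNG substream spawned from the
    root seed, so curves are bit-reproducible and individual cells can be
    recomputed in isolation.
    """
    cfg = cfg or StabilityConfig()
    n = len(table)
    if n < 3:
        raise ValueError("stability analysis needs a cohort of >= 3 subjects")
    k_max = n if cfg.k_max is None else min(cfg.k_max, n)
    sizes = np.arange(cfg.k_min, k_max + 1)
    _, a, q, full = _full_codes(table)

    mismatch = np.empty(sizes.size)
    se = np.empty(sizes.size)
    any_mm = np.empty(sizes.size)
    for j, k in enumerate(sizes):
        idx = np.empty((cfg.iterations, k), dtype=int)
        for it in range(cfg.iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(int(k), it))
            )
            idx[it] = rng.choice(n, size=k, replace=False)
        codes = _subset_codes(a, q, idx)
        diff = codes != full[idx]
        per_iter = diff.mean(axis=1)
        mismatch[j] = diff.mean()
        se[j] = per_iter.std(ddof=1) / math.sqrt(cfg.iterations) if cfg.iterations > 1 else np.nan
        any_mm[j] = diff.any(axis=1).mean()
    return StabilityCurve(
        sizes=sizes,
        iterations=cfg.iterations,
        mismatch_prob=mismatch,
        per_size_se=se,
        any_mismatch_prob=any_mm,
        seed=cfg.seed,
        tolerance=cfg.tolerance,
    )


def exact_mismatch(table: IntakeTable, k: int) -> float:
    """Exact expected per-subject mismatch probability at size k.

    Enumerates every C(N, k) subset uniformly; intended as a brute-force
    oracle at small N (bound: 10^6 subsets).
    """
    n = len(table)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if math.comb(n, k) > _ENUMERATION_BOUND:
        raise CombinatorialBoundError(
            f"C({n},{k}) = {math.comb(n, k)} subsets exceeds the enumeration "
            f"bound of {_ENUMERATION_BOUND}; use mismatch_curve (Monte Carlo)"
        )
    _, a, q, full = _full_codes(table)
    idx = np.array(list(combinations(range(n), k)), dtype=int)
    codes = _subset_codes(a, q, idx)
    return float((codes != full[idx]).mean())


def recommend_min_n(curve: StabilityCurve, tolerance: float | None = None) -> int | None:
    """Smallest k whose entire tail of the curve stays within tolerance.

    Returns None if even the full-sample end of the curve exceeds the
    tolerance (which cannot happen for k = N, where mismatch is 0 by
    construction, unless the curve was truncated).
    """
    tol = curve.tolerance if tolerance is None else tolerance
    sizes = np.asarray(curve.sizes)
    if sizes.size == 0:
        return None
    if np.any(np.diff(sizes) != 1):
        raise ValueError("stability curve must cover a contiguous range of k")
    ok = curve.mismatch_prob <= tol
    # suffix scan: first k after the last failing size
    failing = np.flatnonzero(~ok)
    if failing.size == 0:
        return int(sizes[0])
    if failing[-1] == sizes.size - 1:
        return None
    return int(sizes[failing[-1] + 1])
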