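"""Rank-correlation screen relating brain analyte levels to drinking behavior.

Concentrations of a panel of neurotransmitters, precursors, and
metabolites (normalized to total protein) are correlated, per brain
region, against the two normalized behavior metrics (alcohol-only and
alcohol+quinine percent-of-mean intake) with Spearman's rank
correlation.  Ties receive midranks.  P-values are exact permutation
p-values for small samples (n <= 10 complete pairs by default) and use
the t approximation otherwise.  Significance stars are unadjusted, as
is conventional for this kind of exploratory screen; an optional
Benjamini-Hochberg flag is available.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError

__all__ = ["correlate_analytes", "r_matrix", "DEFAULT_METRICS"]

DEFAULT_METRICS = ("alcohol_pct", "quinine_pct")

_SIG_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for level, mark in _SIG_LEVELS:
        if p < level:
            return mark
    return ""


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, chunk: int = 100_000) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Permutes one rank vector over all n! arrangements (midranks kept),
    counting |rho_null| >= |rho_obs|.  Feasible for n <= 10.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    # the rank variances are permutation-invariant, so comparing |rho| is
    # equivalent to comparing the absolute centered rank covariance
    obs = abs(np.dot(rx_c, ry - ry.mean()))
    count = 0
    total = 0
    buf: list[tuple[float, ...]] = []

    def flush(buf: list[tuple[float, ...]]) -> int:
        perm = np.asarray(buf)
        dots = np.abs((perm - perm.mean(axis=1, keepdims=True)) @ rx_c)
        return int((dots >= obs - 1e-12).sum())

    for p in permutations(ry):
        buf.append(p)
        if len(buf) == chunk:
            count += flush(buf)
            total += len(buf)
            buf = []
    if buf:
        count += flush(buf)
        total += len(buf)
    return count / total


def correlate_analytes(
    analytes: pd.DataFrame,
    behavior: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    min_n: int = 5,
    exact_max_n: int = 10,
    fdr: bool = False,
) -> pd.DataFrame:
    """Spearman screen of every (region, analyte) against each behavior metric.

    Parameters
    ----------
    analytes
        Long table with columns ``subject_id, region, analyte, concentration``.
    behavior
        Phenotype table with ``subject_id`` and the metric columns (e.g. the
        output of :func:`star.phenotype.phenotype_cohort`).
    metrics
        Behavior columns to correlate against.
    min_n
        Cells with fewer complete pairs are reported but not computed.
    exact_max_n
        Use the exact permutation p-value at or below this many pairs.
    fdr
        If True, add a Benjamini-Hochberg adjusted ``p_adj`` column (stars
        remain based on unadjusted p).

    Returns a long frame: ``region, analyte, metric, r, p, n, sig, computed``.
    """
    need = {"subject_id", "region", "analyte", "concentration"}
    if missing := need - set(analytes.columns):
        raise SchemaError(f"analyte table missing columns: {sorted(missing)}")
    if "subject_id" not in behavior.columns:
        raise SchemaError("behavior table needs a subject_id column")
    for m in metrics:
        if m not in behavior.columns:
            raise SchemaError(f"behavior table missing metric column {m!r}")

    rows = []
    beh = behavior.set_index("subject_id")
    for (region, analyte), grp in analytes.groupby(["region", "analyte"], sort=True):
        conc = grp.set_index("subject_id")["concentration"]
        for metric in metrics:
            joined = pd.concat([conc, beh[metric]], axis=1, join="inner").dropna()
            x = joined["concentration"].to_numpy(float)
            y = joined[metric].to_numpy(float)
            n = len(joined)
            if n < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((region, analyte, metric, np.nan, np.nan, n, "", False))
                continue
            r, p = stats.spearmanr(x, y)
            if n <= exact_max_n:
                p = _exact_spearman_p(x, y)
            rows.append((region, analyte, metric, float(r), float(p), n, _stars(p), True))

    out = pd.DataFrame(
        rows, columns=["region", "analyte", "metric", "r", "p", "n", "sig", "computed"]
    )
    if fdr:
        out["p_adj"] = np.nan
        mask = out["computed"].to_numpy()
        if mask.any():
            out.loc[mask, "p_adj"] = _bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def r_matrix(screen: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Wide analyte x region matrix of r values for one behavior metric.

    Suitable for bubble-plot style visualization of the screen.
    """
    sub = screen[screen["metric"] == metric]
    return sub.pivot(index="analyte", columns="region", values="r")
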