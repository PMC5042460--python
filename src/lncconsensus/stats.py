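"""Shared statistics: moderated differential expression, BH, Pearson, hypergeometric enrichment.

Differential expression is a two-sample t-test on log2(FPKM+1) with optional
empirical-Bayes variance moderation toward a fitted mean-variance trend
(a simplified limma-trend-style shrinkage: per-gene variances are shrunk via
an inverse-chi-square update with a prior df estimated by method of moments
on log-variance residuals).  Gene-set enrichment is the hypergeometric upper
tail with BH correction across sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from lncconsensus.data_model import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NaN inputs propagate as NaN and are excluded from the number of tests m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    q = p[mask]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(q)
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson_test(x, y):
    """Pearson r with the two-sided t-test p-value (t = r*sqrt(n-2)/sqrt(1-r^2)).

    Requires equal lengths n >= 4 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Hypergeometric tail and gene-set enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Upper tail P(X >= x) for X ~ Hypergeometric(N, K, n), in log space.

    N: universe size, K: size of one set, n: size of the other (the draw),
    x: observed overlap.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("x", x)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if K > N or n > N:
        raise ValueError("set sizes cannot exceed the universe")
    if x > min(K, n):
        raise ValueError("overlap cannot exceed the smaller set")
    lo = max(0, n + K - N)
    if x <= lo:
        return 1.0
    support = np.arange(x, min(K, n) + 1)
    logpmf = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, math.exp(special.logsumexp(logpmf))))


@dataclass
class EnrichmentResult:
    """Per-set hypergeometric enrichment table for one query gene list."""

    table: pd.DataFrame  # set, x, K, n, N, p_raw, p_adj
    universe_size: int

    def top(self):
        if self.table.empty:
            return None
        return self.table.iloc[0]


def read_gmt(path) -> dict:
    """Read a GMT file: tab-separated set name, description, member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def gene_set_enrichment(
    gene_list, universe, sets: dict, min_set_size: int = 5
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``gene_list`` in each gene set.

    Sets are intersected with the universe first; BH correction runs over
    sets with at least ``min_set_size`` members after intersection.  An empty
    gene list yields p = 1 everywhere.
    """
    universe = set(universe)
    query = set(gene_list)
    if not query <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        inset = set(members) & universe
        K = len(inset)
        if K < min_set_size:
            continue
        x = len(inset & query)
        rows.append(
            {"set": name, "x": x, "K": K, "n": n, "N": N,
             "p_raw": hypergeom_tail(N, K, n, x)}
        )
    table = pd.DataFrame(rows, columns=["set", "x", "K", "n", "N", "p_raw"])
    if len(table):
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        table = table.sort_values(["p_raw", "set"]).reset_index(drop=True)
    else:
        table["p_adj"] = []
    return EnrichmentResult(table=table, universe_size=N)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene two-group differential expression on log2(FPKM+1)."""

    table: pd.DataFrame  # gene_id index: log2fc, t, p_raw, p_adj
    nA: int
    nB: int
    moderation: str

    def write(self, path) -> None:
        out = self.table.rename(columns={"t": "t_stat"})
        out.rename_axis("gene_id").to_csv(path, sep="\t")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, limma-style)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = max(x - dif, 1e-8)
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _moderate_variances(s2: np.ndarray, means: np.ndarray, df: int):
    """Shrink per-gene variances toward a lowess mean-variance trend.

    Returns (moderated s2, prior df d0).  The trend is fitted on
    log-variances vs mean expression; d0 comes from matching the excess
    variance of log(s2/trend) over the theoretical chi-square scatter
    trigamma(df/2), mirroring the classic empirical-Bayes recipe.
    """
    positive = s2 > 0
    if positive.sum() < 10:
        # too few informative genes to fit a trend; fall back to pooled prior
        s0 = np.full_like(s2, max(s2[positive].mean(), 1e-12) if positive.any() else 1e-12)
    else:
        logs2 = np.log(s2[positive])
        fit = lowess(logs2, means[positive], frac=0.5, return_sorted=True)
        s0 = np.exp(np.interp(means, fit[:, 0], fit[:, 1]))
    z = np.log(np.maximum(s2, 1e-300) / s0)[positive]
    resid_var = float(np.var(z, ddof=1)) if len(z) > 1 else 0.0
    excess = resid_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
    if np.isinf(d0):
        s2_mod = s0.copy()
    else:
        s2_mod = (d0 * s0 + df * s2) / (d0 + df)
    return s2_mod, d0


def differential_expression(
    X: ExpressionMatrix,
    groupA,
    groupB,
    moderation: str = "trend",
) -> DEResult:
    """Two-group DE on log2(FPKM+1): log2FC = mean(A) - mean(B), moderated t.

    ``moderation="none"`` gives the plain pooled-variance t-test;
    ``"trend"`` shrinks variances toward a fitted mean-variance trend with
    moderated degrees of freedom.  A gene with zero variance in both groups
    gets p = 1 (logged).  BH adjustment runs over all tested genes.
    """
    if moderation not in {"trend", "none"}:
        raise ValueError("moderation must be 'trend' or 'none'")
    groupA, groupB = list(groupA), list(groupB)
    if set(groupA) & set(groupB):
        raise ValueError("groups must be disjoint")
    if len(groupA) < 2 or len(groupB) < 2:
        raise ValueError("each group needs >= 2 samples")
    Y = np.log2(X.values.to_numpy(dtype=float) + 1.0)
    ia = X.sample_ids.get_indexer(groupA)
    ib = X.sample_ids.get_indexer(groupB)
    if (ia < 0).any() or (ib < 0).any():
        raise KeyError("group sample(s) missing from matrix")
    A, B = Y[:, ia], Y[:, ib]
    nA, nB = len(groupA), len(groupB)
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    lfc = mA - mB
    df = nA + nB - 2
    s2 = (A.var(axis=1, ddof=1) * (nA - 1) + B.var(axis=1, ddof=1) * (nB - 1)) / df

    zero_var = s2 <= 0
    if zero_var.any():
        logger.info("%d genes with zero variance in both groups: p set to 1", zero_var.sum())

    if moderation == "trend":
        overall_mean = Y[:, np.concatenate([ia, ib])].mean(axis=1)
        s2_used, d0 = _moderate_variances(s2, overall_mean, df)
        df_total = df + d0 if np.isfinite(d0) else np.inf
    else:
        s2_used, df_total = s2, df

    se = np.sqrt(s2_used * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.minimum(p, 1.0)
    # no within-group information at all: declared uninformative
    p[zero_var] = 1.0
    t[zero_var] = 0.0

    table = pd.DataFrame(
        {"log2fc": lfc, "t": t, "p_raw": p, "p_adj": bh_adjust(p)},
        index=X.gene_ids,
    )
    return DEResult(table=table, nA=nA, nB=nB, moderation=moderation)
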