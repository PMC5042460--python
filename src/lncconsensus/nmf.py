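"""Consensus non-negative matrix factorization with cophenetic rank selection.

The factorization V ~ WH (W, H >= 0) is fitted by multiplicative updates
minimizing the generalized Kullback-Leibler divergence
``D(V||WH) = sum(V*log(V/WH) - V + WH)`` (Brunet-style updates, the default
of the classic consensus-clustering procedure for expression data).
Clustering stability is summarized by a consensus matrix over many random
initializations; the factorization rank k is chosen by maximizing the gap
between cophenetic correlation coefficients computed on the actual matrix
and on a row-permuted (structureless) copy.  Meta-genes are extracted per
basis with the Kim-Park basis-specificity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class NMFFactors:
    """Result of one NMF run: basis W (genes x k), coefficients H (k x samples)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective: float
    n_iter: int
    seed: int
    objective_history: np.ndarray = field(repr=False, default=None)


@dataclass
class ConsensusResult:
    """Consensus matrix over repeated NMF runs and the derived hard clustering."""

    k: int
    C: np.ndarray
    assignments: pd.Series  # sample -> cluster in 1..k
    mean_consensus_per_cluster: dict
    cophenetic: float
    runs: int
    empty_clusters: list = field(default_factory=list)
    best_factors: NMFFactors = field(repr=False, default=None)


@dataclass
class RankSelection:
    """Cophenetic-gap rank selection over a k range."""

    k_range: list
    cophenetic_actual: dict
    cophenetic_permuted: dict
    delta: dict
    k_star: int


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(V > 0, V * np.log(V / WH), 0.0)
    return float(np.sum(logterm - V + WH))


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> NMFFactors:
    """Factorize a non-negative matrix by multiplicative KL updates.

    W and H are initialized Uniform(0,1), scaled by ``mean(V)``; updates run
    until ``max_iter`` or until the relative objective change over a
    10-iteration window drops below ``tol``.  Zero entries in the
    reconstruction are floored at 1e-12 inside the update.  All-zero rows
    (undefined in KL) are the caller's responsibility to filter and raise.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D")
    if (V < 0).any():
        raise ValueError("V contains negative entries")
    if not (1 <= k < min(V.shape)):
        raise ValueError(f"rank k={k} must satisfy 1 <= k < min(V.shape)")
    zero_rows = np.where(~V.any(axis=1))[0]
    if len(zero_rows):
        raise ValueError(f"all-zero rows (filter before NMF): {zero_rows[:5].tolist()}")

    rng = np.random.default_rng(seed)
    scale = V.mean()
    W = rng.uniform(size=(V.shape[0], k)) * scale
    H = rng.uniform(size=(k, V.shape[1])) * scale
    W = np.maximum(W, _EPS)
    H = np.maximum(H, _EPS)

    history = []
    prev = None
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % 10 == 0 or it == max_iter:
            obj = _kl_divergence(V, W @ H)
            history.append(obj)
            if prev is not None and abs(prev - obj) <= tol * max(abs(prev), _EPS):
                n_iter = it
                break
            prev = obj
    objective = history[-1]
    return NMFFactors(
        W=W,
        H=H,
        k=k,
        objective=objective,
        n_iter=n_iter,
        seed=seed,
        objective_history=np.asarray(history),
    )


def _connectivity(H: np.ndarray) -> np.ndarray:
    labels = H.argmax(axis=0)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_cluster(
    V: np.ndarray,
    k: int,
    runs: int = 200,
    seed0: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
    sample_ids=None,
    seeds=None,
    resample_frac: float | None = None,
    fit_full: bool = True,
) -> ConsensusResult:
    """Average co-clustering indicators over ``runs`` perturbed NMF runs at rank k.

    Run r factorizes with seed ``seed0 + r`` (or ``seeds[r]`` when an
    explicit seed sequence is given); by default every run sees the full
    matrix and only the initialization varies.  ``resample_frac`` switches
    to Monti-style data perturbation, drawing that fraction of gene rows
    per run.
    Samples i,j co-cluster in a run when they share the argmax row of H.
    Hard assignments come from average-linkage hierarchical clustering of
    1 - C cut at k clusters.  The reported best-objective factorization is
    always fitted on the full matrix (best of up to 10 full-data runs;
    resampled-run objectives are not comparable across gene subsets).
    """
    if runs < 2:
        raise ValueError("need at least 2 runs for a consensus")
    if seeds is not None:
        seeds = list(seeds)
        if len(seeds) != runs:
            raise ValueError("seeds length must equal runs")
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    C = np.zeros((n, n))
    for r in range(runs):
        run_seed = seeds[r] if seeds is not None else seed0 + r
        if resample_frac is not None:
            rng = np.random.default_rng(run_seed)
            size = max(2, int(round(resample_frac * V.shape[0])))
            rows = np.sort(rng.choice(V.shape[0], size=size, replace=False))
            V_run = V[rows]
        else:
            V_run = V
        fac = nmf_factorize(V_run, k, seed=run_seed, max_iter=max_iter, tol=tol)
        C += _connectivity(fac.H)
    best = None
    if fit_full:
        for r in range(min(runs, 10)):
            run_seed = seeds[r] if seeds is not None else seed0 + r
            fac = nmf_factorize(V, k, seed=run_seed, max_iter=max_iter, tol=tol)
            if best is None or fac.objective < best.objective:
                best = fac
    C /= runs
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)

    dist = 1.0 - C
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 1..k in first-encountered sample order
    remap, next_label = {}, 1
    relabeled = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = next_label
            next_label += 1
        relabeled[i] = remap[lab]
    labels = relabeled

    empty = [c for c in range(1, k + 1) if not (labels == c).any()]
    if empty:
        logger.warning("empty clusters after cut at k=%d: %s", k, empty)

    mean_cons = {}
    for c in range(1, k + 1):
        members = np.where(labels == c)[0]
        if len(members) == 0:
            mean_cons[c] = float("nan")
        elif len(members) == 1:
            mean_cons[c] = 1.0
        else:
            block = C[np.ix_(members, members)]
            off = block[np.triu_indices(len(members), 1)]
            mean_cons[c] = float(off.mean())

    if sample_ids is None:
        sample_ids = pd.RangeIndex(n)
    assignments = pd.Series(labels, index=sample_ids, name="cluster")
    return ConsensusResult(
        k=k,
        C=C,
        assignments=assignments,
        mean_consensus_per_cluster=mean_cons,
        cophenetic=cophenetic_coefficient(C),
        runs=runs,
        empty_clusters=empty,
        best_factors=best,
    )


def cophenetic_coefficient(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Pearson correlation between the off-diagonal entries of the distance
    matrix 1 - C and the cophenetic (ultrametric) distances implied by its
    average-linkage dendrogram.  A constant distance matrix is perfectly
    stable and defined as 1.0.
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("consensus matrix must be square symmetric")
    dist = 1.0 - C
    np.fill_diagonal(dist, 0.0)
    cond = squareform(dist, checks=False)
    if np.ptp(cond) < 1e-15:
        logger.info("constant consensus distances; cophenetic defined as 1.0")
        return 1.0
    Z = sch.linkage(cond, method="average")
    coph = sch.cophenet(Z)
    if np.ptp(coph) < 1e-15:
        return 1.0
    r, _ = pearsonr(cond, coph)
    return float(r)


def permute_rows(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each gene row across samples (null matrix)."""
    V = np.asarray(V, dtype=float)
    out = np.empty_like(V)
    for i in range(V.shape[0]):
        out[i] = V[i, rng.permutation(V.shape[1])]
    return out


def select_rank(
    V: np.ndarray,
    k_range=range(2, 7),
    runs_per_k: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
    resample_frac: float | None = None,
) -> RankSelection:
    """Choose the rank maximizing the actual-minus-permuted cophenetic gap.

    One row permutation is drawn per call and reused for every k; the
    permuted matrix gets the same number of runs as the actual one.  Ties
    resolve to the smallest k.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    V = np.asarray(V, dtype=float)
    if max(k_range) >= min(V.shape):
        raise ValueError("k_range exceeds matrix rank bound")
    rng = np.random.default_rng(seed)
    V_perm = permute_rows(V, rng)
    actual, permuted, delta = {}, {}, {}
    for k in k_range:
        res_a = consensus_cluster(
            V, k, runs=runs_per_k, seed0=seed + 1000 * k, max_iter=max_iter,
            tol=tol, resample_frac=resample_frac, fit_full=False,
        )
        res_p = consensus_cluster(
            V_perm, k, runs=runs_per_k, seed0=seed + 1000 * k + 500,
            max_iter=max_iter, tol=tol, resample_frac=resample_frac, fit_full=False,
        )
        actual[k] = res_a.cophenetic
        permuted[k] = res_p.cophenetic
        delta[k] = actual[k] - permuted[k]
        logger.info(
            "rank selection k=%d: cophenetic actual=%.4f permuted=%.4f delta=%.4f",
            k, actual[k], permuted[k], delta[k],
        )
    best = max(delta.values())
    k_star = min(k for k in k_range if delta[k] == best)
    return RankSelection(
        k_range=k_range,
        cophenetic_actual=actual,
        cophenetic_permuted=permuted,
        delta=delta,
        k_star=k_star,
    )


def kim_park_scores(W: np.ndarray) -> np.ndarray:
    """Kim-Park basis-specificity score per gene.

    ``score(g) = 1 + (1/log2 k) * sum_q p(g,q) log2 p(g,q)`` with
    ``p(g,q) = W[g,q]/sum_q' W[g,q']``; 1 for a point mass (gene loads one
    basis), 0 for a uniform row.  All-zero rows score NaN (excluded).
    """
    W = np.asarray(W, dtype=float)
    k = W.shape[1]
    rowsum = W.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(rowsum > 0, W / np.where(rowsum > 0, rowsum, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    scores = 1.0 + plogp.sum(axis=1) / np.log2(k)
    scores[rowsum.ravel() == 0] = np.nan
    return scores


def extract_metagenes(
    W: np.ndarray, gene_ids=None, sd_multiplier: float = 3.0
) -> dict:
    """Assign basis-specific meta-genes from the best factorization's W.

    Genes whose Kim-Park score exceeds mean + ``sd_multiplier`` * SD of all
    scores are meta-genes of the basis (cluster, 1-based) on which they load
    maximally.  Returns ``{cluster: [(gene_id, score), ...]}`` sorted by
    descending score.
    """
    W = np.asarray(W, dtype=float)
    if gene_ids is None:
        gene_ids = list(range(W.shape[0]))
    gene_ids = list(gene_ids)
    scores = kim_park_scores(W)
    valid = ~np.isnan(scores)
    mu = scores[valid].mean()
    sd = scores[valid].std(ddof=1) if valid.sum() > 1 else 0.0
    thresh = mu + sd_multiplier * sd
    basis = W.argmax(axis=1)
    out = {q: [] for q in range(1, W.shape[1] + 1)}
    for i in np.where(valid & (scores > thresh))[0]:
        out[int(basis[i]) + 1].append((gene_ids[i], float(scores[i])))
    for q in out:
        out[q].sort(key=lambda t: (-t[1], str(t[0])))
    return out
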