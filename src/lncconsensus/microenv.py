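"""Tumour-microenvironment profiling: guilt-by-association, purity scores, SIC filter.

Bulk tumour samples mix malignant cells with stromal and immune infiltrate.
Per-sample stromal and immune signature scores are computed with a
single-sample rank-based enrichment statistic (ssGSEA-style); tumour purity
is a monotone-decreasing transform of their sum (the cosine form of the
ESTIMATE publication, with configurable constants).  lncRNAs expressed in
clinical bulk samples but low/absent in pure-tumour cell-line and PDX
panels are flagged stromal/immune-cell specific (SIC), and putative immune
lncRNAs are attributed to cell types via median correlation with marker
panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from lncconsensus.data_model import ExpressionMatrix
from lncconsensus.stats import EnrichmentResult, gene_set_enrichment, pearson_test

logger = logging.getLogger(__name__)

# Cosine purity transform constants from the ESTIMATE publication
# (Yoshihara et al. 2013); note the score scale here is this package's own,
# so only the monotone ordering of purity is meaningful, not its absolute
# calibration against that paper's.
DEFAULT_PURITY_TRANSFORM = {"a": 0.6049872018, "b": 0.0001467884}


# ---------------------------------------------------------------------------
# Guilt-by-association
# ---------------------------------------------------------------------------

def gba_profile(
    lnc_list,
    X: ExpressionMatrix,
    pc_genes,
    sets: dict,
    r_thresh: float = 0.60,
    universe=None,
) -> dict:
    """Functional profile of each lncRNA from its strongly co-expressed PC genes.

    For each lncRNA, PC genes with Pearson r > ``r_thresh`` (across all
    samples) form the query list for hypergeometric gene-set enrichment
    against ``universe`` (default: the PC genes themselves).  Returns
    ``{lnc: EnrichmentResult or None}`` (None when the query list is empty).
    """
    pc_genes = [g for g in pc_genes if g in X.gene_ids]
    if universe is None:
        universe = pc_genes
    pc_arr = X.values.loc[pc_genes].to_numpy()
    out = {}
    for lnc in lnc_list:
        x = X.values.loc[lnc].to_numpy()
        if np.ptp(x) == 0:
            logger.warning("lncRNA %s constant; guilt-by-association skipped", lnc)
            out[lnc] = None
            continue
        with np.errstate(invalid="ignore"):
            sd = pc_arr.std(axis=1)
            centred = pc_arr - pc_arr.mean(axis=1, keepdims=True)
            xc = x - x.mean()
            r = centred @ xc / (
                np.where(sd > 0, sd, np.inf) * len(x) * x.std()
            )
        query = [g for g, ri in zip(pc_genes, r) if ri > r_thresh]
        if not query:
            logger.info("lncRNA %s: no PC gene exceeds r > %.2f", lnc, r_thresh)
            out[lnc] = None
            continue
        out[lnc] = gene_set_enrichment(
            [g for g in query if g in set(universe)], universe, sets
        )
    return out


# ---------------------------------------------------------------------------
# Signature scores and purity
# ---------------------------------------------------------------------------

def signature_score(
    X: ExpressionMatrix, gene_set, alpha: float = 0.25, min_genes: int = 10
) -> pd.Series:
    """Single-sample rank-based enrichment score for one gene set.

    Per sample, genes are ordered by descending expression and assigned rank
    weights ``rank^alpha`` (largest for the most expressed gene).  The score
    is the sum over the ordering of the difference between the weighted
    in-set cumulative distribution and the unweighted out-of-set ECDF.
    Being purely rank-based, the score is invariant under any strictly
    monotone transform of a sample's expression values for every alpha.
    """
    genes = [g for g in gene_set if g in X.gene_ids]
    if len(genes) < min_genes:
        raise ValueError(
            f"gene set has {len(genes)} genes in the matrix (< {min_genes})"
        )
    arr = X.values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    inset = np.asarray(X.gene_ids.isin(genes))
    scores = np.empty(n_samples)
    ranks = np.arange(n_genes, 0, -1, dtype=float)  # best rank first
    weights = ranks ** alpha
    for j in range(n_samples):
        order = np.argsort(-arr[:, j], kind="stable")
        m = inset[order]
        w_in = np.where(m, weights, 0.0)
        P_in = np.cumsum(w_in) / w_in.sum()
        P_out = np.cumsum(~m) / float(n_genes - m.sum())
        scores[j] = float(np.sum(P_in - P_out))
    return pd.Series(scores, index=X.sample_ids, name="score")


def purity_estimate(
    stromal: pd.Series, immune: pd.Series, transform_cfg: dict | None = None
) -> pd.Series:
    """Tumour purity from stromal+immune scores: ``cos(a + b*(stromal+immune))``.

    Monotone non-increasing in the combined score while the cosine argument
    stays within [0, pi]; clipped to [0, 1].
    """
    cfg = dict(DEFAULT_PURITY_TRANSFORM)
    if transform_cfg:
        cfg.update(transform_cfg)
    combined = stromal + immune
    purity = np.cos(cfg["a"] + cfg["b"] * combined)
    return pd.Series(np.clip(purity, 0.0, 1.0), index=combined.index, name="purity")


# ---------------------------------------------------------------------------
# Stromal/immune-cell-specific (SIC) filter
# ---------------------------------------------------------------------------

@dataclass
class SICResult:
    """Per-lncRNA medians and fold changes of clinical vs pure-tumour panels."""

    table: pd.DataFrame  # gene_id index: median_clinical median_cellline
    #                      median_pdx lfc_cl lfc_pdx is_sic
    n_clinical_pure: int
    thresholds: dict

    @property
    def sic_genes(self) -> list:
        return self.table.index[self.table["is_sic"]].tolist()

    def write(self, path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")


def sic_filter(
    X_clinical: ExpressionMatrix,
    purity: pd.Series,
    X_cellline: ExpressionMatrix,
    X_pdx: ExpressionMatrix,
    purity_thresh: float = 0.70,
    lfc_thresh: float = 0.50,
    expr_cap: float = 0.50,
    eps: float = 0.10,
) -> SICResult:
    """Flag lncRNAs expressed in bulk clinical samples but not pure-tumour panels.

    Restricted to genes common to all three matrices.  Per gene the median
    FPKM over high-purity clinical samples (purity > ``purity_thresh``) is
    compared to the cell-line and PDX medians:
    ``lfc = log2((median_clinical + eps) / (median_panel + eps))``.  A gene
    is SIC when both fold changes exceed ``lfc_thresh`` and both panel
    medians are below ``expr_cap``.
    """
    pure_samples = purity.index[purity > purity_thresh]
    pure_samples = [s for s in pure_samples if s in X_clinical.sample_ids]
    if not pure_samples:
        raise ValueError(f"no clinical samples with purity > {purity_thresh}")
    common = (
        X_clinical.gene_ids.intersection(X_cellline.gene_ids)
        .intersection(X_pdx.gene_ids)
    )
    med_clin = X_clinical.values.loc[common, pure_samples].median(axis=1)
    med_cl = X_cellline.values.loc[common].median(axis=1)
    med_pdx = X_pdx.values.loc[common].median(axis=1)
    lfc_cl = np.log2((med_clin + eps) / (med_cl + eps))
    lfc_pdx = np.log2((med_clin + eps) / (med_pdx + eps))
    is_sic = (
        (lfc_cl > lfc_thresh)
        & (lfc_pdx > lfc_thresh)
        & (med_cl < expr_cap)
        & (med_pdx < expr_cap)
    )
    table = pd.DataFrame(
        {
            "median_clinical": med_clin,
            "median_cellline": med_cl,
            "median_pdx": med_pdx,
            "lfc_cl": lfc_cl,
            "lfc_pdx": lfc_pdx,
            "is_sic": is_sic,
        }
    )
    return SICResult(
        table=table,
        n_clinical_pure=len(pure_samples),
        thresholds={
            "purity_thresh": purity_thresh,
            "lfc_thresh": lfc_thresh,
            "expr_cap": expr_cap,
            "eps": eps,
        },
    )


# ---------------------------------------------------------------------------
# Immune cell-type association
# ---------------------------------------------------------------------------

def celltype_association(
    lnc: str,
    X: ExpressionMatrix,
    marker_table: pd.DataFrame,
    min_markers: int = 4,
    r_line: float = 0.48,
) -> pd.DataFrame:
    """Median marker correlation of a lncRNA per immune cell type.

    ``marker_table`` has columns ``cell_type, gene_symbol``; markers are
    intersected with the matrix, and only cell types retaining at least
    ``min_markers`` markers are eligible.  Returns a frame with per-type
    marker count, median r, the per-marker r values, and whether
    median r > ``r_line``.
    """
    x = X.values.loc[lnc].to_numpy()
    rows = []
    for cell_type, grp in marker_table.groupby("cell_type"):
        markers = sorted(set(grp["gene_symbol"]) & set(X.gene_ids))
        if len(markers) < min_markers:
            logger.info("cell type %s has %d matched markers (<%d); ineligible",
                        cell_type, len(markers), min_markers)
            continue
        rs = {}
        for m in markers:
            rs[m], _ = pearson_test(x, X.values.loc[m].to_numpy())
        median_r = float(np.median(list(rs.values())))
        rows.append(
            {
                "cell_type": cell_type,
                "n_markers": len(markers),
                "median_r": median_r,
                "above_line": median_r > r_line,
                "marker_r": rs,
            }
        )
    out = pd.DataFrame(
        rows, columns=["cell_type", "n_markers", "median_r", "above_line", "marker_r"]
    )
    if len(out):
        out = out.sort_values("median_r", ascending=False).reset_index(drop=True)
    return out


def cluster_purity_contrast(purity: pd.Series, assignments: pd.Series, focal):
    """Two-sample t-test of purity: focal cluster vs all other clusters.

    Returns ``(per_cluster, t, p)`` where per_cluster maps cluster ->
    (mean, SD, n).  Size-1 clusters are excluded from the summary with a
    warning (their samples still count in the t-test pools).  Degenerate
    (zero-variance) comparisons give p = 1.
    """
    common = purity.index.intersection(assignments.index)
    purity = purity.loc[common]
    assignments = assignments.loc[common]
    per_cluster = {}
    for c, grp in purity.groupby(assignments):
        if len(grp) < 2:
            logger.warning("cluster %s has a single sample; summary excluded", c)
            continue
        per_cluster[c] = (float(grp.mean()), float(grp.std(ddof=1)), len(grp))
    focal_vals = purity[assignments == focal].to_numpy()
    rest_vals = purity[assignments != focal].to_numpy()
    if len(focal_vals) < 2 or len(rest_vals) < 2:
        raise ValueError("focal and rest groups each need >= 2 samples")
    if np.ptp(np.concatenate([focal_vals, rest_vals])) == 0:
        return per_cluster, 0.0, 1.0
    t, p = sps.ttest_ind(focal_vals, rest_vals)
    return per_cluster, float(t), float(p)
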