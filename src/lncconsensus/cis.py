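"""Cis-neighbour assignment and correlation for lncRNAs.

Protein-coding genes get "basal plus extension" regulatory domains: a
strand-aware basal window around the TSS (default 5 kb upstream / 1 kb
downstream), extended on each side by up to 1 Mb but truncated at the
nearest other gene's basal domain.  A PC gene is a neighbour of a lncRNA
when its extended domain intersects the lncRNA locus (or its TSS, in
``tss`` mode).  Support for cis-regulation is summarized by the Pearson
correlation of the pair across samples, by a pan-cancer rank score
``1 - n/N`` (n = the PC gene's 1-based position among N PC genes ranked by
descending correlation with the lncRNA), and by subtype-stratified
correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from lncconsensus.data_model import ExpressionMatrix, expression_variability_mask
from lncconsensus.stats import pearson_test

logger = logging.getLogger(__name__)


def build_regulatory_domains(
    pc_ann: pd.DataFrame,
    upstream: int = 5000,
    downstream: int = 1000,
    max_ext: int = 1_000_000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains for PC genes.

    TSS = start on the + strand, end on the - strand.  The basal domain is
    [TSS - upstream, TSS + downstream) oriented by strand.  Each flank of
    the basal domain then grows by up to ``max_ext`` bp, truncated at the
    nearest other gene's basal domain on that side, and clipped at 0.

    Returns a frame indexed by gene_id with columns chrom, strand,
    basal_start, basal_end, ext_start, ext_end.
    """
    rows = []
    for row in pc_ann.itertuples():
        if row.strand == "+":
            tss = row.start
            b0, b1 = tss - upstream, tss + downstream
        else:
            tss = row.end
            b0, b1 = tss - downstream, tss + upstream
        rows.append((row.gene_id, row.chrom, row.strand, max(0, b0), max(1, b1)))
    dom = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "basal_start", "basal_end"]
    ).set_index("gene_id", drop=False)
    dom.index.name = None

    ext_start = np.empty(len(dom), dtype=int)
    ext_end = np.empty(len(dom), dtype=int)
    pos = {g: i for i, g in enumerate(dom.index)}
    for chrom, grp in dom.groupby("chrom"):
        grp = grp.sort_values(["basal_start", "basal_end", "gene_id"])
        starts = grp["basal_start"].to_numpy()
        ends = grp["basal_end"].to_numpy()
        for j, g in enumerate(grp.index):
            left_limit = starts[j] - max_ext
            right_limit = ends[j] + max_ext
            left_neigh = ends[:j]
            if len(left_neigh):
                left_limit = max(left_limit, int(left_neigh.max()))
            right_neigh = starts[j + 1:]
            if len(right_neigh):
                right_limit = min(right_limit, int(right_neigh.min()))
            # basal domain is always contained in the extended domain
            i = pos[g]
            ext_start[i] = max(0, min(left_limit, starts[j]))
            ext_end[i] = max(right_limit, ends[j])
    dom["ext_start"] = ext_start
    dom["ext_end"] = ext_end
    return dom


def domains_to_bed(dom: pd.DataFrame, path) -> None:
    out = dom[["chrom", "ext_start", "ext_end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = dom["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def assign_neighbours(
    lnc_ann: pd.DataFrame, domains: pd.DataFrame, mode: str = "locus"
) -> dict:
    """Map each lncRNA to the PC genes whose extended domain it intersects.

    ``mode="locus"`` intersects the full lncRNA gene interval (half-open);
    ``mode="tss"`` uses only the strand-aware TSS point.
    """
    if mode not in {"locus", "tss"}:
        raise ValueError("mode must be 'locus' or 'tss'")
    by_chrom = {c: g for c, g in domains.groupby("chrom")}
    nmap = {}
    for row in lnc_ann.itertuples():
        if mode == "tss":
            tss = row.start if row.strand == "+" else row.end - 1
            q0, q1 = tss, tss + 1
        else:
            q0, q1 = row.start, row.end
        dom = by_chrom.get(row.chrom)
        if dom is None:
            nmap[row.gene_id] = []
            continue
        hit = (q0 < dom["ext_end"].to_numpy()) & (dom["ext_start"].to_numpy() < q1)
        nmap[row.gene_id] = sorted(dom.index[hit].tolist())
    return nmap


def top_neighbour_correlation(X: ExpressionMatrix, neighbour_map: dict, lnc: str):
    """The neighbour with the highest Pearson r to the lncRNA across all samples.

    Ties break to the lexicographically smallest gene id.  Returns
    ``(pc_id, r, p)`` or None when the lncRNA has no neighbours.
    """
    neighbours = neighbour_map.get(lnc, [])
    neighbours = [g for g in neighbours if g in X.gene_ids]
    if not neighbours:
        logger.info("lncRNA %s has no neighbours in the matrix", lnc)
        return None
    x = X.values.loc[lnc].to_numpy()
    best = None
    for pc in sorted(neighbours):
        r, p = pearson_test(x, X.values.loc[pc].to_numpy())
        if best is None or r > best[1]:
            best = (pc, r, p)
    return best


def rank_score(
    lnc: str,
    pc: str,
    X_per_cancer: dict,
    mean_sd_thresh: float = 1.00,
    cv_thresh: float = 0.10,
) -> pd.DataFrame:
    """Pan-cancer rank score of a lncRNA-PC pair: ``1 - n/N`` per cancer type.

    For each cancer type's matrix, all PC genes (every gene except the
    lncRNA itself) are ranked by descending Pearson r with the lncRNA; n is
    the query PC gene's 1-based position and N the number of genes ranked.
    Cancer types where the lncRNA fails the expression ((mean+SD) > 1.00) or
    variability (CV > 0.10) thresholds are omitted.
    """
    rows = []
    for cancer, X in X_per_cancer.items():
        if lnc not in X.gene_ids or pc not in X.gene_ids:
            continue
        expressed, variable = expression_variability_mask(
            X.values.loc[[lnc]], mean_sd_thresh, cv_thresh
        )
        if not (expressed[0] and variable[0]):
            logger.info("lncRNA %s fails thresholds in %s; omitted", lnc, cancer)
            continue
        x = X.values.loc[lnc].to_numpy()
        pc_genes = [g for g in X.gene_ids if g != lnc]
        rs = {}
        for g in pc_genes:
            y = X.values.loc[g].to_numpy()
            if np.ptp(y) == 0:
                rs[g] = -np.inf
                continue
            rs[g], _ = pearson_test(x, y)
        ranked = sorted(pc_genes, key=lambda g: (-rs[g], g))
        n = ranked.index(pc) + 1
        N = len(ranked)
        rows.append(
            {"lnc_id": lnc, "pc_id": pc, "cancer_type": cancer,
             "r": rs[pc], "n": n, "N": N, "rank_score": 1.0 - n / N}
        )
    return pd.DataFrame(
        rows, columns=["lnc_id", "pc_id", "cancer_type", "r", "n", "N", "rank_score"]
    )


def stratified_correlation(
    X: ExpressionMatrix, lnc: str, pc: str, strata, min_stratum: int = 4
) -> dict:
    """Pooled and per-stratum Pearson correlation for a lncRNA-PC pair.

    ``strata`` maps stratum name -> sample ids.  Strata smaller than
    ``min_stratum`` are omitted with a warning.  Returns
    ``{"all": (r, p, n), stratum: (r, p, n), ...}``.
    """
    x = X.values.loc[lnc]
    y = X.values.loc[pc]
    out = {}
    r, p = pearson_test(x.to_numpy(), y.to_numpy())
    out["all"] = (r, p, len(x))
    for name, samples in strata.items():
        samples = [s for s in samples if s in X.sample_ids]
        if len(samples) < min_stratum:
            logger.warning("stratum %s has %d samples (<%d); omitted",
                           name, len(samples), min_stratum)
            continue
        r, p = pearson_test(x[samples].to_numpy(), y[samples].to_numpy())
        out[name] = (r, p, len(samples))
    return out
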