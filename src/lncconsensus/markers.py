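"""Cross-cohort meta-gene consensus and marker derivation.

Meta-gene sets driving the clustering of two independent cohorts are
compared pairwise with the hypergeometric test; a matched cluster pair's
overlap genes become consensus markers when they are significantly
over-expressed (log2FC and BH-adjusted p thresholds) in the focal subtype
versus the rest in BOTH cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from lncconsensus.stats import DEResult, hypergeom_tail

logger = logging.getLogger(__name__)


@dataclass
class OverlapTest:
    """Hypergeometric overlap between one cohort-A and one cohort-B meta-gene set."""

    cluster_a: object
    cluster_b: object
    set_a: list
    set_b: list
    universe_size: int
    overlap: list
    x: int
    p: float
    significant: bool = False  # p < 0.001 flag, mirroring the reporting convention


@dataclass
class MarkerSet:
    """Consensus markers passing DE thresholds in both cohorts, with evidence."""

    genes: list
    evidence: pd.DataFrame  # gene_id index: log2fc_A p_A p_adj_A log2fc_B p_B p_adj_B
    lfc_thresh: float = 1.00
    q_thresh: float = 0.05
    dropped: list = field(default_factory=list)

    def write(self, path) -> None:
        self.evidence.rename_axis("gene_id").to_csv(path, sep="\t")


def _resolve_universe(filtered_a, filtered_b, universe_mode):
    if isinstance(universe_mode, str) and universe_mode.startswith("fixed:"):
        return int(universe_mode.split(":", 1)[1])
    filtered_a, filtered_b = set(filtered_a), set(filtered_b)
    if universe_mode == "intersection":
        return filtered_a & filtered_b
    if universe_mode == "union":
        return filtered_a | filtered_b
    if universe_mode == "cohortA":
        return filtered_a
    if universe_mode == "cohortB":
        return filtered_b
    if isinstance(universe_mode, str) and universe_mode.startswith("fixed:"):
        return int(universe_mode.split(":", 1)[1])
    raise ValueError(f"unknown universe mode: {universe_mode!r}")


def metagene_overlap(
    metagenes_a: dict,
    metagenes_b: dict,
    filtered_a,
    filtered_b,
    universe_mode: str = "intersection",
    alpha_star: float = 0.001,
) -> list:
    """Test all cohort-A x cohort-B cluster pairs for meta-gene overlap.

    The universe defaults to the intersection of the two cohorts' filtered
    gene sets; each meta-gene set is restricted to the universe before
    testing.  ``universe_mode`` also accepts ``union``, ``cohortA``,
    ``cohortB`` or ``fixed:N`` (sets restricted only when a real universe set
    is available).  p = P(X >= x) for X ~ Hypergeom(N, |setA|, |setB|).
    """
    universe = _resolve_universe(filtered_a, filtered_b, universe_mode)
    if isinstance(universe, set):
        if not universe:
            raise ValueError("empty universe; check the filtered gene sets")
        N = len(universe)
    else:
        N = universe
        universe = None
    results = []
    for ca, genes_a in metagenes_a.items():
        for cb, genes_b in metagenes_b.items():
            sa = set(genes_a) & universe if universe is not None else set(genes_a)
            sb = set(genes_b) & universe if universe is not None else set(genes_b)
            overlap = sorted(sa & sb)
            x = len(overlap)
            p = hypergeom_tail(N, len(sa), len(sb), x)
            results.append(
                OverlapTest(
                    cluster_a=ca,
                    cluster_b=cb,
                    set_a=sorted(sa),
                    set_b=sorted(sb),
                    universe_size=N,
                    overlap=overlap,
                    x=x,
                    p=p,
                    significant=p < alpha_star,
                )
            )
    return results


def derive_markers(
    overlap: OverlapTest,
    de_a: DEResult,
    de_b: DEResult,
    lfc_thresh: float = 1.00,
    q_thresh: float = 0.05,
) -> MarkerSet:
    """Consensus markers: overlap genes over-expressed in the focal subtype in both cohorts.

    Each DE result should contrast the focal cluster's subtype (group A)
    against all other samples (group B) in its cohort.  A marker requires
    log2FC > ``lfc_thresh`` AND adjusted p < ``q_thresh`` in both cohorts.
    Overlap genes missing from either DE table are excluded with a warning.
    """
    rows, genes, dropped = [], [], []
    for g in overlap.overlap:
        if g not in de_a.table.index or g not in de_b.table.index:
            logger.warning("overlap gene %s missing from a DE result; excluded", g)
            dropped.append(g)
            continue
        ra, rb = de_a.table.loc[g], de_b.table.loc[g]
        passes = (
            ra["log2fc"] > lfc_thresh
            and ra["p_adj"] < q_thresh
            and rb["log2fc"] > lfc_thresh
            and rb["p_adj"] < q_thresh
        )
        rows.append(
            {
                "gene_id": g,
                "log2fc_A": ra["log2fc"],
                "p_A": ra["p_raw"],
                "p_adj_A": ra["p_adj"],
                "log2fc_B": rb["log2fc"],
                "p_B": rb["p_raw"],
                "p_adj_B": rb["p_adj"],
                "is_marker": passes,
            }
        )
        if passes:
            genes.append(g)
    evidence = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "log2fc_A", "p_A", "p_adj_A",
            "log2fc_B", "p_B", "p_adj_B", "is_marker",
        ],
    ).set_index("gene_id")
    return MarkerSet(
        genes=genes,
        evidence=evidence,
        lfc_thresh=lfc_thresh,
        q_thresh=q_thresh,
        dropped=dropped,
    )
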