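"""Expression-matrix and annotation I/O, biotype partitioning, filters, batch adjustment.

The pipeline operates on gene-by-sample FPKM matrices.  Genes are either
lincRNAs or protein-coding; lincRNAs that overlap a protein-coding gene, or
whose longest transcript is under 400 bp (fragment-length artefacts), are
excluded up front.  Expression/variability filtering keeps genes with
(mean FPKM + SD) > 1.00 and coefficient of variation > 0.10.  Batch
adjustment is a per-gene location-scale recentring on log2(FPKM+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ["cohort", "subtype", "hormone_status", "batch"]
SUBTYPES = {"basal", "lumA", "lumB", "her2", "normal", "NA"}

ANNOTATION_COLUMNS = [
    "gene_id",
    "symbol",
    "chrom",
    "start",
    "end",
    "strand",
    "biotype",
    "max_transcript_len",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample FPKM matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative FPKM values, index = gene ids,
        columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with columns
        ``cohort, subtype, hormone_status, batch``.  Every sample in
        ``values`` must have a record.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = v.columns[
                [not np.issubdtype(d, np.number) for d in v.dtypes]
            ].tolist()
            raise ValueError(f"non-numeric columns: {bad[:5]}")
        finite = np.isfinite(arr)
        if not finite.all():
            i, j = np.argwhere(~finite)[0]
            raise ValueError(
                f"non-finite value at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative FPKM at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        missing = v.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {missing.tolist()[:5]}")

    # -- conveniences ----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sample_meta)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.sample_meta.loc[ids])


@dataclass
class FilterReport:
    """Book-keeping for gene filtering; counts reconcile with the input size.

    Each dropped gene is attributed to the first rule that removed it, in
    the order short transcript -> PC overlap -> expression -> CV.
    """

    n_input: int = 0
    n_kept: int = 0
    n_dropped_short: int = 0
    n_dropped_overlap: int = 0
    n_dropped_expression: int = 0
    n_dropped_cv: int = 0
    kept_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.n_kept
            + self.n_dropped_short
            + self.n_dropped_overlap
            + self.n_dropped_expression
            + self.n_dropped_cv
        )
        if total != self.n_input:
            raise ValueError(
                f"filter report does not reconcile: input {self.n_input}, "
                f"accounted {total}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path, meta_path=None) -> ExpressionMatrix:
    """Read a gene-by-sample FPKM TSV (first column ``gene_id``).

    ``meta_path`` points at a companion metadata TSV with columns
    ``sample_id, cohort, subtype, hormone_status, batch``; if omitted,
    placeholder metadata (single cohort/batch, subtype NA) is attached.
    Duplicate ids and negative or non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value in column {col!r} at gene {bad[0]!r}"
                )
            df[col] = coerced
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
        meta = meta[META_COLUMNS]
    else:
        meta = pd.DataFrame(
            {
                "cohort": "cohort1",
                "subtype": "NA",
                "hormone_status": "NA",
                "batch": "batch1",
            },
            index=df.columns,
        )
        meta.index.name = "sample_id"
    return ExpressionMatrix(df.astype(float), meta)


def write_expression_matrix(X: ExpressionMatrix, path, meta_path=None) -> None:
    X.values.to_csv(path, sep="\t")
    if meta_path is not None:
        X.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def _validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate annotation records: {dups[:5]}")
    if not (ann["start"] < ann["end"]).all():
        bad = ann.loc[ann["start"] >= ann["end"], "gene_id"].tolist()
        raise ValueError(f"start >= end for genes: {bad[:5]}")
    if not ann["strand"].isin(["+", "-"]).all():
        bad = ann.loc[~ann["strand"].isin(["+", "-"]), "gene_id"].tolist()
        raise ValueError(f"invalid strand for genes: {bad[:5]}")
    out = ann.set_index("gene_id", drop=False)
    out.index.name = None
    return out


def read_annotation_bed(path) -> pd.DataFrame:
    """Read a BED6+2 annotation: chrom start end gene_id score strand biotype max_transcript_len.

    BED coordinates are 0-based half-open, which is the internal convention,
    so they are taken as-is.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "chrom",
            "start",
            "end",
            "gene_id",
            "score",
            "strand",
            "biotype",
            "max_transcript_len",
        ],
        comment="#",
    )
    df["symbol"] = df["gene_id"]
    return _validate_annotation(df[ANNOTATION_COLUMNS].copy())


def read_annotation_gtf(path) -> pd.DataFrame:
    """Read gene lines from a minimal GTF (needs gene_id and gene_type/gene_biotype).

    GTF is 1-based closed; converted to 0-based half-open on read.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = {}
            for item in parts[8].strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            rows.append(
                {
                    "gene_id": attrs["gene_id"],
                    "symbol": attrs.get("gene_name", attrs["gene_id"]),
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "biotype": attrs.get("gene_type", attrs.get("gene_biotype", "other")),
                    "max_transcript_len": int(attrs.get("max_transcript_len", 0)),
                }
            )
    return _validate_annotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


def write_annotation_bed(ann: pd.DataFrame, path) -> None:
    out = ann[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = ann["strand"]
    out["biotype"] = ann["biotype"]
    out["max_transcript_len"] = ann["max_transcript_len"]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Partitioning and filters
# ---------------------------------------------------------------------------

def partition_biotypes(ann: pd.DataFrame, min_transcript_len: int = 400):
    """Split the annotation into usable lncRNA and protein-coding gene ids.

    PC ids are all protein_coding genes.  lncRNA ids are lincRNA genes whose
    longest transcript is at least ``min_transcript_len`` bp and whose gene
    interval does not overlap any PC gene interval (strand-agnostic,
    half-open).  Returns ``(lnc_ids, pc_ids, drop_info)`` where ``drop_info``
    maps ``{"short": [...], "overlap": [...]}`` in attribution order.
    """
    pc = ann[ann["biotype"] == "protein_coding"]
    lnc = ann[ann["biotype"] == "lincRNA"]
    pc_ids = pc["gene_id"].tolist()

    short = lnc.loc[lnc["max_transcript_len"] < min_transcript_len, "gene_id"]
    candidates = lnc[lnc["max_transcript_len"] >= min_transcript_len]

    overlapping = []
    kept = []
    pc_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in pc.groupby("chrom")}
    for row in candidates.itertuples():
        ivals = pc_by_chrom.get(row.chrom)
        if ivals is not None and bool(
            ((row.start < ivals[:, 1]) & (ivals[:, 0] < row.end)).any()
        ):
            overlapping.append(row.gene_id)
        else:
            kept.append(row.gene_id)
    return kept, pc_ids, {"short": short.tolist(), "overlap": overlapping}


def expression_variability_mask(
    values: pd.DataFrame, mean_sd_thresh: float = 1.00, cv_thresh: float = 0.10
):
    """Per-gene masks for the (mean+SD) and CV filters (sample SD, n-1)."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(len(arr))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)  # all-zero gene: CV := 0
    expressed = (mean + sd) > mean_sd_thresh
    variable = cv > cv_thresh
    return expressed, variable


def filter_expressed_variable(
    X: ExpressionMatrix,
    gene_subset=None,
    mean_sd_thresh: float = 1.00,
    cv_thresh: float = 0.10,
):
    """Keep genes with (mean FPKM + SD) > ``mean_sd_thresh`` and CV > ``cv_thresh``.

    SD uses the n-1 denominator.  The CV of an all-zero gene is defined as 0,
    so such genes are dropped.  Returns the filtered matrix and a
    :class:`FilterReport`.
    """
    if gene_subset is None:
        gene_subset = X.gene_ids.tolist()
    else:
        gene_subset = list(gene_subset)
        missing = set(gene_subset) - set(X.gene_ids)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    sub = X.values.loc[gene_subset]
    expressed, variable = expression_variability_mask(sub, mean_sd_thresh, cv_thresh)
    keep = expressed & variable
    kept_ids = sub.index[keep].tolist()
    n_expr = int((~expressed).sum())
    n_cv = int((expressed & ~variable).sum())
    if not kept_ids:
        logger.warning("expression/variability filter removed every gene")
    report = FilterReport(
        n_input=len(gene_subset),
        n_kept=len(kept_ids),
        n_dropped_expression=n_expr,
        n_dropped_cv=n_cv,
        kept_ids=kept_ids,
    )
    return X.subset_genes(kept_ids), report


def apply_gene_filters(
    X: ExpressionMatrix,
    ann: pd.DataFrame,
    min_transcript_len: int = 400,
    mean_sd_thresh: float = 1.00,
    cv_thresh: float = 0.10,
):
    """Full lncRNA gene-filter chain: short -> PC overlap -> expression -> CV.

    Returns ``(lnc_matrix, pc_matrix, report)`` where the report covers the
    lncRNA side (the attribution-ordered FilterReport) and the PC matrix is
    restricted to annotated PC genes present in ``X``.  Matrix genes absent
    from the annotation are dropped with a warning.
    """
    unannotated = X.gene_ids.difference(ann.index)
    if len(unannotated):
        logger.warning(
            "%d matrix genes absent from annotation; dropped", len(unannotated)
        )
    lnc_ids, pc_ids, drops = partition_biotypes(ann, min_transcript_len)
    lnc_present = [g for g in lnc_ids if g in X.gene_ids]
    pc_present = [g for g in pc_ids if g in X.gene_ids]
    in_matrix = set(X.gene_ids)
    n_short = sum(g in in_matrix for g in drops["short"])
    n_overlap = sum(g in in_matrix for g in drops["overlap"])
    lnc_X, sub_report = filter_expressed_variable(
        X, lnc_present, mean_sd_thresh, cv_thresh
    )
    report = FilterReport(
        n_input=n_short + n_overlap + sub_report.n_input,
        n_kept=sub_report.n_kept,
        n_dropped_short=n_short,
        n_dropped_overlap=n_overlap,
        n_dropped_expression=sub_report.n_dropped_expression,
        n_dropped_cv=sub_report.n_dropped_cv,
        kept_ids=sub_report.kept_ids,
    )
    return lnc_X, X.subset_genes(pc_present), report


# ---------------------------------------------------------------------------
# Batch adjustment
# ---------------------------------------------------------------------------

def batch_adjust(X: ExpressionMatrix, batch_labels=None) -> ExpressionMatrix:
    """Per-gene location-scale batch recentring on log2(FPKM+1).

    Each batch's log-values are rescaled to the pooled per-gene mean and SD;
    genes with zero within-batch variance are recentred only.  Values are
    returned on the FPKM scale, clipped at 0.  Requires >= 2 samples per
    batch.
    """
    if batch_labels is None:
        batch_labels = X.sample_meta.loc[X.sample_ids, "batch"]
    batch_labels = pd.Series(np.asarray(batch_labels), index=X.sample_ids)
    counts = batch_labels.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        raise ValueError(f"singleton batches not adjustable: {singletons}")

    logx = np.log2(X.values.to_numpy(dtype=float) + 1.0)
    pooled_mean = logx.mean(axis=1, keepdims=True)
    pooled_sd = logx.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(logx)
    for batch in counts.index:
        cols = np.asarray(batch_labels == batch)
        block = logx[:, cols]
        m = block.mean(axis=1, keepdims=True)
        s = block.std(axis=1, ddof=1, keepdims=True)
        scale = np.where(s > 0, np.where(pooled_sd > 0, pooled_sd, 0.0) / np.where(s > 0, s, 1.0), 0.0)
        # zero within-batch variance -> recentre only (scale term vanishes)
        adj = np.where(s > 0, (block - m) * scale + pooled_mean, block - m + pooled_mean)
        out[:, cols] = adj
    fpkm = np.clip(np.exp2(out) - 1.0, 0.0, None)
    values = pd.DataFrame(fpkm, index=X.gene_ids, columns=X.sample_ids)
    return ExpressionMatrix(values, X.sample_meta)
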