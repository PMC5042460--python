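"""Synthetic two-cohort breast-cancer-like study with known ground truth.

Emulates the data structure the pipeline consumes: two clinical cohorts of
bulk FPKM profiles with planted intrinsic-subtype expression blocks,
planted cis-correlated lncRNA-PC pairs placed inside regulatory domains,
stromal/immune contamination mixed into tumour profiles at per-sample
fractions, and pure-tumour cell-line/PDX panels.

Model: per-gene baseline FPKM is log-normal; subtype signature genes are
multiplied by a fold factor in their subtype's samples; cis pairs share a
latent Gaussian on the log2 scale achieving a target correlation; each
observed bulk profile is the exact mixture ``(1 - phi) * tumour +
phi * environment`` where phi is a Beta-distributed contamination fraction
and the environment is a per-sample blend of a stromal profile and immune
cell-type profiles.  SIC lncRNAs and microenvironment marker genes are
expressed in the environment profiles and (near) silent in tumour cells.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from lncconsensus.data_model import ANNOTATION_COLUMNS, ExpressionMatrix

_LOG2_MIN_FPKM = np.log2(0.02)  # tumour level of environment-restricted genes


def _default_marker_counts() -> dict:
    # neutrophil panel deliberately below the 4-marker eligibility rule
    return {"macrophage": 6, "t_cell": 5, "b_cell": 4, "nk_cell": 4, "neutrophil": 3}


@dataclass
class SimulationConfig:
    """Generator settings; defaults define the study conditions.

    Sample sizes, filters and thresholds mirror the clinical setting the
    pipeline targets: three intrinsic subtypes at 30 samples each per
    cohort, ~900 genes of which ~500 lncRNAs survive the expression and
    variability filters, contamination fractions Beta-distributed with mean
    0.40 and SD 0.16 (bulk tumour purity 0.60 +/- 0.16), and 41-cell-line /
    10-PDX pure panels.
    """

    seed: int = 0
    subtypes: tuple = ("basal", "lumA", "lumB")
    n_per_subtype: int = 30
    n_lnc: int = 520
    n_pc: int = 400
    n_sig_lnc_per_subtype: int = 25
    n_sig_pc_per_subtype: int = 20
    base_log2_mean: float = 2.0
    base_log2_sd: float = 1.0
    noise_log2_sd: float = 0.4
    sig_fold: float = 6.0
    n_cis_pairs: int = 10
    cis_rho: float = 0.9
    cis_log2_sd: float = 1.0
    contamination_alpha: float = 2.9
    contamination_beta: float = 4.4
    n_sic_stromal: int = 10
    n_sic_immune: int = 10
    n_ecm_pc: int = 30
    marker_counts: dict = field(default_factory=_default_marker_counts)
    env_expr: float = 30.0
    sic_env_expr: float = 2.5
    meg3_like_expr: float = 100.0
    tumour_program_env_frac: float = 0.05
    env_noise_log2_sd: float = 0.2
    panel_noise_log2_sd: float = 0.5
    n_celllines: int = 41
    n_pdx: int = 10
    # annotation geometry (one synthetic chromosome, bp)
    chrom: str = "chr1"
    pc_tss0: int = 200_000
    pc_spacing: int = 10_000
    pc_body_len: int = 2_000
    lnc_len: int = 500
    max_ext: int = 1_000_000

    def __post_init__(self) -> None:
        if not (-1.0 < self.cis_rho < 1.0):
            raise ValueError("cis_rho must lie in (-1, 1)")
        for name in ("n_per_subtype", "n_lnc", "n_pc", "n_cis_pairs",
                     "n_celllines", "n_pdx"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.contamination_alpha < 0 or self.contamination_beta <= 0:
            raise ValueError("invalid contamination Beta parameters")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated cohort."""

    subtype: dict            # sample -> planted subtype
    contamination: dict      # sample -> phi in [0, 1]
    metagenes: dict          # subtype -> planted lnc signature genes
    cis_pairs: list          # (lnc_id, pc_id, rho)
    sic_genes: list          # planted SIC lncRNAs
    marker_map: dict         # cell type -> marker PC gene ids
    ecm_genes: list          # stromal/ECM PC gene set
    immune_genes: list       # immune marker PC gene set (all cell types)
    caf_markers: list        # FAP/ACTA2-like CAF marker gene ids
    immune_assoc_lnc: list   # lncs tied specifically to the macrophage profile

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Gene universe (deterministic given cfg.seed; shared by cohorts and panels)
# ---------------------------------------------------------------------------

class _GeneUniverse:
    def __init__(self, cfg: SimulationConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 97]))
        self.cfg = cfg
        self.lnc_ids = [f"LNC{i:04d}" for i in range(1, cfg.n_lnc + 1)]
        self.pc_ids = [f"PC{i:04d}" for i in range(1, cfg.n_pc + 1)]
        self.gene_ids = self.lnc_ids + self.pc_ids

        # --- role assignment (deterministic blocks) ---
        k = len(cfg.subtypes)
        need_lnc = k * cfg.n_sig_lnc_per_subtype + cfg.n_cis_pairs \
            + cfg.n_sic_stromal + cfg.n_sic_immune
        if need_lnc > cfg.n_lnc:
            raise ValueError("n_lnc too small for the planted structure")
        cursor = 0
        self.sig_lnc = {}
        for s in cfg.subtypes:
            self.sig_lnc[s] = self.lnc_ids[cursor:cursor + cfg.n_sig_lnc_per_subtype]
            cursor += cfg.n_sig_lnc_per_subtype
        self.cis_lnc = self.lnc_ids[cursor:cursor + cfg.n_cis_pairs]
        cursor += cfg.n_cis_pairs
        self.sic_stromal = self.lnc_ids[cursor:cursor + cfg.n_sic_stromal]
        cursor += cfg.n_sic_stromal
        self.sic_immune = self.lnc_ids[cursor:cursor + cfg.n_sic_immune]
        cursor += cfg.n_sic_immune
        self.meg3_like = self.sic_stromal[0]
        self.immune_assoc_lnc = self.sic_immune[:3]

        n_markers = sum(cfg.marker_counts.values())
        need_pc = k * cfg.n_sig_pc_per_subtype + cfg.n_cis_pairs \
            + cfg.n_ecm_pc + n_markers
        if need_pc > cfg.n_pc:
            raise ValueError("n_pc too small for the planted structure")
        cursor = 0
        self.sig_pc = {}
        for s in cfg.subtypes:
            self.sig_pc[s] = self.pc_ids[cursor:cursor + cfg.n_sig_pc_per_subtype]
            cursor += cfg.n_sig_pc_per_subtype
        self.cis_pc = self.pc_ids[cursor:cursor + cfg.n_cis_pairs]
        cursor += cfg.n_cis_pairs
        self.ecm_pc = self.pc_ids[cursor:cursor + cfg.n_ecm_pc]
        cursor += cfg.n_ecm_pc
        self.caf_markers = self.ecm_pc[:2]  # FAP- and ACTA2-like
        self.marker_map = {}
        for ct, cnt in cfg.marker_counts.items():
            self.marker_map[ct] = self.pc_ids[cursor:cursor + cnt]
            cursor += cnt
        self.immune_marker_pc = [g for ms in self.marker_map.values() for g in ms]
        env_only_pc = set(self.ecm_pc) | set(self.immune_marker_pc)
        env_only_lnc = set(self.sic_stromal) | set(self.sic_immune)
        self.env_only = env_only_pc | env_only_lnc

        # --- per-gene baselines (log2 FPKM) ---
        base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, len(self.gene_ids))
        self.base = pd.Series(base, index=self.gene_ids)
        # cis genes: well expressed so correlation survives the log2(FPKM+1) read-out
        for g in self.cis_lnc + self.cis_pc:
            self.base[g] = rng.normal(3.0, 0.5)
        # environment-restricted genes are (near) silent in tumour cells
        for g in self.env_only:
            self.base[g] = _LOG2_MIN_FPKM

        # --- environment profiles (FPKM) ---
        # Non-malignant cells share the housekeeping transcriptome (so bulk
        # totals stay balanced, as FPKM's per-million scaling enforces);
        # tumour programs are (near) absent and compartment-specific genes
        # high.
        jitter = lambda n: np.exp2(rng.normal(0.0, 0.3, n))
        base_fpkm = np.exp2(self.base.to_numpy())
        tumour_program = [g for s in cfg.subtypes
                          for g in self.sig_lnc[s] + self.sig_pc[s]]
        tumour_program += self.cis_lnc + self.cis_pc

        def env_profile() -> pd.Series:
            prof = pd.Series(base_fpkm * jitter(len(self.gene_ids)),
                             index=self.gene_ids)
            prof[tumour_program] *= cfg.tumour_program_env_frac
            prof[list(env_only_lnc | env_only_pc)] = 0.0
            return prof

        self.E_stromal = env_profile()
        self.E_stromal[self.sic_stromal] = cfg.sic_env_expr * jitter(cfg.n_sic_stromal)
        self.E_stromal[self.meg3_like] = cfg.meg3_like_expr
        self.E_stromal[self.ecm_pc] = cfg.env_expr * jitter(cfg.n_ecm_pc)
        self.E_immune = {}
        shared_immune = [g for g in self.sic_immune if g not in self.immune_assoc_lnc]
        for ct in cfg.marker_counts:
            prof = env_profile()
            prof[self.marker_map[ct]] = cfg.env_expr * jitter(len(self.marker_map[ct]))
            prof[shared_immune] = cfg.sic_env_expr * jitter(len(shared_immune))
            if ct == "macrophage":
                prof[self.immune_assoc_lnc] = cfg.sic_env_expr * jitter(
                    len(self.immune_assoc_lnc))
            self.E_immune[ct] = prof

        # --- annotation geometry ---
        self.annotation = self._build_annotation()

    def _build_annotation(self) -> pd.DataFrame:
        cfg = self.cfg
        rows = []
        tss = {}
        for i, g in enumerate(self.pc_ids):
            t = cfg.pc_tss0 + i * cfg.pc_spacing
            tss[g] = t
            rows.append((g, g, cfg.chrom, t, t + cfg.pc_body_len, "+",
                         "protein_coding", 1500))
        # cis lncs sit inside the partner's basal domain, clear of gene bodies
        for lnc, pc in zip(self.cis_lnc, self.cis_pc):
            t = tss[pc]
            rows.append((lnc, lnc, cfg.chrom, t - 3400, t - 3400 + cfg.lnc_len,
                         "+", "lincRNA", cfg.lnc_len))
        # remaining lncs live beyond any PC extended domain
        far0 = cfg.pc_tss0 + cfg.n_pc * cfg.pc_spacing + cfg.max_ext + 500_000
        others = [g for g in self.lnc_ids if g not in set(self.cis_lnc)]
        for j, g in enumerate(others):
            s = far0 + j * 2_000
            rows.append((g, g, cfg.chrom, s, s + cfg.lnc_len, "+",
                         "lincRNA", cfg.lnc_len))
        ann = pd.DataFrame(
            rows,
            columns=["gene_id", "symbol", "chrom", "start", "end", "strand",
                     "biotype", "max_transcript_len"],
        )
        ann = ann[ANNOTATION_COLUMNS].set_index("gene_id", drop=False)
        ann.index.name = None
        return ann


def _cohort_seed(cfg: SimulationConfig, label: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([cfg.seed, zlib.crc32(label.encode()) % (2**31)])


def _tumour_log2(uni: _GeneUniverse, subtypes_per_sample, rng) -> np.ndarray:
    """Tumour-cell log2-FPKM profiles (genes x samples)."""
    cfg = uni.cfg
    n = len(subtypes_per_sample)
    G = len(uni.gene_ids)
    idx = {g: i for i, g in enumerate(uni.gene_ids)}
    log2fold = np.log2(cfg.sig_fold)

    T = uni.base.to_numpy()[:, None] + rng.normal(0.0, cfg.noise_log2_sd, (G, n))
    for j, s in enumerate(subtypes_per_sample):
        for g in uni.sig_lnc[s] + uni.sig_pc[s]:
            T[idx[g], j] += log2fold
    # cis pairs: shared latent Gaussian replaces the independent noise
    for lnc, pc in zip(uni.cis_lnc, uni.cis_pc):
        z = rng.normal(size=n)
        e = rng.normal(size=n)
        T[idx[lnc]] = uni.base[lnc] + cfg.cis_log2_sd * z
        T[idx[pc]] = uni.base[pc] + cfg.cis_log2_sd * (
            cfg.cis_rho * z + np.sqrt(1.0 - cfg.cis_rho**2) * e
        )
    return T


def simulate_cohort(cfg: SimulationConfig, cohort_label: str = "A",
                    return_components: bool = False):
    """Generate one clinical cohort: (ExpressionMatrix, GeneAnnotation, SyntheticTruth).

    Observed profiles are the exact mixture ``(1 - phi) * tumour +
    phi * environment``; phi ~ Beta(contamination_alpha, contamination_beta)
    per sample.  Deterministic for a given (cfg.seed, cohort_label).  With
    ``return_components=True`` a fourth element exposes the tumour and
    environment matrices for mixture-conservation checks.
    """
    uni = _GeneUniverse(cfg)
    rng = np.random.default_rng(_cohort_seed(cfg, cohort_label))
    subtype_labels = [s for s in cfg.subtypes for _ in range(cfg.n_per_subtype)]
    n = len(subtype_labels)
    sample_ids = [f"{cohort_label}S{j:03d}" for j in range(1, n + 1)]

    T = np.exp2(_tumour_log2(uni, subtype_labels, rng))
    if cfg.contamination_alpha == 0:
        phi = np.zeros(n)  # contamination switched off entirely
    else:
        phi = rng.beta(cfg.contamination_alpha, cfg.contamination_beta, n)

    # per-sample environment blend: stromal share + immune cell-type weights
    psi = rng.beta(2.0, 2.0, n)
    celltypes = list(cfg.marker_counts)
    w = np.exp(rng.normal(0.0, 0.7, (n, len(celltypes))))
    w /= w.sum(axis=1, keepdims=True)
    E_str = uni.E_stromal.to_numpy()[:, None]
    E_imm = np.column_stack([uni.E_immune[ct].to_numpy() for ct in celltypes])
    env = psi[None, :] * E_str + (1.0 - psi[None, :]) * (E_imm @ w.T)
    env = env * np.exp2(rng.normal(0.0, cfg.env_noise_log2_sd, env.shape))

    observed = (1.0 - phi[None, :]) * T + phi[None, :] * env

    values = pd.DataFrame(observed, index=uni.gene_ids, columns=sample_ids)
    hormone = {"basal": "TNBC", "lumA": "ER+", "lumB": "ER+"}
    meta = pd.DataFrame(
        {
            "cohort": cohort_label,
            "subtype": subtype_labels,
            "hormone_status": [hormone.get(s, "NA") for s in subtype_labels],
            "batch": [f"b{j % 2 + 1}" for j in range(n)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    X = ExpressionMatrix(values, meta)
    truth = SyntheticTruth(
        subtype=dict(zip(sample_ids, subtype_labels)),
        contamination=dict(zip(sample_ids, phi.tolist())),
        metagenes={s: list(uni.sig_lnc[s]) for s in cfg.subtypes},
        cis_pairs=[(l, p, cfg.cis_rho) for l, p in zip(uni.cis_lnc, uni.cis_pc)],
        sic_genes=list(uni.sic_stromal) + list(uni.sic_immune),
        marker_map={ct: list(ms) for ct, ms in uni.marker_map.items()},
        ecm_genes=list(uni.ecm_pc),
        immune_genes=list(uni.immune_marker_pc),
        caf_markers=list(uni.caf_markers),
        immune_assoc_lnc=list(uni.immune_assoc_lnc),
    )
    if return_components:
        components = {"tumour": T, "environment": env, "phi": phi}
        return X, uni.annotation.copy(), truth, components
    return X, uni.annotation.copy(), truth


def simulate_pure_panels(cfg: SimulationConfig):
    """Pure-tumour panels (phi = 0): (X_cellline, X_pdx), same gene universe.

    Panels draw tumour profiles only, with their own per-sample noise, so
    planted SIC genes stay near-silent (median FPKM well under 0.5).
    """
    uni = _GeneUniverse(cfg)
    rng = np.random.default_rng(_cohort_seed(cfg, "panels"))
    panels = []
    for prefix, n_samples in (("CL", cfg.n_celllines), ("PDX", cfg.n_pdx)):
        subtypes = [cfg.subtypes[i % len(cfg.subtypes)] for i in range(n_samples)]
        ids = [f"{prefix}{j:03d}" for j in range(1, n_samples + 1)]
        T = _tumour_log2(uni, subtypes, rng)
        T += rng.normal(0.0, cfg.panel_noise_log2_sd, T.shape)
        values = pd.DataFrame(np.exp2(T), index=uni.gene_ids, columns=ids)
        meta = pd.DataFrame(
            {
                "cohort": prefix,
                "subtype": subtypes,
                "hormone_status": "NA",
                "batch": "b1",
            },
            index=pd.Index(ids, name="sample_id"),
        )
        panels.append(ExpressionMatrix(values, meta))
    return panels[0], panels[1]


def truth_gene_sets(truth: SyntheticTruth, universe, rng=None, n_decoys: int = 5,
                    decoy_size: int = 30) -> dict:
    """GMT-style gene sets for enrichment tests: planted sets plus random decoys."""
    rng = np.random.default_rng(0) if rng is None else rng
    sets = {
        "extracellular_matrix": list(truth.ecm_genes),
        "immune_response": list(truth.immune_genes),
    }
    pool = sorted(set(universe))
    for i in range(n_decoys):
        sets[f"decoy_{i + 1}"] = list(
            rng.choice(pool, size=min(decoy_size, len(pool)), replace=False)
        )
    return sets


def simulate_study(cfg: SimulationConfig, cohort_b_overrides: dict | None = None):
    """Two cohorts plus pure panels sharing one gene universe.

    ``cohort_b_overrides`` may change per-cohort knobs (sample sizes,
    contamination Beta parameters) to emulate cohort asymmetry.
    """
    XA, ann, truthA = simulate_cohort(cfg, "A")
    cfg_b = replace(cfg, **(cohort_b_overrides or {}))
    XB, _, truthB = simulate_cohort(cfg_b, "B")
    X_cl, X_pdx = simulate_pure_panels(cfg)
    return {
        "cohortA": (XA, truthA),
        "cohortB": (XB, truthB),
        "annotation": ann,
        "cellline": X_cl,
        "pdx": X_pdx,
    }
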