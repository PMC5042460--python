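import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lncconsensus import (
    celltype_association,
    cluster_purity_contrast,
    gba_profile,
    purity_estimate,
    sic_filter,
    signature_score,
)

from conftest import make_matrix


def score_for_positions(positions, n_genes=10, alpha=0.25):
    """Signature score of a single sample whose set genes occupy `positions`
    (0 = most expressed) in the expression ranking."""
    expr = np.arange(n_genes, 0, -1, dtype=float)  # strictly decreasing
    gene_ids = [f"g{i}" for i in range(n_genes)]
    X = make_matrix(expr[:, None], gene_ids=gene_ids)
    gene_set = [gene_ids[p] for p in positions]
    return signature_score(X, gene_set, alpha=alpha, min_genes=1).iloc[0]


class TestSignatureScore:
    def test_top_ranked_set_is_maximal_over_all_position_patterns(self):
        scores = {
            pos: score_for_positions(pos)
            for pos in itertools.combinations(range(10), 3)
        }
        assert max(scores, key=scores.get) == (0, 1, 2)

    def test_interleaved_set_scores_near_zero(self):
        n = 20
        interleaved = score_for_positions(tuple(range(0, n, 2)), n_genes=n,
                                          alpha=0.0)
        top = score_for_positions(tuple(range(n // 2)), n_genes=n, alpha=0.0)
        # balanced in/out ECDFs: small compared to the top-ranked arrangement
        assert abs(interleaved) < 0.15 * top

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(1.0, 1.0, (50, 6))
        gene_ids = [f"g{i}" for i in range(50)]
        gene_set = gene_ids[5:25]
        a = signature_score(make_matrix(values, gene_ids=gene_ids), gene_set)
        b = signature_score(
            make_matrix(np.sqrt(values) * 7 + 1, gene_ids=gene_ids), gene_set
        )
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_invariant_to_out_of_set_relabelling(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(0.5, 1.0, (30, 4))
        gene_ids = [f"g{i}" for i in range(30)]
        gene_set = gene_ids[:12]
        a = signature_score(make_matrix(values, gene_ids=gene_ids), gene_set)
        shuffled = gene_ids[:12] + [f"x{i}" for i in range(18)]
        b = signature_score(make_matrix(values, gene_ids=shuffled), gene_set)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_too_small_set_is_an_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="10"):
            signature_score(tiny_matrix, ["G000"])


class TestPurityEstimate:
    def test_equal_scores_give_equal_purity(self):
        s = pd.Series([10.0, 10.0], index=["a", "b"])
        p = purity_estimate(s, s)
        assert p["a"] == p["b"]

    def test_strictly_decreasing_over_valid_score_grid(self):
        grid = np.linspace(0, 3000, 50)
        stromal = pd.Series(grid, index=range(50))
        immune = pd.Series(np.zeros(50), index=range(50))
        p = purity_estimate(stromal, immune)
        assert (np.diff(p.to_numpy()) < 0).all()

    def test_clipped_to_unit_interval(self):
        s = pd.Series([-50_000.0, 50_000.0], index=["lo", "hi"])
        p = purity_estimate(s, s)
        assert p.between(0, 1).all()


def constant_matrix(medians, n_samples, gene_ids, prefix):
    values = np.tile(np.asarray(medians, dtype=float)[:, None], (1, n_samples))
    return make_matrix(values, gene_ids=gene_ids,
                       sample_ids=[f"{prefix}{j}" for j in range(n_samples)])


class TestSICFilter:
    def test_hand_computed_fold_changes(self):
        genes = ["lncA", "lncB"]
        X_clin = constant_matrix([2.0, 1.0], 6, genes, "c")
        X_cl = constant_matrix([0.4, 1.0], 5, genes, "l")
        X_pdx = constant_matrix([0.3, 1.0], 4, genes, "p")
        purity = pd.Series(0.9, index=X_clin.sample_ids)
        res = sic_filter(X_clin, purity, X_cl, X_pdx)
        row = res.table.loc["lncA"]
        assert row.lfc_cl == pytest.approx(np.log2(2.1 / 0.5), abs=1e-12)
        assert row.lfc_pdx == pytest.approx(np.log2(2.1 / 0.4), abs=1e-12)
        assert bool(row.is_sic)
        # identical medians everywhere: zero fold change, not SIC
        assert res.table.loc["lncB", "lfc_cl"] == 0.0
        assert not bool(res.table.loc["lncB", "is_sic"])

    def test_restricted_to_common_genes(self):
        X_clin = constant_matrix([2.0, 2.0], 4, ["a", "b"], "c")
        X_cl = constant_matrix([0.1], 4, ["a"], "l")
        X_pdx = constant_matrix([0.1], 4, ["a"], "p")
        purity = pd.Series(0.9, index=X_clin.sample_ids)
        res = sic_filter(X_clin, purity, X_cl, X_pdx)
        assert list(res.table.index) == ["a"]

    def test_no_high_purity_samples_is_an_error(self):
        X = constant_matrix([1.0], 4, ["a"], "c")
        purity = pd.Series(0.2, index=X.sample_ids)
        with pytest.raises(ValueError, match="purity"):
            sic_filter(X, purity, X, X)

    def test_raising_eps_shrinks_fold_changes_toward_zero(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        X_clin = constant_matrix(rng.uniform(0, 4, 30), 5, genes, "c")
        X_cl = constant_matrix(rng.uniform(0, 1, 30), 5, genes, "l")
        X_pdx = constant_matrix(rng.uniform(0, 1, 30), 5, genes, "p")
        purity = pd.Series(0.9, index=X_clin.sample_ids)
        prev = None
        for eps in (0.05, 0.1, 0.5, 2.0):
            res = sic_filter(X_clin, purity, X_cl, X_pdx, eps=eps)
            lfc = res.table["lfc_cl"].abs()
            if prev is not None:
                assert (lfc <= prev + 1e-12).all()
            prev = lfc

    def test_lowering_expr_cap_never_adds_genes(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        X_clin = constant_matrix(rng.uniform(0, 4, 30), 5, genes, "c")
        X_cl = constant_matrix(rng.uniform(0, 1, 30), 5, genes, "l")
        X_pdx = constant_matrix(rng.uniform(0, 1, 30), 5, genes, "p")
        purity = pd.Series(0.9, index=X_clin.sample_ids)
        wide = set(sic_filter(X_clin, purity, X_cl, X_pdx, expr_cap=0.8).sic_genes)
        narrow = set(sic_filter(X_clin, purity, X_cl, X_pdx, expr_cap=0.3).sic_genes)
        assert narrow <= wide


class TestCelltypeAssociation:
    @pytest.fixture()
    def marker_table(self):
        rows = [("macrophage", f"m{i}") for i in range(5)]
        rows += [("t_cell", f"t{i}") for i in range(4)]
        rows += [("neutrophil", f"n{i}") for i in range(3)]  # below threshold
        return pd.DataFrame(rows, columns=["cell_type", "gene_symbol"])

    def test_under_threshold_cell_type_is_ineligible(self, marker_table):
        rng = np.random.default_rng(4)
        genes = ["lnc"] + [f"m{i}" for i in range(5)] + [f"t{i}" for i in range(4)] \
            + [f"n{i}" for i in range(3)]
        X = make_matrix(rng.lognormal(1, 0.8, (len(genes), 20)), gene_ids=genes)
        out = celltype_association("lnc", X, marker_table)
        assert set(out["cell_type"]) == {"macrophage", "t_cell"}

    def test_identical_markers_give_unit_median(self, marker_table):
        rng = np.random.default_rng(5)
        lnc = rng.lognormal(1, 0.8, 20)
        rows = [lnc] + [lnc] * 5 + [rng.lognormal(1, 0.8, 20) for _ in range(7)]
        genes = ["lnc"] + [f"m{i}" for i in range(5)] + [f"t{i}" for i in range(4)] \
            + [f"n{i}" for i in range(3)]
        X = make_matrix(np.vstack(rows), gene_ids=genes)
        out = celltype_association("lnc", X, marker_table)
        mac = out[out.cell_type == "macrophage"].iloc[0]
        assert mac.median_r == pytest.approx(1.0)
        assert bool(mac.above_line)

    def test_invariant_to_marker_order(self, marker_table):
        rng = np.random.default_rng(6)
        genes = ["lnc"] + [f"m{i}" for i in range(5)] + [f"t{i}" for i in range(4)] \
            + [f"n{i}" for i in range(3)]
        X = make_matrix(rng.lognormal(1, 0.8, (len(genes), 15)), gene_ids=genes)
        a = celltype_association("lnc", X, marker_table)
        shuffled = marker_table.sample(frac=1.0, random_state=1)
        b = celltype_association("lnc", X, shuffled)
        pd.testing.assert_frame_equal(
            a.drop(columns="marker_r"), b.drop(columns="marker_r")
        )


class TestGuiltByAssociation:
    def test_planted_coexpression_recovers_top_set(self):
        rng = np.random.default_rng(7)
        n = 60
        z = rng.normal(size=n)
        ecm_genes = [f"e{i}" for i in range(50)]
        bg_genes = [f"b{i}" for i in range(50)]
        ecm = np.exp2(2 + 0.9 * z[None, :] + 0.4 * rng.normal(size=(50, n)))
        bg = np.exp2(2 + rng.normal(size=(50, n)))
        lnc = np.exp2(2 + z)
        X = make_matrix(np.vstack([lnc, ecm, bg]),
                        gene_ids=["lnc"] + ecm_genes + bg_genes)
        sets = {"extracellular matrix": ecm_genes,
                "decoy": bg_genes[:30]}
        out = gba_profile(["lnc"], X, ecm_genes + bg_genes, sets, r_thresh=0.60)
        assert out["lnc"].top()["set"] == "extracellular matrix"

    def test_threshold_above_one_gives_no_query(self):
        rng = np.random.default_rng(8)
        X = make_matrix(rng.lognormal(1, 0.5, (10, 12)))
        sets = {"s": list(X.gene_ids[1:8])}
        out = gba_profile([X.gene_ids[0]], X, list(X.gene_ids[1:]), sets,
                          r_thresh=1.01)
        assert out[X.gene_ids[0]] is None

    def test_identical_profile_yields_unit_correlation_in_query(self):
        rng = np.random.default_rng(9)
        prof = rng.lognormal(1, 0.8, 15)
        other = rng.lognormal(1, 0.8, (6, 15))
        X = make_matrix(np.vstack([prof, prof, other]),
                        gene_ids=["lnc", "twin"] + [f"o{i}" for i in range(6)])
        sets = {"s": ["twin"] + [f"o{i}" for i in range(4)]}
        out = gba_profile(["lnc"], X, ["twin"] + [f"o{i}" for i in range(6)],
                          sets, r_thresh=0.99)
        assert out["lnc"] is not None
        assert out["lnc"].table.iloc[0]["x"] >= 1


class TestClusterPurityContrast:
    def test_identical_purity_gives_p_one(self):
        purity = pd.Series(0.5, index=[f"s{i}" for i in range(12)])
        clusters = pd.Series([1] * 6 + [2] * 6, index=purity.index)
        _, t, p = cluster_purity_contrast(purity, clusters, 1)
        assert (t, p) == (0.0, 1.0)

    def test_planted_low_purity_cluster_is_significant(self):
        rng = np.random.default_rng(10)
        low = rng.beta(10, 20, 12)    # ~0.33
        high = rng.beta(24, 12, 36)   # ~0.67
        purity = pd.Series(np.concatenate([low, high]),
                           index=[f"s{i}" for i in range(48)])
        clusters = pd.Series([1] * 12 + [2] * 12 + [3] * 12 + [4] * 12,
                             index=purity.index)
        per_cluster, t, p = cluster_purity_contrast(purity, clusters, 1)
        assert p < 0.001 and t < 0
        assert per_cluster[1][0] < per_cluster[2][0]

    def test_swapping_focal_and_rest_flips_t_sign(self):
        rng = np.random.default_rng(11)
        purity = pd.Series(rng.uniform(0.2, 0.9, 20),
                           index=[f"s{i}" for i in range(20)])
        clusters = pd.Series([1] * 10 + [2] * 10, index=purity.index)
        _, t1, p1 = cluster_purity_contrast(purity, clusters, 1)
        _, t2, p2 = cluster_purity_contrast(purity, clusters, 2)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
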