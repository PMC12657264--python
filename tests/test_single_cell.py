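"""Tests for QC filtering, log-normalisation, module/AUC scoring, the
rank-sum DEG test, and composition arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

import reference as ref
from epiquant import single_cell as sc
from epiquant import synthetic as syn


def tiny_matrix(counts, gene_names=None, groups=None, types=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_names = gene_names or [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample": ["s"] * n_cells,
            "group": groups or ["A"] * n_cells,
            "cell_type": types or ["T"] * n_cells,
        }
    ).set_index("cell_id")
    return sc.CountMatrix(
        counts=sparse.csr_matrix(counts),
        gene_names=np.asarray(gene_names, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
        cell_meta=meta,
    )


class TestQc:
    def qc_world(self, n_features_per_cell, total_per_cell, mito_frac):
        """One cell per scenario: expression spread over the first k genes."""
        n_genes = 400
        cols = []
        for k, total, mf in zip(n_features_per_cell, total_per_cell, mito_frac):
            col = np.zeros(n_genes, dtype=int)
            mito_total = int(round(total * mf))
            body = total - mito_total
            col[1 : k + 1] = np.diff(np.linspace(0, body, k + 1).astype(int))
            col[0] = mito_total
            cols.append(col)
        counts = np.column_stack(cols)
        genes = ["mt-Nd1"] + [f"g{i}" for i in range(n_genes - 1)]
        return tiny_matrix(counts, gene_names=genes)

    def test_boundary_250_features_removed(self):
        # "nFeature > 250" is strict: exactly 250 detected genes fails
        m = self.qc_world([250, 251], [5000, 5000], [0.0, 0.0])
        kept = sc.qc_filter(m)
        assert list(kept.cell_ids) == ["c1"]

    def test_count_and_mito_rules(self):
        m = self.qc_world([300, 300, 300], [1000, 1001, 5000], [0.0, 0.0, 0.30])
        kept = sc.qc_filter(m)
        assert list(kept.cell_ids) == ["c1"]  # 1000 UMIs and 30% mito removed

    def test_idempotent(self, counts_world):
        _cfg, matrix, _truth = counts_world
        once = sc.qc_filter(matrix)
        twice = sc.qc_filter(once)
        assert list(once.cell_ids) == list(twice.cell_ids)

    def test_no_survivors_reports_rules(self):
        m = self.qc_world([100, 120], [500, 600], [0.0, 0.5])
        with pytest.raises(ValueError, match="low_features"):
            sc.qc_filter(m)


class TestLogNormalize:
    def test_closed_forms(self):
        m = tiny_matrix([[0, 10], [1000, 990]])
        norm = sc.log_normalize(m)
        assert norm.values[0, 0] == 0.0
        assert norm.values[0, 1] == pytest.approx(np.log(1 + 100))

    def test_single_gene_cell(self):
        m = tiny_matrix([[5], [0]])
        norm = sc.log_normalize(m)
        assert norm.values[0, 0] == pytest.approx(np.log(10001))

    def test_zero_total_cell_rejected(self):
        m = tiny_matrix([[0, 1], [0, 1]])
        with pytest.raises(ValueError, match="zero total"):
            sc.log_normalize(m)

    def test_order_preserving_within_cell(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(30, 4))
        norm = sc.log_normalize(tiny_matrix(counts))
        for c in range(4):
            assert np.array_equal(
                np.argsort(counts[:, c], kind="stable"),
                np.argsort(norm.values[:, c], kind="stable"),
            )


class TestModuleScore:
    def test_determinism_and_shift_invariance(self, counts_world):
        _cfg, matrix, _truth = counts_world
        norm = sc.log_normalize(sc.qc_filter(matrix))
        gs = sc.GeneSet("s", tuple(norm.gene_names[100:104]))
        s1 = sc.module_score(norm, gs, seed=3)
        s2 = sc.module_score(norm, gs, seed=3)
        assert np.array_equal(s1, s2)
        # adding a constant to every gene in a cell leaves the score unchanged
        shifted = sc.NormalizedMatrix(
            norm.values + 0.7, norm.gene_names, norm.cell_ids, norm.cell_meta
        )
        s3 = sc.module_score(shifted, gs, seed=3)
        assert np.allclose(s1, s3)

    def test_large_control_limit_matches_bin_means(self, counts_world):
        # with many control draws the control mean converges to the mean
        # expression of the members' bins (closed-form oracle)
        _cfg, matrix, _truth = counts_world
        norm = sc.log_normalize(sc.qc_filter(matrix))
        members = tuple(norm.gene_names[200:204])
        gs = sc.GeneSet("s", members)
        score = sc.module_score(norm, gs, n_ctrl=4000, seed=0)
        avg = norm.values.mean(axis=1)
        order = np.argsort(avg, kind="stable")
        bin_of = np.empty(norm.n_genes, dtype=int)
        bin_of[order] = (np.arange(norm.n_genes) * 24) // norm.n_genes
        midx = norm.gene_index(members)
        expected = norm.values[midx].mean(axis=0) - np.mean(
            [norm.values[bin_of == bin_of[g]].mean(axis=0) for g in midx], axis=0
        )
        assert np.allclose(score, expected, atol=0.05)

    def test_missing_members_rejected(self, counts_world):
        _cfg, matrix, _truth = counts_world
        norm = sc.log_normalize(matrix)
        with pytest.raises(KeyError, match="Nope"):
            sc.module_score(norm, sc.GeneSet("s", ("Nope1", "Nope2")))

    def test_agrees_with_scanpy(self, counts_world):
        # independent cross-check against scanpy's implementation of the
        # same bin-matched control scheme
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        cfg, matrix, _truth = counts_world
        norm = sc.log_normalize(sc.qc_filter(matrix))
        genes = tuple(cfg.planted_sets[0].genes)
        ours = sc.module_score(norm, sc.GeneSet("sig", genes), n_ctrl=500, seed=0)
        adata = anndata.AnnData(
            X=norm.values.T.copy(),
            obs=norm.cell_meta.copy(),
            var=pd.DataFrame(index=list(norm.gene_names)),
        )
        scanpy.tl.score_genes(adata, list(genes), ctrl_size=500, n_bins=24, score_name="sp")
        assert np.corrcoef(ours, adata.obs["sp"].to_numpy())[0, 1] > 0.95


class TestAucScore:
    def random_norm(self, n_genes=2000, n_cells=300, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.random((n_genes, n_cells))
        cell_ids = [f"c{i}" for i in range(n_cells)]
        meta = pd.DataFrame(
            {"cell_id": cell_ids, "sample": "s", "group": "A", "cell_type": "T"}
        ).set_index("cell_id")
        return sc.NormalizedMatrix(
            values,
            np.asarray([f"g{i}" for i in range(n_genes)], dtype=object),
            np.asarray(cell_ids, dtype=object),
            meta,
        )

    def test_extremes(self):
        norm = self.random_norm(n_genes=100, n_cells=3)
        members = tuple(f"g{i}" for i in range(4))
        top = norm.values.copy()
        top[:4] = 10.0 + np.arange(4)[:, None]  # members occupy the top ranks
        hot = sc.NormalizedMatrix(top, norm.gene_names, norm.cell_ids, norm.cell_meta)
        assert np.allclose(sc.auc_score(hot, sc.GeneSet("s", members), top_fraction=0.1), 1.0)
        cold = norm.values.copy()
        cold[:4] = -1.0  # members at the bottom
        cold_m = sc.NormalizedMatrix(cold, norm.gene_names, norm.cell_ids, norm.cell_meta)
        assert np.allclose(sc.auc_score(cold_m, sc.GeneSet("s", members), top_fraction=0.1), 0.0)

    def test_random_matches_monte_carlo(self):
        norm = self.random_norm()
        members = tuple(f"g{i}" for i in range(0, 2000, 100))  # 20 genes
        scores = sc.auc_score(norm, sc.GeneSet("s", members), top_fraction=0.05)
        k = 100
        mc_mean, mc_se = ref.mc_auc_expectation(
            2000, 20, k, n_draws=3000, rng=np.random.default_rng(99)
        )
        cell_se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean() - mc_mean) < 3 * np.hypot(mc_se, cell_se)

    def test_monotone_transform_invariance(self):
        norm = self.random_norm(n_genes=500, n_cells=50)
        members = tuple(f"g{i}" for i in range(10))
        gs = sc.GeneSet("s", members)
        base = sc.auc_score(norm, gs, seed=4)
        warped = sc.NormalizedMatrix(
            np.exp(3.0 * norm.values), norm.gene_names, norm.cell_ids, norm.cell_meta
        )
        assert np.allclose(base, sc.auc_score(warped, gs, seed=4))

    def test_set_larger_than_window_rejected(self):
        norm = self.random_norm(n_genes=100, n_cells=2)
        with pytest.raises(ValueError, match="window"):
            sc.auc_score(norm, sc.GeneSet("s", tuple(f"g{i}" for i in range(20))), top_fraction=0.05)


class TestWilcoxonDeg:
    def test_exact_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 40, size=(20, 10))
        m = tiny_matrix(counts, groups=["A"] * 5 + ["B"] * 5)
        norm = sc.log_normalize(m)
        degs = sc.wilcoxon_deg(norm).set_index("gene")
        for g in range(20):
            name = f"g{g}"
            if name not in degs.index:
                continue
            p_oracle = ref.exact_ranksum_pvalues(norm.values[g, :5], norm.values[g, 5:])
            assert degs.loc[name, "p_value"] == pytest.approx(p_oracle, abs=0.01)

    def test_sign_conventions(self):
        counts = np.zeros((10, 12), dtype=int)
        counts[0, :6] = 20  # expressed only in group A
        counts[1:] = 5
        m = tiny_matrix(counts, groups=["A"] * 6 + ["B"] * 6)
        norm = sc.log_normalize(m)
        degs = sc.wilcoxon_deg(norm, groups=("A", "B")).set_index("gene")
        assert degs.loc["g0", "avg_log2FC"] > 0
        swapped = sc.wilcoxon_deg(norm, groups=("B", "A")).set_index("gene")
        assert swapped.loc["g0", "avg_log2FC"] == pytest.approx(
            -degs.loc["g0", "avg_log2FC"]
        )

    def test_null_pvalues_uniform(self):
        cfg = syn.CountSimConfig(n_genes=2000, cells_per_type={"OL": 150}, seed=21)
        matrix, _ = syn.gen_count_matrix(cfg)
        norm = sc.log_normalize(matrix)
        rng = np.random.default_rng(5)
        norm.cell_meta = norm.cell_meta.copy()
        norm.cell_meta["group"] = rng.permutation(norm.cell_meta["group"].to_numpy())
        degs = sc.wilcoxon_deg(norm)
        ks = stats.kstest(degs["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_small_group_rejected(self):
        m = tiny_matrix(np.ones((5, 4), dtype=int), groups=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="3 cells"):
            sc.wilcoxon_deg(sc.log_normalize(m))


class TestFilterDegs:
    def records(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "p_value": [0.001, 0.0001, 0.2],
                "p_adjusted": [0.01, 0.001, 0.3],
                "avg_log2FC": [1.0, 2.3, 4.0],
            }
        )

    def test_strict_boundaries(self):
        kept = sc.filter_degs(self.records())
        assert list(kept.gene) == ["b"]  # lfc exactly 1.0 removed; p_adj 0.3 removed

    def test_alpha_zero_empty(self):
        assert sc.filter_degs(self.records(), alpha=0.0).empty


class TestComposition:
    def test_published_worked_example(self):
        # 5292/11707 OL in the epileptic group, 3219/10432 in controls
        meta = pd.DataFrame(
            {
                "group": ["TLE"] * 11707 + ["Con"] * 10432,
                "cell_type": (
                    ["OL"] * 5292 + ["Other"] * (11707 - 5292)
                    + ["OL"] * 3219 + ["Other"] * (10432 - 3219)
                ),
            }
        )
        table = sc.composition(meta).set_index(["group", "cell_type"])
        assert table.loc[("TLE", "OL"), "percent"] == 45.2
        assert table.loc[("Con", "OL"), "percent"] == 30.9

    def test_equal_split(self):
        meta = pd.DataFrame({"group": ["A"] * 10, "cell_type": ["x"] * 5 + ["y"] * 5})
        table = sc.composition(meta)
        assert (table.percent == 50.0).all()

    def test_percent_sums_to_100(self, counts_world):
        _cfg, matrix, _truth = counts_world
        table = sc.composition(matrix.cell_meta)
        sums = table.groupby("group").percent.sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.composition(pd.DataFrame(columns=["group", "cell_type"]))
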