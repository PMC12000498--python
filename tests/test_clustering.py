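import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6akit.clustering import (build_feature_matrix, cluster_correlation_sign,
                               hypergeometric_enrichment, kmeans_cluster)
from m6akit.errors import ParameterError
from m6akit.io import GeneSetCollection
from m6akit.landscape import M6ALandscape


def make_landscape(z_values: np.ndarray, pops: list[str]) -> M6ALandscape:
    genes = [f"G{i:03d}" for i in range(z_values.shape[0])]
    z = pd.DataFrame(z_values, index=pd.Index(genes, name="gene_id"), columns=pops)
    is_target = pd.DataFrame(True, index=z.index, columns=pops, dtype="boolean")
    return M6ALandscape(z, is_target)


POPS = ["A", "B", "C", "D"]


class TestFeatureMatrix:
    def test_width_and_constant_gene_row(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(20, 4))
        z[0] = 1.0  # constant in m6A
        ls = make_landscape(z, POPS)
        expr = pd.DataFrame(np.full((20, 4), 7.0), index=ls.z.index, columns=POPS)
        feats = build_feature_matrix(ls, expr)
        assert feats.shape[1] == 2 * len(POPS)
        np.testing.assert_allclose(feats.iloc[0, :4], 0.0, atol=1e-12)  # m6a row
        np.testing.assert_allclose(feats.loc[:, feats.columns[4:]], 0.0, atol=1e-12)

    def test_channel_pooled_variance_one(self):
        rng = np.random.default_rng(1)
        ls = make_landscape(rng.normal(size=(50, 4)), POPS)
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(50, 4)), index=ls.z.index,
                            columns=POPS)
        feats = build_feature_matrix(ls, expr)
        m6a_block = feats.iloc[:, :4].to_numpy()
        expr_block = feats.iloc[:, 4:].to_numpy()
        assert (m6a_block ** 2).mean() == pytest.approx(1.0, abs=1e-9)
        assert (expr_block ** 2).mean() == pytest.approx(1.0, abs=1e-9)

    def test_incomplete_rows_dropped(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(10, 4))
        z[3, 1] = np.nan
        ls = make_landscape(z, POPS)
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(10, 4)), index=ls.z.index,
                            columns=POPS)
        feats = build_feature_matrix(ls, expr)
        assert "G003" not in feats.index

    def test_empty_intersection_errors(self):
        ls = make_landscape(np.random.default_rng(3).normal(size=(5, 4)), POPS)
        expr = pd.DataFrame(np.ones((5, 4)), index=ls.z.index, columns=POPS)
        with pytest.raises(ParameterError):
            build_feature_matrix(ls, expr, genes=["NOPE"])


class TestKMeans:
    def test_k1_inertia_is_total_ss(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(30, 6)),
                           index=[f"G{i}" for i in range(30)])
        assignment = kmeans_cluster(mat, k=1, seed=0)
        assert set(assignment.labels) == {1}
        centered = mat - mat.mean(axis=0)
        assert assignment.inertia == pytest.approx(
            float((centered ** 2).to_numpy().sum()), rel=1e-9)

    def test_planted_blobs_perfect_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(40, 6))
        b = rng.normal(8, 1, size=(40, 6))
        mat = pd.DataFrame(np.vstack([a, b]),
                           index=[f"G{i:03d}" for i in range(80)])
        truth = [0] * 40 + [1] * 40
        assignment = kmeans_cluster(mat, k=2, seed=5)
        assert adjusted_rand_score(truth, assignment.labels.to_numpy()) == 1.0

    def test_duplicated_row_same_label(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(20, 4))
        base[7] = base[3]  # exact duplicate
        mat = pd.DataFrame(base, index=[f"G{i}" for i in range(20)])
        assignment = kmeans_cluster(mat, k=3, seed=1)
        assert assignment.labels.iloc[7] == assignment.labels.iloc[3]

    def test_k_exceeds_rows(self):
        mat = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        with pytest.raises(ParameterError):
            kmeans_cluster(mat, k=4, seed=0)
        with pytest.raises(ParameterError):
            kmeans_cluster(mat, k=0, seed=0)

    def test_labels_renumbered_by_size(self):
        rng = np.random.default_rng(7)
        big = rng.normal(0, 0.2, size=(30, 3))
        small = rng.normal(10, 0.2, size=(5, 3))
        mat = pd.DataFrame(np.vstack([small, big]),
                           index=[f"G{i:02d}" for i in range(35)])
        assignment = kmeans_cluster(mat, k=2, seed=2)
        # the larger cluster must carry label 1
        assert (assignment.labels == 1).sum() == 30
        assert assignment.labels.iloc[0] == 2

    def test_determinism(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.normal(size=(40, 5)),
                           index=[f"G{i}" for i in range(40)])
        a = kmeans_cluster(mat, k=3, seed=9)
        b = kmeans_cluster(mat, k=3, seed=9)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestCorrelationSign:
    def _assignment(self, labels, genes):
        from m6akit.clustering import ClusterAssignment
        return ClusterAssignment(pd.Series(labels, index=genes, name="cluster"),
                                 k=len(set(labels)), seed=0, n_init=10,
                                 inertia=0.0)

    def test_identical_profiles_r_one(self):
        rng = np.random.default_rng(9)
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.tile(profile, (10, 1)) + rng.normal(0, 1e-9, size=(10, 4))
        ls = make_landscape(z, POPS)
        # expression chosen so log2(mean+1) equals the m6A profile
        expr = pd.DataFrame(np.tile(2.0 ** profile - 1, (10, 1)),
                            index=ls.z.index, columns=POPS)
        assignment = self._assignment([1] * 10, list(ls.z.index))
        out = cluster_correlation_sign(assignment, ls, expr)
        assert out.iloc[0]["r"] == pytest.approx(1.0, abs=1e-6)
        assert out.iloc[0]["sign"] == "positive"

    def test_negated_profiles_r_minus_one(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.tile(-profile, (10, 1))
        ls = make_landscape(z, POPS)
        expr = pd.DataFrame(np.tile(2.0 ** profile - 1, (10, 1)),
                            index=ls.z.index, columns=POPS)
        assignment = self._assignment([1] * 10, list(ls.z.index))
        out = cluster_correlation_sign(assignment, ls, expr)
        assert out.iloc[0]["r"] == pytest.approx(-1.0, abs=1e-9)
        assert out.iloc[0]["sign"] == "negative"

    def test_needs_three_populations(self):
        ls = make_landscape(np.ones((5, 2)), ["A", "B"])
        expr = pd.DataFrame(np.ones((5, 2)), index=ls.z.index, columns=["A", "B"])
        assignment = self._assignment([1] * 5, list(ls.z.index))
        with pytest.raises(ParameterError):
            cluster_correlation_sign(assignment, ls, expr)

    def test_zero_variance_flagged(self):
        ls = make_landscape(np.ones((5, 4)), POPS)
        expr = pd.DataFrame(np.random.default_rng(0).lognormal(1, 1, (5, 4)),
                            index=ls.z.index, columns=POPS)
        assignment = self._assignment([1] * 5, list(ls.z.index))
        out = cluster_correlation_sign(assignment, ls, expr)
        assert out.iloc[0]["sign"] == "undefined"


def brute_force_hypergeom_p(N, K, n, k):
    """P(overlap >= k) by enumerating all C(N, n) draws."""
    universe = list(range(N))
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(annotated & set(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestHypergeometric:
    def _run(self, N, K, n):
        universe = {f"G{i}" for i in range(N)}
        annotated = {f"G{i}" for i in range(K)}
        selected = {f"G{i}" for i in range(n)}
        gsc = GeneSetCollection({"set": annotated})
        out = hypergeometric_enrichment(selected, gsc, universe)
        return out.iloc[0]

    def test_exact_1_over_252(self):
        row = self._run(10, 5, 5)
        # selected == annotated (both first 5 genes): k = 5
        assert row["overlap"] == 5
        assert row["p_value"] == pytest.approx(1 / 252, rel=1e-9)

    def test_empty_selection(self):
        universe = {f"G{i}" for i in range(10)}
        gsc = GeneSetCollection({"set": {f"G{i}" for i in range(4)}})
        out = hypergeometric_enrichment(set(), gsc, universe)
        assert out.iloc[0]["p_value"] == 1.0

    def test_all_annotated_p_one(self):
        universe = {f"G{i}" for i in range(8)}
        gsc = GeneSetCollection({"set": set(universe)})
        out = hypergeometric_enrichment({f"G{i}" for i in range(3)}, gsc, universe)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(6, 3, 2), (8, 4, 5), (10, 5, 5),
                                       (12, 7, 4), (9, 2, 6)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        row = self._run(N, K, n)
        k = int(row["overlap"])
        assert row["p_value"] == pytest.approx(
            brute_force_hypergeom_p(N, K, n, k), rel=1e-9)

    def test_selected_outside_universe_rejected(self):
        gsc = GeneSetCollection({"set": {"G1"}})
        with pytest.raises(ParameterError):
            hypergeometric_enrichment({"ALIEN"}, gsc, {"G1", "G2"})

    def test_empty_universe_rejected(self):
        gsc = GeneSetCollection({"set": {"G1"}})
        with pytest.raises(ParameterError):
            hypergeometric_enrichment(set(), gsc, set())

    def test_bh_column_present(self):
        universe = {f"G{i}" for i in range(12)}
        gsc = GeneSetCollection({"a": {"G0", "G1"}, "b": {"G5", "G6", "G7"}})
        out = hypergeometric_enrichment({"G0", "G1", "G2"}, gsc, universe)
        assert ((out["padj"] >= out["p_value"] - 1e-12) & (out["padj"] <= 1)).all()
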