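import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from coexnet.modules import (
    GREY,
    ModulePartition,
    auto_merge,
    cluster_genes,
    compute_eigengene,
    connectivity_stats,
    dynamic_tree_cut,
    eigengene_dissimilarity,
    eigengene_matrix,
    manual_merge,
    reassign_by_kme,
)
from coexnet.network import NetworkModel
from conftest import make_expression


def tom_frame(dissim, genes=None):
    dissim = np.asarray(dissim, dtype=float)
    genes = genes or [f"G{i}" for i in range(dissim.shape[0])]
    return pd.DataFrame(1.0 - dissim, index=genes, columns=genes)


def naive_average_linkage(dissim):
    """O(n^3) agglomeration oracle returning the sorted merge heights."""
    d = {frozenset([i]): None for i in range(dissim.shape[0])}
    clusters = [frozenset([i]) for i in range(dissim.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                dist = np.mean([dissim[i, j] for i in ca for j in cb])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
    return sorted(heights)


class TestClusterGenes:
    def test_forced_first_merge(self):
        dissim = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        Z = cluster_genes(tom_frame(dissim))
        assert Z[0, 2] == pytest.approx(0.1)
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]

    def test_matches_naive_agglomeration_oracle(self, rng):
        d = rng.uniform(0.1, 1.0, size=(7, 7))
        dissim = (d + d.T) / 2
        np.fill_diagonal(dissim, 0)
        Z = cluster_genes(tom_frame(dissim))
        np.testing.assert_allclose(
            sorted(Z[:, 2]), naive_average_linkage(dissim), atol=1e-12
        )

    def test_permutation_gives_same_height_multiset(self, rng):
        d = rng.uniform(0.1, 1.0, size=(8, 8))
        dissim = (d + d.T) / 2
        np.fill_diagonal(dissim, 0)
        perm = rng.permutation(8)
        Z1 = cluster_genes(tom_frame(dissim))
        Z2 = cluster_genes(tom_frame(dissim[np.ix_(perm, perm)]))
        np.testing.assert_allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]), atol=1e-12)

    def test_requires_two_genes(self):
        with pytest.raises(ValueError, match="2 genes"):
            cluster_genes(tom_frame(np.zeros((1, 1))))


def planted_network(rng, block_sizes, n_noise, within=0.8, beta=6, n_samples=60):
    """Expression with correlated blocks plus iid noise genes, and its network."""
    rows, truth = [], []
    for b, size in enumerate(block_sizes):
        factor = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(
                np.sqrt(within) * factor + np.sqrt(1 - within) * rng.normal(size=n_samples)
            )
            truth.append(f"block{b}")
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        truth.append("noise")
    expr = make_expression(np.array(rows))
    return expr, truth, NetworkModel.from_expression(expr, beta=beta)


class TestDynamicTreeCut:
    def test_planted_blocks_recovered_and_noise_grey(self, rng):
        from sklearn.metrics import adjusted_rand_score

        expr, truth, net = planted_network(rng, [50, 50, 50], 100)
        Z = cluster_genes(net.tom)
        part = dynamic_tree_cut(Z, net.tom, min_module_size=30)
        assert len(part.modules()) == 3
        assert adjusted_rand_score(truth, list(part.labels)) >= 0.8
        noise_labels = [
            part.labels.iloc[i] for i, t in enumerate(truth) if t == "noise"
        ]
        assert np.mean([lab == GREY for lab in noise_labels]) > 0.5

    def test_min_size_above_n_genes_all_grey(self, rng):
        expr, _, net = planted_network(rng, [20], 0)
        Z = cluster_genes(net.tom)
        with pytest.warns(RuntimeWarning, match="all genes grey"):
            part = dynamic_tree_cut(Z, net.tom, min_module_size=50)
        assert set(part.labels) == {GREY}

    def test_min_size_above_largest_block_all_grey(self, rng):
        expr, _, net = planted_network(rng, [30, 30], 0)
        Z = cluster_genes(net.tom)
        part = dynamic_tree_cut(Z, net.tom, min_module_size=35)
        assert set(part.labels) == {GREY}

    def test_single_block_permutation_invariant(self, rng):
        expr, truth, net = planted_network(rng, [40], 60)
        Z = cluster_genes(net.tom)
        part = dynamic_tree_cut(Z, net.tom, min_module_size=30)
        assert len(part.modules()) == 1
        perm = rng.permutation(net.tom.shape[0])
        genes = list(net.tom.index)
        tom_p = net.tom.iloc[perm, perm]
        part_p = dynamic_tree_cut(cluster_genes(tom_p), tom_p, min_module_size=30)
        assert part_p.labels.loc[genes].tolist() == part.labels.tolist()

    def test_deterministic(self, rng):
        expr, _, net = planted_network(rng, [40, 40], 40)
        Z = cluster_genes(net.tom)
        p1 = dynamic_tree_cut(Z, net.tom)
        p2 = dynamic_tree_cut(Z, net.tom)
        assert p1.labels.equals(p2.labels)

    def test_invalid_deep_split(self, rng):
        expr, _, net = planted_network(rng, [10], 0)
        with pytest.raises(ValueError, match="0..4"):
            dynamic_tree_cut(cluster_genes(net.tom), net.tom, deep_split=7)


class TestEigengene:
    def test_single_gene_module_is_the_zscored_gene(self, rng):
        expr = make_expression(rng.normal(size=(3, 12)))
        eg = compute_eigengene(expr, ["G1"])
        gene = expr.frame.loc["G1"].to_numpy()
        z = (gene - gene.mean()) / gene.std()
        cor = np.corrcoef(eg.vector, z)[0, 1]
        assert abs(cor) == pytest.approx(1.0)
        assert cor > 0  # orientation toward the member gene
        assert eg.variance_explained == pytest.approx(1.0)

    def test_anticorrelated_pair_fully_explained(self, rng):
        g = rng.normal(size=10)
        expr = make_expression([g, -g])
        eg = compute_eigengene(expr, ["G0", "G1"])
        assert eg.variance_explained == pytest.approx(1.0)
        # tie in mean member correlation resolved toward the first gene
        assert np.corrcoef(eg.vector, expr.frame.loc["G0"])[0, 1] > 0

    def test_matches_svd_oracle(self, rng):
        values = rng.normal(size=(20, 15))
        expr = make_expression(values)
        eg = compute_eigengene(expr, expr.gene_ids)
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(z)
        expected = vt[0]
        dot = float(eg.vector.to_numpy() @ expected)
        np.testing.assert_allclose(eg.vector.to_numpy(), np.sign(dot) * expected, atol=1e-10)
        assert eg.variance_explained == pytest.approx(s[0] ** 2 / np.sum(s**2))

    def test_zero_variance_member_excluded_with_warning(self, rng):
        values = rng.normal(size=(3, 8))
        values[1] = 5.0
        expr = make_expression(values)
        with pytest.warns(RuntimeWarning, match="G1"):
            eg = compute_eigengene(expr, expr.gene_ids)
        assert eg.excluded_genes == ["G1"]

    def test_empty_module_rejected(self, rng):
        expr = make_expression(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match="no member genes"):
            compute_eigengene(expr, [])


class TestEigengeneDissimilarity:
    def test_worked_value(self, rng):
        # construct two vectors with correlation exactly 0.20
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= (b @ a) / (a @ a) * a
        b = (b - b.mean()) / b.std()
        me_b = 0.20 * a + np.sqrt(1 - 0.04) * b
        assert eigengene_dissimilarity(pd.Series(a), pd.Series(me_b)) == pytest.approx(0.80)

    def test_identity_and_bound(self, rng):
        v = pd.Series(rng.normal(size=30))
        assert eigengene_dissimilarity(v, v) == pytest.approx(0.0)
        assert eigengene_dissimilarity(v, -v) == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            eigengene_dissimilarity(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))


def partition_from(labels_list, genes, min_module_size=2):
    return ModulePartition(
        pd.Series(labels_list, index=genes), min_module_size=min_module_size
    )


class TestAutoMerge:
    def test_same_factor_modules_merge(self, rng):
        factor = rng.normal(size=40)
        rows = [
            np.sqrt(0.9) * factor + np.sqrt(0.1) * rng.normal(size=40) for _ in range(20)
        ]
        expr = make_expression(np.array(rows))
        part = partition_from(["turquoise"] * 10 + ["blue"] * 10, expr.gene_ids)
        merged = auto_merge(part, expr, merge_cut_height=0.25)
        assert len(merged.modules()) == 1

    def test_dissimilar_modules_not_merged(self, rng):
        # two independent factors: eigengene dissimilarity ~1 >> 0.25
        rows = []
        for _ in range(2):
            factor = rng.normal(size=40)
            rows += [
                np.sqrt(0.9) * factor + np.sqrt(0.1) * rng.normal(size=40)
                for _ in range(10)
            ]
        expr = make_expression(np.array(rows))
        part = partition_from(["yellow"] * 10 + ["brown"] * 10, expr.gene_ids)
        me, _ = eigengene_matrix(expr, part)
        dissim = eigengene_dissimilarity(me["yellow"], me["brown"])
        assert dissim > 0.25  # the situation the threshold is meant to keep apart
        merged = auto_merge(part, expr, merge_cut_height=0.25)
        assert sorted(merged.modules()) == ["brown", "yellow"]

    def test_zero_height_is_identity(self, rng):
        expr = make_expression(rng.normal(size=(8, 20)))
        part = partition_from(["a"] * 4 + ["b"] * 4, expr.gene_ids)
        merged = auto_merge(part, expr, merge_cut_height=0.0)
        assert merged.labels.equals(part.labels)

    def test_idempotent_at_fixpoint(self, rng):
        rows = []
        for _ in range(3):
            factor = rng.normal(size=50)
            rows += [
                np.sqrt(0.85) * factor + np.sqrt(0.15) * rng.normal(size=50)
                for _ in range(8)
            ]
        expr = make_expression(np.array(rows))
        part = partition_from(
            ["m1"] * 8 + ["m2"] * 8 + ["m3"] * 8, expr.gene_ids
        )
        once = auto_merge(part, expr, 0.25)
        twice = auto_merge(once, expr, 0.25)
        assert once.labels.equals(twice.labels)

    def test_grey_never_merged(self, rng):
        factor = rng.normal(size=40)
        rows = [
            np.sqrt(0.9) * factor + np.sqrt(0.1) * rng.normal(size=40) for _ in range(12)
        ]
        expr = make_expression(np.array(rows))
        part = partition_from(["a"] * 4 + ["b"] * 4 + [GREY] * 4, expr.gene_ids)
        merged = auto_merge(part, expr, 0.5)
        assert (merged.labels.iloc[8:] == GREY).all()


class TestManualMerge:
    def test_yellow_brown_sizes(self, rng):
        genes = [f"G{i}" for i in range(200)]
        labels = ["yellow"] * 42 + ["brown"] * 144 + [GREY] * 14
        part = partition_from(labels, genes, min_module_size=30)
        merged = manual_merge(part, ["yellow", "brown"], "yb")
        assert merged.module_sizes()["yb"] == 186

    def test_duplicate_names_rejected(self, rng):
        part = partition_from(["a"] * 3 + ["b"] * 3, [f"G{i}" for i in range(6)])
        with pytest.raises(ValueError, match="duplicated"):
            manual_merge(part, ["a", "a"], "x")

    def test_unknown_and_grey_rejected(self):
        part = partition_from(["a"] * 3 + [GREY] * 3, [f"G{i}" for i in range(6)])
        with pytest.raises(KeyError, match="nope"):
            manual_merge(part, ["a", "nope"], "x")
        with pytest.raises(ValueError, match="grey"):
            manual_merge(part, ["a", GREY], "x")

    def test_merged_eigengene_is_recomputed_not_averaged(self, rng):
        expr = make_expression(rng.normal(size=(12, 25)))
        part = partition_from(["a"] * 6 + ["b"] * 6, expr.gene_ids)
        merged = manual_merge(part, ["a", "b"], "ab")
        eg = compute_eigengene(expr, merged.members("ab"))
        me, entries = eigengene_matrix(expr, merged)
        np.testing.assert_allclose(me["ab"], eg.vector, atol=1e-12)
        # and it differs from the average of the two original eigengenes
        me_orig, _ = eigengene_matrix(expr, part)
        avg = (me_orig["a"] + me_orig["b"]).to_numpy()
        avg /= np.linalg.norm(avg)
        assert not np.allclose(np.abs(eg.vector @ avg), 1.0, atol=1e-6)


class TestConnectivityStats:
    def test_two_gene_module_kwithin_is_adjacency(self, rng):
        expr = make_expression(rng.normal(size=(2, 10)))
        net = NetworkModel.from_expression(expr, beta=3)
        part = partition_from(["m", "m"], expr.gene_ids)
        stats = connectivity_stats(expr, net.adjacency, part)
        expected = net.adjacency.iloc[0, 1]
        assert stats.kwithin["G0"] == pytest.approx(expected)
        assert stats.kwithin["G1"] == pytest.approx(expected)

    def test_single_gene_module_kme_plus_one(self, rng):
        expr = make_expression(rng.normal(size=(3, 10)))
        part = partition_from(["solo", "x", "x"], expr.gene_ids, min_module_size=1)
        net = NetworkModel.from_expression(expr, beta=3)
        stats = connectivity_stats(expr, net.adjacency, part)
        assert stats.kme.loc["G0", "solo"] == pytest.approx(1.0)

    def test_matches_definitional_oracle(self, rng):
        expr = make_expression(rng.normal(size=(9, 14)))
        net = NetworkModel.from_expression(expr, beta=4)
        labels = ["a"] * 4 + ["b"] * 3 + [GREY] * 2
        part = partition_from(labels, expr.gene_ids)
        stats = connectivity_stats(expr, net.adjacency, part)
        me, _ = eigengene_matrix(expr, part)
        adj = net.adjacency.to_numpy()
        for gi, gene in enumerate(expr.gene_ids):
            for module in me.columns:
                expected = np.corrcoef(expr.values[gi], me[module])[0, 1]
                assert stats.kme.loc[gene, module] == pytest.approx(expected, abs=1e-12)
            same = [j for j, lab in enumerate(labels) if lab == labels[gi] and j != gi]
            assert stats.kwithin[gene] == pytest.approx(adj[gi, same].sum(), abs=1e-12)

    def test_hub_ranking_breaks_ties_lexically(self):
        kw = pd.Series({"Gb": 1.0, "Ga": 1.0, "Gc": 2.0})
        from coexnet.modules import ConnectivityStats

        stats = ConnectivityStats(kme=pd.DataFrame(index=kw.index), kwithin=kw)
        part = partition_from(["m"] * 3, ["Gb", "Ga", "Gc"])
        assert stats.hub_genes(part, "m", n=3) == ["Gc", "Ga", "Gb"]


class TestReassignByKme:
    def test_grey_gene_joins_matching_module(self, rng):
        factor = rng.normal(size=50)
        rows = [
            np.sqrt(0.9) * factor + np.sqrt(0.1) * rng.normal(size=50) for _ in range(9)
        ] + [rng.normal(size=50)]
        expr = make_expression(np.array(rows))
        labels = ["m"] * 8 + [GREY, GREY]  # G8 tracks the factor, G9 is noise
        rows[8] = factor
        expr = make_expression(np.array(rows))
        part = partition_from(labels, expr.gene_ids)
        out = reassign_by_kme(part, expr, min_kme=0.5)
        assert out.labels["G8"] == "m"
        assert out.labels["G9"] == GREY
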