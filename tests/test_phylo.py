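"""Neighbor joining, additivity, and clade/locus concordance."""

import numpy as np
import pytest

from rlpscape import lrr, phylo
from rlpscape.clusters import call_clusters


def random_additive_instance(rng, n):
    """A random binary tree with uniform edge lengths and its leaf distances.

    Built by sequential attachment: each new leaf is grafted onto a random
    existing edge, which keeps the metric exactly additive.  Distances are
    computed as path sums over the tree graph (the oracle is independent of
    the neighbor-joining code under test).
    """
    import networkx as nx

    g = nx.Graph()
    g.add_edge("L0", "L1", length=float(rng.uniform(0.1, 1.0)))
    next_internal = 0
    for i in range(2, n):
        u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
        w = g[u][v]["length"]
        g.remove_edge(u, v)
        mid = f"I{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, length=w * split)
        g.add_edge(mid, v, length=w * (1 - split))
        g.add_edge(mid, f"L{i}", length=float(rng.uniform(0.1, 1.0)))
    ids = [f"L{i}" for i in range(n)]
    dist = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = lengths[ids[i]][ids[j]]
    return ids, dist


def nj_path_error(ids, dist):
    tree = phylo.neighbor_joining(ids, dist)
    labels, paths = phylo.tree_path_lengths(tree)
    order = [labels.index(x) for x in ids]
    return np.max(np.abs(paths[np.ix_(order, order)] - dist))


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        # additive matrix with an (A,B) cherry; path lengths must match input
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 4], [6, 6, 4, 0]], float
        )
        tree = phylo.neighbor_joining(ids, d)
        assert nj_path_error(ids, d) < 1e-12
        # A and B form a cherry: their path has exactly one internal node
        taxa = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        assert taxa["A"].parent_node is taxa["B"].parent_node

    def test_three_taxon_closed_form(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = phylo.neighbor_joining(ids, d)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(["A", "B"], np.zeros((2, 2)))

    def test_recovers_additive_metrics(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ids, dist = random_additive_instance(rng, int(rng.integers(4, 9)))
            assert nj_path_error(ids, dist) < 1e-9

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(1)
        ids, dist = random_additive_instance(rng, 7)
        _, paths_a = phylo.tree_path_lengths(phylo.neighbor_joining(ids, dist))
        perm = rng.permutation(len(ids))
        ids_p = [ids[i] for i in perm]
        dist_p = dist[np.ix_(perm, perm)]
        _, paths_b = phylo.tree_path_lengths(phylo.neighbor_joining(ids_p, dist_p))
        np.testing.assert_allclose(paths_a, paths_b, atol=1e-9)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(2)
        # non-additive noise can drive raw NJ lengths negative; they are clamped
        for _ in range(10):
            n = 6
            noise = rng.uniform(0, 1, (n, n))
            d = (noise + noise.T) / 2
            np.fill_diagonal(d, 0)
            tree = phylo.neighbor_joining([f"t{i}" for i in range(n)], d)
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0

    def test_agrees_with_independent_nj_oracle(self):
        # scikit-bio's neighbor joining as a cross-check on additive inputs
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        for _ in range(5):
            ids, dist = random_additive_instance(rng, 7)
            mine = phylo.neighbor_joining(ids, dist)
            _, paths_mine = phylo.tree_path_lengths(mine)
            other = skbio_nj(DistanceMatrix(dist, ids=ids))
            labels = sorted(ids)
            paths_other = np.zeros_like(dist)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        d_ab = other.find(a).distance(other.find(b))
                        paths_other[i, j] = paths_other[j, i] = d_ab
            np.testing.assert_allclose(paths_mine, paths_other, atol=1e-9)


class TestDistanceMatrix:
    def test_identical_sequences_distance_zero(self):
        ids, d = phylo.build_distance_matrix({"a": "MKLV" * 20, "b": "MKLV" * 20})
        assert d[0, 1] == 0.0

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = {f"s{i}": "".join(rng.choice(aas, size=80)) for i in range(8)}
        _, d = phylo.build_distance_matrix(seqs)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all((d >= 0) & (d <= 1))

    def test_within_family_closer_than_between(self):
        from rlpscape import simulate

        rng = np.random.default_rng(5)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        fa = "".join(rng.choice(aas, size=120))
        fb = "".join(rng.choice(aas, size=120))
        seqs = {"a0": fa, "b0": fb}
        for i in range(1, 3):
            seqs[f"a{i}"] = simulate.mutate_protein(fa, fraction=0.1, rng=rng)
            seqs[f"b{i}"] = simulate.mutate_protein(fb, fraction=0.1, rng=rng)
        ids, d = phylo.build_distance_matrix(seqs)
        idx = {x: i for i, x in enumerate(ids)}
        within = [d[idx["a0"], idx["a1"]], d[idx["b0"], idx["b2"]]]
        between = [d[idx["a0"], idx["b0"]], d[idx["a1"], idx["b1"]]]
        assert max(within) < min(between)


class TestConcordance:
    def _cluster_tree(self):
        rng = np.random.default_rng(6)
        ids, dist = random_additive_instance(rng, 8)
        return phylo.neighbor_joining(ids, dist), ids

    def test_perfect_concordance_is_1(self):
        tree, ids = self._cluster_tree()
        clades = phylo.cut_clades(tree, 3)
        locations = {x: f"locus{c}" for x, c in clades.items()}
        assert phylo.clade_locus_concordance(tree, locations, k=3) == pytest.approx(1.0)

    def test_random_labels_score_near_zero(self):
        tree, ids = self._cluster_tree()
        rng = np.random.default_rng(7)
        scores = []
        for _ in range(100):
            labels = rng.integers(0, 3, size=len(ids))
            locations = {x: f"l{labels[i]}" for i, x in enumerate(ids)}
            scores.append(phylo.clade_locus_concordance(tree, locations, k=3))
        assert abs(np.mean(scores)) <= 0.1
        assert all(-1.0 <= s <= 1.0 for s in scores)

    def test_twin_chromosome_scenario_high_concordance(self, default_bundle):
        # a 96%-identity twin duplication is more recent than within-cluster
        # divergence, so each receptor's closest relative is its copy on the
        # twin chromosome and the two clusters form one mixed clade -- the
        # same pattern the twin chromosomes show in real data.  Labelling the
        # copy by its duplication lineage, clades and loci should agree.
        genome, truth = default_bundle
        anns = lrr.annotate_proteome(
            {r: genome.proteins[r] for r in truth.receptor_ids}
        )
        clustered = {m for c in truth.clusters for m in c["members"]}
        c3d = {r: a.c3d_seq for r, a in anns.items()
               if r in clustered and a.c3d_seq}
        ids, dist = phylo.build_distance_matrix(c3d)
        tree = phylo.neighbor_joining(ids, dist)
        lineage = {
            c["cluster_id"]: c["cluster_id"] for c in truth.clusters
        }
        lineage[truth.twin["copy_cluster"]] = truth.twin["source_cluster"]
        locations = {
            m: lineage[c["cluster_id"]]
            for c in truth.clusters
            for m in c["members"]
        }
        k = len(set(lineage.values())) + 1
        ari = phylo.clade_locus_concordance(tree, locations, k=k)
        assert ari >= 0.8

    def test_cut_respects_k(self):
        tree, ids = self._cluster_tree()
        for k in (1, 2, 3, 4):
            clades = phylo.cut_clades(tree, k)
            assert len(set(clades.values())) <= k
            assert sorted(clades) == sorted(ids)
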