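"""Phylogeny of the conserved C3–D receptor region vs. genomic location.

Receptor trees are built from the concatenated C3 (conserved C-terminal LRR
block) and D (juxtamembrane linker) domains — the only part of an LRR-RLP
alignable across the whole family.  Pairwise global-alignment identities give
a distance matrix (d = 1 - identity/100); the tree is canonical
neighbor-joining (Saitou–Nei Q-criterion with standard branch-length
formulas, ties broken by the smallest index pair).  Agreement between tree
clades and genomic location (cluster or chromosome membership) is quantified
with the adjusted Rand index after cutting the tree at its longest internal
branches.
"""

from __future__ import annotations

import dendropy
import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .spuf import pairwise_identity


def build_distance_matrix(c3d_seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """All-pairs identity distances between C3–D sequences.

    Returns the taxon ids (insertion order) and a symmetric matrix with
    ``d = 1 - identity/100`` and a zero diagonal.
    """
    ids = list(c3d_seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(c3d_seqs[ids[i]], c3d_seqs[ids[j]])
            d[i, j] = d[j, i] = 1.0 - pid / 100.0
    return ids, d


def neighbor_joining(ids: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Canonical neighbor-joining on a distance matrix.

    Implements the Saitou–Nei agglomeration: at each step the pair (i, j)
    minimizing ``Q(i,j) = (m - 2) d(i,j) - r_i - r_j`` is joined, with branch
    lengths ``l_i = d(i,j)/2 + (r_i - r_j) / (2 (m - 2))`` and the new node's
    distances ``d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2``.  Ties are broken
    by the smallest (i, j) index pair in the current matrix; negative branch
    lengths are clamped to zero.  The result is an unrooted tree (trifurcating
    seed node) with the input ids as leaf labels.
    """
    n = len(ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    taxa = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = []
    for name in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    # working distance store: full matrix over ever-created nodes
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dist
    active = list(range(n))
    next_idx = n

    def _join(i_pos: int, j_pos: int, li: float, lj: float) -> int:
        nonlocal next_idx
        i, j = active[i_pos], active[j_pos]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        nodes.append(parent)
        u = next_idx
        next_idx += 1
        for k_pos, k in enumerate(active):
            if k_pos in (i_pos, j_pos):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        # drop j first so i_pos stays valid
        for pos in sorted((i_pos, j_pos), reverse=True):
            del active[pos]
        active.append(u)
        return u

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-15:
                    best = (q, a, b)
        _, a, b = best
        dij = sub[a, b]
        la = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lb = dij - la
        _join(a, b, la, lb)

    # terminal three-taxon star with closed-form branch lengths
    i, j, k = active
    center = dendropy.Node()
    for x, y, z in ((i, j, k), (j, i, k), (k, i, j)):
        lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
        center.add_child(nodes[x])
        nodes[x].edge.length = max(0.0, lx)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return tree


def tree_path_lengths(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf patristic distances, sorted by taxon label."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return [t.label for t in taxa], out


def _leaf_labels_below(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def cut_clades(tree: dendropy.Tree, k: int) -> dict[str, int]:
    """Partition leaves into (up to) ``k`` clades.

    Removes the ``k - 1`` longest internal branches (longest first; ties
    broken by the lexicographically smallest leaf set below the branch) and
    labels the resulting leaf groups 0..k-1 in order of their smallest leaf.
    A tree with fewer internal branches yields fewer clades.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    internal = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            length = node.edge.length or 0.0
            internal.append((-length, sorted(_leaf_labels_below(node))[0], node))
    internal.sort(key=lambda t: (t[0], t[1]))
    removed = {id(node) for _, _, node in internal[: k - 1]}
    graph = nx.Graph()
    for node in tree.preorder_node_iter():
        graph.add_node(id(node))
        if node.parent_node is not None and id(node) not in removed:
            graph.add_edge(id(node.parent_node), id(node))
        elif node.parent_node is not None:
            graph.add_node(id(node.parent_node))
    leaves = {id(leaf): leaf.taxon.label for leaf in tree.leaf_node_iter()}
    groups: list[list[str]] = []
    for comp in nx.connected_components(graph):
        labels = sorted(leaves[nid] for nid in comp if nid in leaves)
        if labels:
            groups.append(labels)
    groups.sort(key=lambda g: g[0])
    return {label: gi for gi, group in enumerate(groups) for label in group}


def clade_locus_concordance(
    tree: dendropy.Tree, locations: dict[str, str], k: int = 4
) -> float:
    """Adjusted Rand index between tree clades and genomic-location labels.

    ``locations`` maps leaf labels to a location label (cluster id or
    chromosome); leaves without a location are ignored.  The score lies in
    [-1, 1]; 1 means clades coincide exactly with loci, 0 is chance level.
    """
    clades = cut_clades(tree, k)
    shared = sorted(set(clades) & set(locations))
    if len(shared) < 2:
        raise ValueError("need at least 2 leaves with locations")
    return float(
        adjusted_rand_score(
            [locations[x] for x in shared], [clades[x] for x in shared]
        )
    )


__all__ = [
    "build_distance_matrix",
    "neighbor_joining",
    "tree_path_lengths",
    "cut_clades",
    "clade_locus_concordance",
]
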