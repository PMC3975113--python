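"""Cluster/super-cluster calling and vicinity association vs. brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlpscape.clusters import (
    call_clusters,
    call_superclusters,
    collect_associated,
    summarize_architecture,
)
from rlpscape.model import GeneModel, Genome


def _receptors(gaps, chrom="chr1", start=100_000, length=2_000):
    """Receptor gene models separated by the given end-to-start gaps."""
    genes = []
    pos = start
    for i, gap in enumerate([0] + list(gaps)):
        pos += gap
        genes.append(GeneModel(f"r{i}", chrom, "+", pos, pos + length))
        pos += length
    return genes


def _brute_force_clusters(genes, gap_max):
    """O(n^2) transitive closure of the pairwise gap relation (union-find)."""
    parent = list(range(len(genes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(genes):
        for j, b in enumerate(genes):
            if i >= j or a.chrom != b.chrom:
                continue
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            if hi.start - lo.end <= gap_max:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(genes)):
        groups.setdefault(find(i), set()).add(genes[i].gene_id)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


class TestCallClusters:
    def test_all_gaps_within_bound_one_cluster(self):
        clusters, singles = call_clusters(_receptors([10_000, 49_000]))
        assert len(clusters) == 1 and len(clusters[0]) == 3 and not singles

    def test_gap_above_bound_splits(self):
        clusters, singles = call_clusters(_receptors([10_000, 51_000]))
        assert len(clusters) == 1 and len(clusters[0]) == 2
        assert singles == ["r2"]

    def test_boundary_gap_exactly_50kb_is_included(self):
        clusters, singles = call_clusters(_receptors([50_000]))
        assert len(clusters) == 1 and not singles

    def test_every_receptor_clustered_or_singleton(self):
        rng = np.random.default_rng(0)
        genes = _random_layout(rng, n=40)
        clusters, singles = call_clusters(genes)
        members = [m for c in clusters for m in c.members] + singles
        assert sorted(members) == sorted(g.gene_id for g in genes)

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            genes = _random_layout(rng, n=int(rng.integers(5, 40)))
            clusters, _ = call_clusters(genes, cluster_gap_max=50_000)
            got = {frozenset(c.members) for c in clusters}
            assert got == _brute_force_clusters(genes, 50_000)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        genes = _random_layout(rng, n=25)
        a, _ = call_clusters(genes)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        b, _ = call_clusters(shuffled)
        assert [c.members for c in a] == [c.members for c in b]


def _random_layout(rng, n=20, chroms=("chr1", "chr2"), span=1_500_000):
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        genes.append(GeneModel(f"g{i}", chrom, "+", start, start + int(rng.integers(500, 4000))))
    # drop overlapping genes to keep the layout well-formed
    genes.sort(key=lambda g: (g.chrom, g.start))
    kept = []
    for g in genes:
        if kept and kept[-1].chrom == g.chrom and g.start < kept[-1].end:
            continue
        kept.append(g)
    return kept


@given(st.lists(st.integers(min_value=0, max_value=120_000), min_size=1, max_size=15))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_chaining_equals_transitive_closure_for_any_gaps(gaps):
    genes = _receptors(gaps)
    clusters, singles = call_clusters(genes)
    assert {frozenset(c.members) for c in clusters} == _brute_force_clusters(
        genes, 50_000
    )
    members = [m for c in clusters for m in c.members] + singles
    assert sorted(members) == sorted(g.gene_id for g in genes)


class TestSuperClusters:
    def _two_clusters(self, gap):
        c1, _ = call_clusters(_receptors([10_000]))
        genes2 = _receptors([10_000], start=100_000 + 2 * 2_000 + 10_000 + gap)
        genes2 = [GeneModel(f"s{g.gene_id}", g.chrom, "+", g.start, g.end) for g in genes2]
        c2, _ = call_clusters(genes2)
        # renumber to keep ids unique
        c2[0].cluster_id = "C2"
        return c1 + c2

    def test_below_2mb_joins(self):
        supers = call_superclusters(self._two_clusters(1_500_000))
        assert len(supers) == 1 and supers[0].cluster_ids == ["C1", "C2"]

    def test_exactly_2mb_is_excluded(self):
        assert call_superclusters(self._two_clusters(2_000_000)) == []

    def test_just_below_2mb_is_included(self):
        assert len(call_superclusters(self._two_clusters(1_999_999))) == 1


class TestAssociation:
    def _genome(self, gene_positions):
        genes = [GeneModel("r0", "chr1", "+", 100_000, 102_000)]
        for i, (s, e) in enumerate(gene_positions):
            genes.append(GeneModel(f"g{i}", "chr1", "+", s, e))
        return Genome(chromosomes={"chr1": 1_000_000}, genes=genes)

    def test_gene_at_24999_bp_is_associated(self):
        genome = self._genome([(74_001, 75_001)])  # ends 24,999 bp before r0
        table = collect_associated(genome, ["r0"])
        assert {g for g, _ in table.per_receptor["r0"]} == {"g0"}
        assert table.per_receptor["r0"][0][1] == -24_999

    def test_gene_at_25001_bp_is_not_associated(self):
        genome = self._genome([(73_999, 74_999)])
        assert collect_associated(genome, ["r0"]).union == set()

    def test_boundary_25000_excluded_half_open(self):
        genome = self._genome([(74_000, 75_000)])
        assert collect_associated(genome, ["r0"]).union == set()

    def test_receptors_never_associated(self):
        genes = [
            GeneModel("r0", "chr1", "+", 100_000, 102_000),
            GeneModel("r1", "chr1", "+", 110_000, 112_000),
            GeneModel("g0", "chr1", "+", 104_000, 105_000),
        ]
        genome = Genome(chromosomes={"chr1": 1_000_000}, genes=genes)
        table = collect_associated(genome, ["r0", "r1"])
        assert table.union == {"g0"}

    def test_negative_window_rejected(self):
        genome = self._genome([])
        with pytest.raises(ValueError):
            collect_associated(genome, ["r0"], window=-1)

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            genes = _random_layout(rng, n=int(rng.integers(10, 50)))
            receptor_ids = {g.gene_id for g in genes if rng.random() < 0.2}
            if not receptor_ids:
                receptor_ids = {genes[0].gene_id}
            chroms = {c: 2_000_000 for c in {g.chrom for g in genes}}
            genome = Genome(chromosomes=chroms, genes=list(genes))
            table = collect_associated(genome, receptor_ids, window=25_000)
            for rid in receptor_ids:
                r = genome.gene_index()[rid]
                oracle = {
                    g.gene_id
                    for g in genes
                    if g.gene_id not in receptor_ids
                    and g.chrom == r.chrom
                    and g.start < r.end + 25_000
                    and g.end > r.start - 25_000
                }
                assert {g for g, _ in table.per_receptor[rid]} == oracle

    def test_multiplicity_at_least_union(self, default_bundle):
        genome, truth = default_bundle
        table = collect_associated(genome, truth.receptor_ids)
        total = sum(len(h) for h in table.per_receptor.values())
        assert total >= len(table.union)


class TestSummarize:
    def test_zero_clusters_no_division_error(self):
        report = summarize_architecture([], [], [], [])
        assert report["pct_clustered"] == 0.0
        assert report["pct_top_units"] == 0.0

    def test_counts_match_planted_truth(self, default_bundle):
        genome, truth = default_bundle
        index = genome.gene_index()
        receptors = [index[r] for r in truth.receptor_ids]
        clusters, singles = call_clusters(receptors)
        supers = call_superclusters(clusters)
        got = {frozenset(c.members) for c in clusters}
        want = {frozenset(c["members"]) for c in truth.clusters}
        assert got == want
        assert sorted(singles) == sorted(truth.singleton_receptor_ids)
        assert len(supers) == len(truth.superclusters)
        report = summarize_architecture(
            truth.receptor_ids, clusters, supers, singles
        )
        n_clustered = sum(len(c["members"]) for c in truth.clusters)
        assert report["n_clustered"] == n_clustered
        assert report["n_clusters"] == len(truth.clusters)
        assert report["pct_clustered"] == pytest.approx(
            round(100 * n_clustered / len(truth.receptor_ids), 1)
        )
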