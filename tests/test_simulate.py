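"""Synthetic-genome generator: determinism, planted structure, expression."""

import numpy as np
import pytest

from rlpscape import io as rio
from rlpscape import lrr, simulate
from rlpscape.simulate import (
    ChromosomePlan,
    ClusterSpec,
    GenomeParams,
    ParameterError,
    make_expression,
    make_genome,
    mutate_protein,
)


class TestDeterminism:
    def test_same_seed_same_genome(self):
        params = GenomeParams.small()
        g1, t1 = make_genome(params, seed=42)
        g2, t2 = make_genome(GenomeParams.small(), seed=42)
        assert g1.genes == g2.genes
        assert g1.proteins == g2.proteins
        assert g1.genomic_seq == g2.genomic_seq
        assert t1 == t2

    def test_different_seed_different_genome(self):
        g1, _ = make_genome(GenomeParams.small(), seed=1)
        g2, _ = make_genome(GenomeParams.small(), seed=2)
        assert g1.genomic_seq != g2.genomic_seq

    def test_bundle_files_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            g, t = make_genome(GenomeParams.small(), seed=3)
            simulate.write_bundle(g, t, tmp_path / sub)
        for name in ("genome.gff3", "proteins.fasta", "annotation.tsv",
                     "expression_wounded.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestPlantedStructure:
    def test_truth_ids_exist_in_genome(self, default_bundle):
        genome, truth = default_bundle
        ids = {g.gene_id for g in genome.genes}
        planted = (
            set(truth.receptor_ids)
            | set(truth.spuf_ids)
            | set(truth.truncated_lrr_ids)
            | {m for c in truth.clusters for m in c["members"]}
        )
        assert planted <= ids

    def test_planted_gaps_respected_exactly(self, default_bundle):
        genome, truth = default_bundle
        index = genome.gene_index()
        for cluster in truth.clusters:
            members = [index[m] for m in cluster["members"]]
            for a, b in zip(members, members[1:]):
                assert b.start - a.end == cluster["intra_gap"]

    def test_single_cluster_spec(self):
        params = GenomeParams(
            chromosomes=[ChromosomePlan(
                length=500_000, clusters=[ClusterSpec(4, intra_gap=10_000)],
                cluster_gaps=[50_000], n_filler=0, n_background_spuf=0,
            )],
            twin=None, spuf_families=[], promoter_block=None,
        )
        _, truth = make_genome(params, seed=0)
        assert len(truth.clusters) == 1
        assert len(truth.clusters[0]["members"]) == 4

    def test_two_clusters_below_2mb_form_supercluster(self):
        params = GenomeParams(
            chromosomes=[ChromosomePlan(
                length=2_500_000,
                clusters=[ClusterSpec(3), ClusterSpec(3)],
                cluster_gaps=[50_000, 1_500_000],
                n_filler=0, n_background_spuf=0,
            )],
            twin=None, spuf_families=[], promoter_block=None,
        )
        _, truth = make_genome(params, seed=0)
        assert len(truth.superclusters) == 1
        assert truth.superclusters[0]["clusters"] == ["C1", "C2"]

    def test_spuf_proteins_are_small_and_unannotated(self, default_bundle):
        genome, truth = default_bundle
        index = genome.gene_index()
        for sid in truth.spuf_ids:
            g = index[sid]
            assert g.protein_length < 200
            assert g.description == ""
            assert g.domain_hits == []

    def test_twin_cluster_identity(self, default_bundle):
        from rlpscape.spuf import pairwise_identity

        genome, truth = default_bundle
        for a, b in truth.twin["receptor_pairs"]:
            pid = pairwise_identity(genome.proteins[a], genome.proteins[b])
            # members diverge from their founders on top of the twin copy
            assert pid > 80.0

    def test_placement_overflow_raises(self):
        params = GenomeParams(
            chromosomes=[ChromosomePlan(
                length=30_000, clusters=[ClusterSpec(4)], cluster_gaps=[1_000],
                n_filler=0, n_background_spuf=0,
            )],
            twin=None, spuf_families=[], promoter_block=None,
        )
        with pytest.raises(ParameterError):
            make_genome(params, seed=0)

    def test_receptor_verdict_mostly_true_under_default_noise(self):
        ok = 0
        for seed in range(20):
            seq = simulate.make_receptor_protein(17, seed=seed, p_sub=0.15)
            ok += lrr.annotate_protein("g", seq).is_lrr_rlp
        assert ok >= 19

    def test_conserved_block_planted_between_designated_pair(self, default_bundle):
        from rlpscape.promoter import extract_promoter

        genome, truth = default_bundle
        block = truth.conserved_block
        pa = extract_promoter(genome, block["gene_a"], 1000)
        pb = extract_promoter(genome, block["gene_b"], 1000)
        rel = 1000 + block["offset"]
        a = np.frombuffer(pa[rel : rel + block["length"]].encode(), dtype=np.uint8)
        b = np.frombuffer(pb[rel : rel + block["length"]].encode(), dtype=np.uint8)
        ident = 100.0 * (a == b).mean()
        assert ident == pytest.approx(block["identity"], abs=1e-9)


class TestMutateProtein:
    def test_exact_fraction_of_positions_changed(self):
        seq = "A" * 200
        out = mutate_protein(seq, fraction=0.37, seed=1)
        assert sum(a != b for a, b in zip(seq, out)) == 74

    def test_protected_region_untouched(self):
        seq = "A" * 100
        out = mutate_protein(seq, n_mut=50, seed=2, protect_end=30)
        assert out[:30] == seq[:30]


class TestExpression:
    def test_noiseless_fold_change_exact(self, default_bundle):
        genome, truth = default_bundle
        nw, w = make_expression(genome, truth, noise_sd=0.0)
        for gid, fc in truth.inductions.items():
            measured = w.loc[gid].mean() / nw.loc[gid].mean()
            assert measured == pytest.approx(fc, rel=1e-12)

    def test_mean_ratio_unbiased_under_noise(self, default_bundle):
        genome, truth = default_bundle
        gid = next(g for g, fc in truth.inductions.items() if fc == 10.0)
        estimates = []
        for seed in range(30):
            nw, w = make_expression(genome, truth, noise_sd=0.2, seed=seed)
            estimates.append(w.loc[gid].mean() / nw.loc[gid].mean())
        assert 9.0 <= np.mean(estimates) <= 11.0

    def test_null_genes_have_small_fold_changes(self, default_bundle):
        genome, truth = default_bundle
        nw, w = make_expression(genome, truth, noise_sd=0.1, seed=0)
        null = [g.gene_id for g in genome.genes if g.gene_id not in truth.inductions]
        log2fc = np.log2(w.loc[null].mean(axis=1) / nw.loc[null].mean(axis=1))
        assert (np.abs(log2fc) < 0.5).mean() >= 0.95

    def test_matrices_have_requested_conditions(self, default_bundle):
        genome, truth = default_bundle
        nw, w = make_expression(genome, truth, n_cond=4)
        assert nw.shape == w.shape == (len(genome.genes), 4)

    def test_written_matrix_roundtrips(self, tmp_path, small_bundle):
        genome, truth = small_bundle
        nw, _ = make_expression(genome, truth, noise_sd=0.2)
        rio.write_expression(nw, tmp_path / "nw.tsv")
        assert rio.read_expression(tmp_path / "nw.tsv").equals(nw)
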