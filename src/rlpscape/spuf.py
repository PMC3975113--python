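"""SPUF classification, secretion, paralog families, and enrichment.

A SPUF (small protein of unknown function) is a protein shorter than 200
amino acids whose gene carries no functional annotation and no recognized
protein-domain hit.  Secretion is predicted from the same rule-based
signal-peptide heuristic the receptor annotation uses.  Paralogy is scored by
Smith–Waterman local alignment (BLOSUM62, affine gaps 11/1) with a
length-normalized score cut-off — a desk-scale emulation of a stringent
Blastp E-value threshold; the exact Karlin–Altschul calibration is out of
scope and this cut is documented as an approximation.  Enrichment of SPUFs in
receptor neighborhoods is assessed with a permutation test (an addition on
top of the raw percentages, and flagged as such in the report).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from intervaltree import IntervalTree

from .clusters import Cluster, SuperCluster, architecture_units, collect_associated
from .lrr import detect_signal_peptide, scan_lrr_repeats
from .model import GeneModel, Genome, normalize_description

#: descriptions treated as "no annotation" (normalized form)
UNKNOWN_DESCRIPTIONS = frozenset({"", "unknown", "hypothetical protein", "expressed protein"})


@dataclass
class SpufRecord:
    gene_id: str
    protein_length: int
    is_spuf: bool
    secreted: bool = False
    n_paralogs: int = 0
    n_homologs_other: int = 0
    family_id: str | None = None


@dataclass
class EnrichmentReport:
    pct_spuf_associated: float
    pct_spuf_genome: float
    pct_spuf_top_clusters_excl_receptors: float
    p_value: float
    n_perm: int
    seed: int
    note: str = (
        "permutation test is an addition beyond the raw percentages "
        "reported by the source analysis"
    )


def classify_spuf(
    gene: GeneModel,
    len_max: int = 200,
    unknown_descriptions: frozenset[str] = UNKNOWN_DESCRIPTIONS,
) -> bool:
    """SPUF verdict: protein strictly below ``len_max`` aa, an unknown/empty
    description, and no protein-domain hits."""
    if gene.protein_length is None or gene.protein_length >= len_max:
        return False
    if normalize_description(gene.description) not in unknown_descriptions:
        return False
    return not gene.domain_hits


def predict_secreted(seq: str) -> bool:
    """Secretion flag: true iff an N-terminal signal peptide is detected."""
    return detect_signal_peptide(seq) is not None


_B62 = substitution_matrices.load("BLOSUM62")


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = _B62
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = _B62
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    # end gaps are free: identity is computed over the aligned core only
    a.open_end_insertion_score = 0.0
    a.extend_end_insertion_score = 0.0
    a.open_end_deletion_score = 0.0
    a.extend_end_deletion_score = 0.0
    return a


def sw_score(seq_a: str, seq_b: str) -> float:
    """Smith–Waterman local alignment score (BLOSUM62, gaps 11/1)."""
    return float(_local_aligner().score(seq_a, seq_b))


def is_paralog_pair(seq_a: str, seq_b: str, score_min: float = 1.0) -> bool:
    """Length-normalized paralogy call: SW score / min(length) >= cut-off."""
    return sw_score(seq_a, seq_b) / min(len(seq_a), len(seq_b)) >= score_min


def find_paralogs(
    proteome: dict[str, str],
    query_ids: list[str],
    score_min: float = 1.0,
) -> tuple[dict[str, int], list[set[str]]]:
    """Count paralogs of each query in a proteome and group paralog families.

    A pair is paralogous iff its length-normalized Smith–Waterman score
    reaches ``score_min``.  Returns ``(counts, families)`` where ``counts``
    maps each query to its number of paralogs among all other proteome
    entries, and ``families`` are the connected components of the paralogy
    graph restricted to the queries (singleton queries are size-1 families).
    """
    if not proteome:
        raise ValueError("empty proteome")
    aligner = _local_aligner()
    counts: dict[str, int] = {}
    graph = nx.Graph()
    graph.add_nodes_from(query_ids)
    query_set = set(query_ids)
    for qid in query_ids:
        q = proteome[qid]
        n = 0
        for tid, t in proteome.items():
            if tid == qid:
                continue
            score = float(aligner.score(q, t))
            if score / min(len(q), len(t)) >= score_min:
                n += 1
                if tid in query_set and qid < tid:
                    graph.add_edge(qid, tid)
        counts[qid] = n
    families = [set(c) for c in nx.connected_components(graph)]
    families.sort(key=lambda s: sorted(s)[0])
    return counts, families


def count_homologs(
    query_seqs: dict[str, str],
    other_proteome: dict[str, str],
    score_min: float = 1.0,
) -> dict[str, int]:
    """Hits of each query in another species' proteome (same score cut)."""
    aligner = _local_aligner()
    out: dict[str, int] = {}
    for qid, q in query_seqs.items():
        n = 0
        for t in other_proteome.values():
            if float(aligner.score(q, t)) / min(len(q), len(t)) >= score_min:
                n += 1
        out[qid] = n
    return out


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent amino-acid identity from a global alignment.

    Identity is matches over alignment columns, excluding columns in the
    leading/trailing end-gap regions; end gaps are free in the alignment.
    """
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    n = len(row_a)
    lo = 0
    while lo < n and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if row_a[i] == row_b[i] and row_a[i] != "-")
    return 100.0 * matches / (hi - lo)


def tag_truncated_lrr(
    proteins: dict[str, str],
    receptor_ids: set[str],
    score_min: float = 10.0,
    min_repeats: int = 1,
    max_repeats: int = 15,
) -> set[str]:
    """Genes encoding a restricted number of LRR domains (1-15 repeats).

    These receptor-like relics are reported as a class of their own; no
    receptor verdict is attached to them.
    """
    tagged: set[str] = set()
    for gid, seq in proteins.items():
        if gid in receptor_ids:
            continue
        n = len(scan_lrr_repeats(seq, score_min=score_min))
        if min_repeats <= n <= max_repeats:
            tagged.add(gid)
    return tagged


def build_spuf_records(
    genome: Genome,
    receptor_ids: set[str],
    other_proteome: dict[str, str] | None = None,
    score_min: float = 1.0,
    len_max: int = 200,
) -> list[SpufRecord]:
    """Full SPUF table: verdicts, secretion flags, paralog counts, families."""
    records: list[SpufRecord] = []
    spuf_ids: list[str] = []
    for g in genome.genes:
        if g.gene_id in receptor_ids or g.protein_length is None:
            continue
        is_spuf = classify_spuf(g, len_max=len_max)
        if is_spuf:
            spuf_ids.append(g.gene_id)
    counts, families = find_paralogs(genome.proteins, spuf_ids, score_min=score_min)
    family_of: dict[str, str] = {}
    for k, fam in enumerate(families, start=1):
        if len(fam) > 1:
            for gid in fam:
                family_of[gid] = f"F{k}"
    homologs = (
        count_homologs({gid: genome.proteins[gid] for gid in spuf_ids},
                       other_proteome, score_min=score_min)
        if other_proteome
        else {}
    )
    for gid in spuf_ids:
        seq = genome.proteins[gid]
        records.append(
            SpufRecord(
                gene_id=gid,
                protein_length=len(seq),
                is_spuf=True,
                secreted=predict_secreted(seq),
                n_paralogs=counts[gid],
                n_homologs_other=homologs.get(gid, 0),
                family_id=family_of.get(gid),
            )
        )
    return records


def enrichment(
    genome: Genome,
    receptor_ids: set[str] | list[str],
    spuf_ids: set[str] | list[str],
    clusters: list[Cluster] | None = None,
    superclusters: list[SuperCluster] | None = None,
    window: int = 25_000,
    top_k: int = 9,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentReport:
    """SPUF share of receptor neighborhoods vs. the genome background.

    * ``pct_spuf_associated``: SPUFs as a percentage of all receptor-
      associated genes (deduplicated union).
    * ``pct_spuf_genome``: SPUFs as a percentage of all non-receptor genes.
    * ``pct_spuf_top_clusters_excl_receptors``: SPUF share of the gene
      content of the ``top_k`` largest clusters/super-clusters, receptors
      themselves not counted.
    * ``p_value``: permutation null that relabels the receptor anchors
      uniformly among all gene positions and recomputes the associated-SPUF
      percentage; ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    receptor_set = set(receptor_ids)
    spuf_set = set(spuf_ids)
    table = collect_associated(genome, receptor_set, window=window)
    associated = table.union

    def pct_spuf(assoc: set[str]) -> float:
        if not assoc:
            return 0.0
        return 100.0 * len(assoc & spuf_set) / len(assoc)

    if not associated:
        warnings.warn("no associated genes; SPUF percentage defined as 0")
    obs = pct_spuf(associated)
    n_non_receptor = sum(1 for g in genome.genes if g.gene_id not in receptor_set)
    pct_genome = 100.0 * len(spuf_set) / n_non_receptor if n_non_receptor else 0.0

    pct_top = 0.0
    if clusters:
        units = architecture_units(clusters, superclusters or [])
        units.sort(key=lambda u: (-len(u[1]), u[0]))
        member_ids = {m for _, members in units[:top_k] for m in members}
        content: set[str] = set()
        for rid in member_ids:
            content.update(gid for gid, _ in table.per_receptor.get(rid, []))
        pct_top = pct_spuf(content)

    # permutation null: relabel the receptor anchors uniformly among all gene
    # positions; the gene layout is fixed, so one interval tree serves every
    # permutation
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    genes = genome.genes
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree())[g.start : g.end] = i
    k = len(receptor_set)
    exceed = 0
    for _ in range(n_perm):
        anchor_idx = rng.choice(len(genes), size=k, replace=False)
        anchor_set = set(int(i) for i in anchor_idx)
        assoc_idx: set[int] = set()
        for i in anchor_set:
            a = genes[i]
            for iv in trees[a.chrom].overlap(a.start - window, a.end + window):
                assoc_idx.add(iv.data)
        assoc_idx -= anchor_set
        perm_assoc = {genes[i].gene_id for i in assoc_idx}
        if pct_spuf(perm_assoc) >= obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return EnrichmentReport(
        pct_spuf_associated=obs,
        pct_spuf_genome=pct_genome,
        pct_spuf_top_clusters_excl_receptors=pct_top,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


__all__ = [
    "UNKNOWN_DESCRIPTIONS",
    "SpufRecord",
    "EnrichmentReport",
    "classify_spuf",
    "predict_secreted",
    "sw_score",
    "is_paralog_pair",
    "find_paralogs",
    "count_homologs",
    "pairwise_identity",
    "tag_truncated_lrr",
    "build_spuf_records",
    "enrichment",
]
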