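"""Receptor gene clusters, super-clusters, and vicinity-gene association.

A cluster is at least two receptor genes on one chromosome chained by
single linkage at end-to-start gaps of at most 50 kb ("within a 50 kb
stretch", bound included); a super-cluster is at least two clusters separated
by strictly less than 2 Mb.  An associated gene is any gene whose span
overlaps the window extending 25 kb upstream and downstream of a receptor
gene; receptors themselves are never counted as associated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .model import GeneModel, Genome


@dataclass
class Cluster:
    cluster_id: str
    chrom: str
    members: list[str]          # gene ids sorted by start
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SuperCluster:
    sc_id: str
    chrom: str
    cluster_ids: list[str]
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AssociationTable:
    """Per-receptor associated genes with signed distances, plus their union."""

    window: int
    per_receptor: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @property
    def union(self) -> set[str]:
        return {gid for hits in self.per_receptor.values() for gid, _ in hits}

    def counts(self) -> dict[str, int]:
        return {rid: len(hits) for rid, hits in self.per_receptor.items()}

    def mean_sd(self) -> tuple[float, float]:
        """Mean and SD of the per-receptor associated-gene counts."""
        counts = np.array(list(self.counts().values()), dtype=float)
        if counts.size == 0:
            return (0.0, 0.0)
        sd = counts.std(ddof=1) if counts.size > 1 else 0.0
        return (float(counts.mean()), float(sd))


def call_clusters(
    receptor_genes: list[GeneModel], cluster_gap_max: int = 50_000
) -> tuple[list[Cluster], list[str]]:
    """Chain receptors into clusters; returns (clusters, singleton ids).

    Consecutive receptors on a chromosome join one chain iff the boundary gap
    ``next.start - prev.end`` is at most ``cluster_gap_max`` (single linkage).
    Chains of two or more genes become clusters, numbered in (chrom, start)
    order; the rest are singletons.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(receptor_genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    clusters: list[Cluster] = []
    singletons: list[str] = []
    n = 0
    for chrom in sorted(by_chrom):
        chain: list[GeneModel] = []
        for g in by_chrom[chrom] + [None]:  # sentinel flushes the last chain
            if chain and (g is None or g.start - chain[-1].end > cluster_gap_max):
                if len(chain) >= 2:
                    n += 1
                    clusters.append(
                        Cluster(
                            cluster_id=f"C{n}",
                            chrom=chrom,
                            members=[m.gene_id for m in chain],
                            start=chain[0].start,
                            end=chain[-1].end,
                        )
                    )
                else:
                    singletons.append(chain[0].gene_id)
                chain = []
            if g is not None:
                chain.append(g)
    return clusters, singletons


def call_superclusters(
    clusters: list[Cluster], sc_gap_max: int = 2_000_000
) -> list[SuperCluster]:
    """Chain cluster spans into super-clusters at gaps strictly below the bound."""
    by_chrom: dict[str, list[Cluster]] = {}
    for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
        by_chrom.setdefault(c.chrom, []).append(c)
    supers: list[SuperCluster] = []
    n = 0
    for chrom in sorted(by_chrom):
        chain: list[Cluster] = []
        for c in by_chrom[chrom] + [None]:
            if chain and (c is None or c.start - chain[-1].end >= sc_gap_max):
                if len(chain) >= 2:
                    n += 1
                    supers.append(
                        SuperCluster(
                            sc_id=f"SC{n}",
                            chrom=chrom,
                            cluster_ids=[c2.cluster_id for c2 in chain],
                            start=chain[0].start,
                            end=chain[-1].end,
                        )
                    )
                chain = []
            if c is not None:
                chain.append(c)
    return supers


def collect_associated(
    genome: Genome,
    receptor_ids: set[str] | list[str],
    window: int = 25_000,
    window_overrides: dict[str, int] | None = None,
) -> AssociationTable:
    """Genes overlapping the padded window around each receptor.

    A gene is associated with a receptor iff its half-open span overlaps
    ``[receptor.start - w, receptor.end + w)``.  Receptors are excluded from
    every association list (associated genes are, by definition, the
    non-receptor gene content of receptor neighborhoods).  The signed
    distance is 0 for overlap, negative for genes upstream of the receptor
    start, positive for genes downstream of the receptor end.
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    window_overrides = window_overrides or {}
    receptor_set = set(receptor_ids)
    trees: dict[str, IntervalTree] = {}
    for g in genome.genes:
        trees.setdefault(g.chrom, IntervalTree())[g.start : g.end] = g.gene_id
    index = genome.gene_index()
    table = AssociationTable(window=window)
    for rid in sorted(receptor_set):
        r = index[rid]
        w = window_overrides.get(rid, window)
        hits: list[tuple[str, int]] = []
        for iv in trees[r.chrom].overlap(r.start - w, r.end + w):
            gid = iv.data
            if gid in receptor_set:
                continue
            g = index[gid]
            if g.end <= r.start:
                dist = g.end - r.start
            elif g.start >= r.end:
                dist = g.start - r.end
            else:
                dist = 0
            hits.append((gid, dist))
        hits.sort(key=lambda h: (h[1], h[0]))
        table.per_receptor[rid] = hits
    return table


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def architecture_units(
    clusters: list[Cluster], superclusters: list[SuperCluster]
) -> list[tuple[str, list[str]]]:
    """Top-level genomic units: super-clusters, plus clusters outside any.

    Returns ``(unit_id, member receptor ids)`` pairs; a super-cluster unit
    pools the receptors of its member clusters.
    """
    cluster_by_id = {c.cluster_id: c for c in clusters}
    in_sc = {cid for sc in superclusters for cid in sc.cluster_ids}
    units: list[tuple[str, list[str]]] = []
    for sc in superclusters:
        members = [m for cid in sc.cluster_ids for m in cluster_by_id[cid].members]
        units.append((sc.sc_id, members))
    for c in clusters:
        if c.cluster_id not in in_sc:
            units.append((c.cluster_id, list(c.members)))
    return units


def summarize_architecture(
    receptor_ids: list[str],
    clusters: list[Cluster],
    superclusters: list[SuperCluster],
    singletons: list[str] | None = None,
    top_k: int = 9,
) -> dict:
    """Family-level architecture report.

    ``pct_top_units`` is the share of the receptor family contained in the
    ``top_k`` largest clusters/super-clusters (super-clusters counted as one
    unit), mirroring the "nine largest clusters or super-clusters" summary
    statistic; the rounded value is reported as an integer percentage.
    """
    n_receptors = len(receptor_ids)
    n_clustered = sum(len(c) for c in clusters)
    units = architecture_units(clusters, superclusters)
    units.sort(key=lambda u: (-len(u[1]), u[0]))
    top = units[:top_k]
    n_top = sum(len(m) for _, m in top)
    pct = lambda n: 0.0 if n_receptors == 0 else 100.0 * n / n_receptors
    return {
        "n_receptors": n_receptors,
        "n_clustered": n_clustered,
        "n_clusters": len(clusters),
        "n_singletons": len(singletons) if singletons is not None else n_receptors - n_clustered,
        "n_superclusters": len(superclusters),
        "pct_clustered": _round_half_up(pct(n_clustered), 1),
        "cluster_sizes": {c.cluster_id: len(c) for c in clusters},
        "supercluster_sizes": {
            sc.sc_id: sum(len(c.members) for c in clusters if c.cluster_id in sc.cluster_ids)
            for sc in superclusters
        },
        "top_units": [{"unit_id": uid, "n_receptors": len(m)} for uid, m in top],
        "n_top_units_receptors": n_top,
        "pct_top_units": _round_half_up(pct(n_top), 1),
        "pct_top_units_rounded": int(_round_half_up(pct(n_top), 0)),
    }


__all__ = [
    "Cluster",
    "SuperCluster",
    "AssociationTable",
    "call_clusters",
    "call_superclusters",
    "collect_associated",
    "architecture_units",
    "summarize_architecture",
]
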