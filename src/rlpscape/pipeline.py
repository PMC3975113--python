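"""End-to-end orchestration: annotate -> cluster -> associate -> SPUF/enrich
-> phylogeny -> expression -> promoter, with a machine-readable summary.

Every numeric threshold of the analysis lives in :class:`PipelineConfig` and
is serialized (with a content hash) into every report for provenance.  The
summary JSON mirrors the family-table row structure: receptor and SPUF
counts, clustered receptors [number of clusters], SPUF percentages of the
associated set and of the proteome, secreted SPUFs, and the paralog-count
histogram.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import clusters as carch
from . import expression as expr
from . import io as rio
from . import lrr, phylo, spuf
from .model import Genome

SCHEMA_VERSION = 1


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10**ndigits
    return math.floor(x * scale + 0.5) / scale


def format_pct(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Percentage of ``numerator/denominator`` rounded half-up, as printed in
    the family table (e.g. ``format_pct(87, 375) == "23.2"``)."""
    if denominator == 0:
        return "-"
    value = _round_half_up(100.0 * numerator / denominator, decimals)
    return f"{value:.{decimals}f}" if decimals else str(int(value))


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline (units: bp, aa, intensity)."""

    cluster_gap_max: int = 50_000
    sc_gap_max: int = 2_000_000
    association_window: int = 25_000
    spuf_len_max: int = 200
    min_lrr: int = 15
    tail_max: int = 30
    lrr_score_min: float = 10.0
    island_min: int = 15
    paralog_score_min: float = 1.0
    background: float = 200.0
    pseudocount: float = 1.0
    low_max: float = 4_000.0
    high_max: float = 10_000.0
    slight_min: float = 1.5
    strong_min: float = 5.0
    promoter_length: int = 1_000
    promoter_window: int = 100
    promoter_step: int = 10
    promoter_min_identity: float = 85.0
    promoter_min_block: int = 200
    promoter_band: int = 50
    top_k: int = 9
    n_perm: int = 1_000
    phylo_k: int | None = None  # None: one clade per genomic cluster
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name in ("phylo_k", "seed") or value is None:
                continue
            if value <= 0:
                raise ValueError(f"config field {f.name} must be positive, got {value}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the config hash."""


@contextmanager
def _stage(name: str, config: PipelineConfig):
    try:
        yield
    except Exception as exc:
        raise PipelineError(
            f"stage {name!r} failed (config {config.hash()}): {exc}"
        ) from exc


def run_all(
    genome: Genome,
    config: PipelineConfig,
    outdir: str | os.PathLike,
    matrix_nonwounded: pd.DataFrame | None = None,
    matrix_wounded: pd.DataFrame | None = None,
    other_proteome: dict[str, str] | None = None,
) -> dict:
    """Run every stage in dependency order and return the summary dict.

    Each stage's outputs are written under ``outdir`` before the next stage
    starts.  Missing expression matrices skip the expression and promoter
    stages (flagged in the summary) without failing the run.
    """
    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(outdir, name)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": config.as_dict(),
        "config_hash": config.hash(),
        "n_genes": len(genome.genes),
    }

    # --- stage 1: receptor annotation -------------------------------------
    with _stage("annotate", config):
        annotations = lrr.annotate_proteome(
            genome.proteins,
            score_min=config.lrr_score_min,
            min_lrr=config.min_lrr,
            tail_max=config.tail_max,
            island_min=config.island_min,
        )
        receptor_ids = sorted(g for g, a in annotations.items() if a.is_lrr_rlp)
        rows = []
        for gid in sorted(annotations):
            a = annotations[gid]
            rows.append(
                {
                    "gene_id": gid,
                    "lrr_count": a.lrr_count,
                    "is_lrr_rlp": a.is_lrr_rlp,
                    "signal_peptide": _iv(a.signal_peptide),
                    "tm": _iv(a.tm),
                    "tail_len": a.cytoplasmic_tail_len,
                    "domains": ";".join(
                        f"{k}:{v[0]}-{v[1]}" for k, v in a.domains.items()
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(out("receptors.tsv"), sep="\t", index=False)
        c3d = {gid: annotations[gid].c3d_seq for gid in receptor_ids
               if annotations[gid].c3d_seq}
        if c3d:
            rio.write_fasta(c3d, out("c3d.fasta"))
        summary["lrr_rlp_genes"] = len(receptor_ids)

    # --- stage 2: clusters, super-clusters, association -------------------
    with _stage("architecture", config):
        index = genome.gene_index()
        receptor_genes = [index[g] for g in receptor_ids]
        cls, singletons = carch.call_clusters(
            receptor_genes, cluster_gap_max=config.cluster_gap_max
        )
        supers = carch.call_superclusters(cls, sc_gap_max=config.sc_gap_max)
        rio.write_bed(cls, out("clusters.bed"))
        rio.write_bed(supers, out("superclusters.bed"))
        association = carch.collect_associated(
            genome, receptor_ids, window=config.association_window
        )
        assoc_rows = [
            {"receptor": rid, "gene_id": gid, "distance": dist}
            for rid in sorted(association.per_receptor)
            for gid, dist in association.per_receptor[rid]
        ]
        pd.DataFrame(assoc_rows, columns=["receptor", "gene_id", "distance"]).to_csv(
            out("association.tsv"), sep="\t", index=False
        )
        arch = carch.summarize_architecture(
            receptor_ids, cls, supers, singletons, top_k=config.top_k
        )
        mean, sd = association.mean_sd()
        summary["architecture"] = arch
        summary["clustered"] = arch["n_clustered"]
        summary["n_clusters"] = arch["n_clusters"]
        summary["associated_genes"] = len(association.union)
        summary["associated_mean"] = mean
        summary["associated_sd"] = sd

    # --- stage 3: SPUFs and enrichment -------------------------------------
    with _stage("spuf", config):
        records = spuf.build_spuf_records(
            genome,
            set(receptor_ids),
            other_proteome=other_proteome,
            score_min=config.paralog_score_min,
            len_max=config.spuf_len_max,
        )
        spuf_ids = sorted(r.gene_id for r in records)
        truncated = spuf.tag_truncated_lrr(
            genome.proteins, set(receptor_ids), score_min=config.lrr_score_min
        )
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            out("spuf_records.tsv"), sep="\t", index=False
        )
        enr = spuf.enrichment(
            genome,
            receptor_ids,
            spuf_ids,
            clusters=cls,
            superclusters=supers,
            window=config.association_window,
            top_k=config.top_k,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        with open(out("enrichment.json"), "w") as fh:
            json.dump(dataclasses.asdict(enr), fh, indent=1, sort_keys=True)
        histogram: dict[str, int] = {}
        for r in records:
            histogram[str(r.n_paralogs)] = histogram.get(str(r.n_paralogs), 0) + 1
        summary["spuf_genes"] = len(spuf_ids)
        summary["spufs_secreted"] = sum(r.secreted for r in records)
        summary["spufs_no_paralog"] = sum(r.n_paralogs == 0 for r in records)
        summary["spufs_1_2_paralogs"] = sum(r.n_paralogs in (1, 2) for r in records)
        summary["spufs_no_homolog_other"] = (
            sum(r.n_homologs_other == 0 for r in records) if other_proteome else None
        )
        summary["paralog_histogram"] = histogram
        summary["truncated_lrr_genes"] = len(truncated)
        summary["spuf_associated"] = len(set(spuf_ids) & association.union)
        summary["pct_spuf_of_associated"] = enr.pct_spuf_associated
        summary["pct_spuf_of_genome"] = enr.pct_spuf_genome
        summary["enrichment"] = dataclasses.asdict(enr)

    # --- stage 4: phylogeny vs. genomic location ---------------------------
    with _stage("phylo", config):
        clustered = {m for c in cls for m in c.members}
        tree_input = {gid: seq for gid, seq in c3d.items()}
        summary["phylo"] = {"skipped": True}
        if len(tree_input) >= 3:
            ids, dmat = phylo.build_distance_matrix(tree_input)
            tree = phylo.neighbor_joining(ids, dmat)
            rio.write_newick(tree, out("tree.nwk"))
            locations = {
                m: c.cluster_id for c in cls for m in c.members if m in tree_input
            }
            ari = None
            k = config.phylo_k or len(cls)
            if len(cls) >= 2 and len(locations) >= 4:
                ari = phylo.clade_locus_concordance(tree, locations, k=k)
                clades = phylo.cut_clades(tree, k)
                pd.DataFrame(
                    sorted(clades.items()), columns=["gene_id", "clade"]
                ).to_csv(out("clades.tsv"), sep="\t", index=False)
            summary["phylo"] = {"n_leaves": len(ids), "k": k, "ari": ari}

    # --- stage 5: expression ----------------------------------------------
    pairs = pd.DataFrame()
    if matrix_nonwounded is None or matrix_wounded is None:
        summary["expression"] = {"skipped": True}
    else:
        with _stage("expression", config):
            results = expr.summarize_expression(
                matrix_nonwounded,
                matrix_wounded,
                background=config.background,
                pseudocount=config.pseudocount,
                slight_min=config.slight_min,
                strong_min=config.strong_min,
                low_max=config.low_max,
                high_max=config.high_max,
            )
            results.to_csv(out("expression_results.tsv"), sep="\t",
                           index_label="gene_id")
            reg = {}
            for label, subset in (
                ("lrr_rlp", receptor_ids),
                ("spuf", spuf_ids),
            ):
                sub = results.loc[[g for g in subset if g in results.index]]
                if len(sub) >= 3 and np.ptp(sub["mean_nonwounded"]) > 0:
                    slope, intercept, r2 = expr.regression_wounded_vs_nonwounded(sub)
                    reg[label] = {"slope": slope, "intercept": intercept, "r2": r2}
            pairs = expr.coexpressed_pairs(
                cls,
                association,
                results,
                set(spuf_ids),
                matrix_nonwounded=matrix_nonwounded,
                matrix_wounded=matrix_wounded,
                background=config.background,
            )
            pairs.to_csv(out("coexpressed_pairs.tsv"), sep="\t", index=False)
            induced = results[results["induction"] != "none"]
            summary["expression"] = {
                "n_expressed": int(results["expressed"].sum()),
                "n_expressed_lrr_rlp": int(
                    results.loc[[g for g in receptor_ids if g in results.index],
                                "expressed"].sum()
                ),
                "n_expressed_spuf": int(
                    results.loc[[g for g in spuf_ids if g in results.index],
                                "expressed"].sum()
                ),
                "n_strong_induced": int((results["induction"] == "strong").sum()),
                "n_slight_induced": int((results["induction"] == "slight").sum()),
                "induced_genes": sorted(induced.index),
                "regression": reg,
                "n_coexpressed_pairs": len(pairs),
            }

    # --- stage 6: promoter conservation ------------------------------------
    if genome.genomic_seq is None or pairs.empty:
        summary["promoter"] = {"skipped": True}
    else:
        with _stage("promoter", config):
            from .promoter import extract_promoter, scan_conserved_blocks

            block_rows = []
            for _, row in pairs.iterrows():
                pa = extract_promoter(genome, row["receptor"], config.promoter_length)
                pb = extract_promoter(genome, row["spuf"], config.promoter_length)
                for bl in scan_conserved_blocks(
                    pa,
                    pb,
                    window=config.promoter_window,
                    step=config.promoter_step,
                    min_identity=config.promoter_min_identity,
                    min_block=config.promoter_min_block,
                    band=config.promoter_band,
                ):
                    block_rows.append(
                        {
                            "gene_a": row["receptor"],
                            "gene_b": row["spuf"],
                            "offset_a": bl.offset_a,
                            "offset_b": bl.offset_b,
                            "length": bl.length,
                            "identity": bl.identity,
                        }
                    )
            pd.DataFrame(
                block_rows,
                columns=["gene_a", "gene_b", "offset_a", "offset_b",
                         "length", "identity"],
            ).to_csv(out("promoter_blocks.tsv"), sep="\t", index=False)
            summary["promoter"] = {"n_blocks": len(block_rows), "blocks": block_rows}

    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _iv(interval) -> str:
    return "" if interval is None else f"{interval[0]}-{interval[1]}"


_TABLE1_ROWS = [
    "LRR-RLP genes",
    "SPUF genes",
    "LRR-RLP-associated genes [avg. per LRR-RLP gene]",
    "% of SPUF genes compared with the total no. of LRR-RLP-associated genes",
    "% of SPUF genes in the whole predicted proteome",
    "LRR-RLP genes clustered [no. of clusters]",
    "SPUFs predicted secreted",
    "SPUFs with no paralog",
    "SPUFs with 1 or 2 paralogs",
]


def _table1_column(summary: dict) -> list[str]:
    n_receptors = summary.get("lrr_rlp_genes", 0)
    if n_receptors == 0:
        return ["0"] + ["-"] * (len(_TABLE1_ROWS) - 1)
    n_assoc = summary.get("associated_genes", 0)
    n_spuf = summary.get("spuf_genes", 0)
    n_spuf_assoc = summary.get("spuf_associated")
    if n_spuf_assoc is None:
        # reconstruct from the reported percentage when the raw count is absent
        n_spuf_assoc = round(summary.get("pct_spuf_of_associated", 0.0) * n_assoc / 100)
    n_non_receptor = summary.get("n_genes", 0) - n_receptors
    mean = summary.get("associated_mean", 0.0)
    sd = summary.get("associated_sd", 0.0)
    return [
        str(n_receptors),
        str(n_spuf),
        f"{n_assoc} [{mean:.2f} ± {sd:.1f}]",
        format_pct(n_spuf_assoc, n_assoc),
        format_pct(n_spuf, n_non_receptor) if n_non_receptor else "-",
        f"{summary.get('clustered', 0)} [{summary.get('n_clusters', 0)}]",
        str(summary.get("spufs_secreted", "-")),
        str(summary.get("spufs_no_paralog", "-")),
        str(summary.get("spufs_1_2_paralogs", "-")),
    ]


def make_table1(summary_self: dict, summary_other: dict | None = None) -> str:
    """Render the two-column family table for one or two genomes.

    Percentages are printed to one decimal; a genome with zero receptors
    yields dashes instead of undefined ratios.
    """
    col_a = _table1_column(summary_self)
    cols = [col_a]
    if summary_other is not None:
        cols.append(_table1_column(summary_other))
    lines = []
    for i, label in enumerate(_TABLE1_ROWS):
        lines.append("\t".join([label] + [c[i] for c in cols]))
    return "\n".join(lines)


__all__ = [
    "SCHEMA_VERSION",
    "PipelineConfig",
    "PipelineError",
    "format_pct",
    "run_all",
    "make_table1",
]
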