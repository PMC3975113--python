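"""Readers and writers for the standard formats the pipeline touches.

GFF3 is parsed through :mod:`gffutils`; a light pre-scan of the raw lines
provides parse errors that name the offending line number.  FASTA goes through
Biopython, expression matrices through pandas, trees through dendropy.  All
coordinates are converted to the internal 0-based half-open convention at this
boundary.
"""

from __future__ import annotations

import os
import urllib.parse
import warnings
from typing import Iterable

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneModel, Genome, ValidationError


class Gff3ParseError(ValueError):
    """Raised for a malformed GFF3 line; the message names the line number."""


_QUOTE_SAFE = " .:^*$@!+?|"  # characters left as-is in GFF3 attribute values


def _prescan_gff3(path: str | os.PathLike) -> None:
    """Validate basic GFF3 line structure so errors can cite line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise Gff3ParseError(
                    f"line {lineno}: start/end are not integers: {fields[3]!r}, {fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise Gff3ParseError(
                    f"line {lineno}: invalid 1-based span {start}..{end}"
                )


def read_gff3(path: str | os.PathLike) -> Genome:
    """Read gene features from a GFF3 file into a :class:`Genome`.

    Only ``gene`` features are considered (feature hierarchies are out of
    scope).  1-based inclusive coordinates become 0-based half-open.  The
    description is taken from the ``Note`` or ``description`` attribute
    (``""`` if absent); ``domain_hits`` and ``protein_length`` attributes are
    honoured when present so that a written genome round-trips.

    Chromosome lengths come from ``##sequence-region`` pragmas when present,
    otherwise from the rightmost gene end per chromosome.
    """
    _prescan_gff3(path)
    chrom_lengths: dict[str, int] = {}
    n_feature_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
            elif line.strip() and not line.startswith("#"):
                n_feature_lines += 1
    if n_feature_lines == 0:
        return Genome(chromosomes=chrom_lengths, genes=[])
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises plain ValueError on dup IDs
        if "duplicate" in str(exc).lower() or "Duplicate" in str(exc):
            raise ValidationError(f"duplicate feature ID in {path}: {exc}") from exc
        raise

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.id
        if gene_id in seen:
            raise ValidationError(f"duplicate gene ID {gene_id!r} in {path}")
        seen.add(gene_id)
        note = feat.attributes.get("Note") or feat.attributes.get("description") or [""]
        description = urllib.parse.unquote(note[0])
        hits_attr = feat.attributes.get("domain_hits") or []
        domain_hits = [h for part in hits_attr for h in part.split(",") if h]
        plen_attr = feat.attributes.get("protein_length")
        protein_length = int(plen_attr[0]) if plen_attr else None
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                description=description,
                domain_hits=domain_hits,
                protein_length=protein_length,
            )
        )
    for g in genes:
        chrom_lengths.setdefault(g.chrom, 0)
        chrom_lengths[g.chrom] = max(chrom_lengths[g.chrom], g.end)
    return Genome(chromosomes=chrom_lengths, genes=genes)


def write_gff3(genome: Genome, path: str | os.PathLike) -> None:
    """Write gene features (gene-level only) to GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.chromosomes):
            fh.write(f"##sequence-region {chrom} 1 {genome.chromosomes[chrom]}\n")
        for g in genome.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.description:
                attrs.append(f"Note={urllib.parse.quote(g.description, safe=_QUOTE_SAFE)}")
            if g.domain_hits:
                attrs.append("domain_hits=" + ",".join(g.domain_hits))
            if g.protein_length is not None:
                attrs.append(f"protein_length={g.protein_length}")
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "rlpscape",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` map.

    Record ids are the first whitespace-delimited token of each header.
    Duplicate ids raise :class:`~rlpscape.model.ValidationError`.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"duplicate FASTA id {record.id!r} in {path}")
        seqs[record.id] = str(record.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x condition intensity matrix from TSV.

    First column holds gene ids; every other column must be numeric and
    non-negative.  A missing or negative value raises an error naming the
    offending cell (gene id and column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.index[series.isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric or missing value at gene {bad[0]!r}, column {col!r}"
            )
        neg = series.index[series < 0]
        if len(neg):
            raise ValidationError(
                f"{path}: negative intensity at gene {neg[0]!r}, column {col!r}"
            )
        df[col] = series.astype(float)
    return df


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    # 17 significant digits so a written matrix reads back value-identical
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_bed(intervals: Iterable, path: str | os.PathLike) -> None:
    """Write cluster-like objects (``chrom``, ``start``, ``end``, id) as BED.

    BED is natively 0-based half-open, matching the internal convention.
    Accepts any object with ``chrom``/``start``/``end`` attributes plus a
    ``cluster_id`` or ``sc_id`` attribute for the name column.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "cluster_id", None) or getattr(iv, "sc_id", None) or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    """Serialize a tree to Newick with >= 6 significant digits on lengths."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_annotation_table(genome: Genome, path: str | os.PathLike) -> None:
    """Write the functional-annotation TSV (gene id, description, domain hits)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "description": g.description,
            "domain_hits": ";".join(g.domain_hits),
            "protein_length": "" if g.protein_length is None else g.protein_length,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_annotation_table(genome: Genome, path: str | os.PathLike) -> None:
    """Overlay descriptions/domain hits from an annotation TSV onto a genome."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
    index = genome.gene_index()
    for _, row in df.iterrows():
        gene = index.get(row["gene_id"])
        if gene is None:
            warnings.warn(f"annotation for unknown gene {row['gene_id']!r} ignored")
            continue
        gene.description = str(row.get("description", "") or "")
        hits = str(row.get("domain_hits", "") or "")
        gene.domain_hits = [h for h in hits.split(";") if h]
        plen = row.get("protein_length", "")
        if plen != "" and not pd.isna(plen):
            gene.protein_length = int(float(plen))


__all__ = [
    "Gff3ParseError",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "write_bed",
    "write_newick",
    "read_newick",
    "write_annotation_table",
    "apply_annotation_table",
]
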