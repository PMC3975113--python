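"""Core data model: annotated genes and genomes.

All coordinates inside the package are 0-based, half-open intervals on the
forward strand of the chromosome; conversion to/from the 1-based inclusive
GFF3 convention happens only at the I/O boundary (:mod:`rlpscape.io`).
Interval length is always ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when a record violates a data-model invariant."""


def normalize_description(text: str) -> str:
    """Lower-case a functional description and collapse runs of whitespace.

    Description matching throughout the package is case-insensitive and
    whitespace-normalized, so "Hypothetical  Protein" == "hypothetical protein".
    """
    return " ".join(text.lower().split())


@dataclass
class GeneModel:
    """One annotated gene model.

    Parameters
    ----------
    gene_id:
        Unique identifier within a genome.
    chrom:
        Chromosome (or scaffold) name.
    strand:
        ``"+"`` or ``"-"``.
    start, end:
        0-based half-open span of the outermost gene feature.
    description:
        Free-text functional annotation; ``""`` when the gene has none.
    domain_hits:
        Identifiers of protein-domain library hits (e.g. Pfam accessions);
        empty when no domain is recognized.
    protein_length:
        Length of the encoded protein in amino acids, or ``None`` for a
        non-coding model.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    description: str = ""
    domain_hits: list[str] = field(default_factory=list)
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A set of chromosomes with sorted gene models and optional sequences.

    ``genes`` is kept sorted by ``(chrom, start)``; ``proteins`` maps gene ids
    to amino-acid sequences; ``genomic_seq`` (optional) maps chromosome names
    to nucleotide sequences and is only required by promoter analysis.
    """

    chromosomes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)
    genomic_seq: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sort()
        self.validate()

    def sort(self) -> None:
        self.genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chromosomes:
                raise ValidationError(
                    f"gene {g.gene_id!r} on unknown chromosome {g.chrom!r}"
                )
            if g.end > self.chromosomes[g.chrom]:
                raise ValidationError(
                    f"gene {g.gene_id!r} extends past the end of {g.chrom!r} "
                    f"({g.end} > {self.chromosomes[g.chrom]})"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_index(self) -> dict[str, GeneModel]:
        """Return a gene_id -> GeneModel mapping (built on demand)."""
        return {g.gene_id: g for g in self.genes}

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]

    def __len__(self) -> int:
        return len(self.genes)
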