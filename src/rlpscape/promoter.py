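"""Conserved-block detection between promoter pairs.

Promoters are the 1 kb immediately upstream of the translation start,
strand-aware.  Conservation between two promoters is scanned with a banded,
alignment-free windowed-identity search: the two sequences are compared at
every small relative offset (the band), windows above the identity floor are
merged, and merged blocks above the length floor are reported with their
identity recomputed over the merged extent.  Offsets are reported relative to
the translation start (negative positions), the natural frame when no TSS
annotation exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import Genome

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ConservedBlock:
    """A conserved stretch shared by two promoters.

    ``offset_a``/``offset_b`` are the block-start positions relative to the
    translation start of each gene (negative, e.g. -1000 for a block starting
    1 kb upstream); ``length`` is in bp and ``identity`` in percent over the
    merged extent.
    """

    offset_a: int
    offset_b: int
    length: int
    identity: float


def extract_promoter(genome: Genome, gene_id: str, length: int = 1000) -> str:
    """Strand-aware upstream sequence ending at the translation start.

    For a + strand gene this is ``[start - length, start)`` of the
    chromosome; for a - strand gene the reverse complement of
    ``[end, end + length)``.  Promoters running off the chromosome edge are
    truncated with a warning.
    """
    if genome.genomic_seq is None:
        raise ValueError("genome carries no nucleotide sequence")
    gene = genome.gene_index()[gene_id]
    chrom_seq = genome.genomic_seq[gene.chrom]
    if gene.strand == "+":
        lo = gene.start - length
        if lo < 0:
            warnings.warn(
                f"promoter of {gene_id} truncated to {gene.start} bp at chromosome start"
            )
            lo = 0
        return chrom_seq[lo : gene.start]
    hi = gene.end + length
    if hi > len(chrom_seq):
        warnings.warn(
            f"promoter of {gene_id} truncated to {len(chrom_seq) - gene.end} bp "
            "at chromosome end"
        )
        hi = len(chrom_seq)
    return revcomp(chrom_seq[gene.end : hi])


def _merge_windows(starts: list[int], window: int) -> list[tuple[int, int]]:
    """Merge overlapping fixed-length windows into maximal extents."""
    merged: list[tuple[int, int]] = []
    for s in starts:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], s + window)
        else:
            merged.append((s, s + window))
    return merged


def scan_conserved_blocks(
    prom_a: str,
    prom_b: str,
    window: int = 100,
    step: int = 10,
    min_identity: float = 85.0,
    min_block: int = 200,
    band: int = 50,
    edge_trim_identity: float = 50.0,
) -> list[ConservedBlock]:
    """Banded windowed-identity scan for shared promoter blocks.

    For every relative offset ``d`` with ``|d| <= band`` the two promoters
    are laid side by side and windows of ``window`` bp (every ``step`` bp)
    with percent identity at least ``min_identity`` are collected.
    Overlapping passing windows on the same offset merge into one block;
    blocks shorter than ``min_block`` or whose recomputed identity over the
    merged extent falls below ``min_identity`` are discarded.  Overlapping
    blocks from neighbouring offsets are deduplicated in favour of the higher
    identity.  Results are sorted by ``offset_a``.
    """
    len_a, len_b = len(prom_a), len(prom_b)
    if len_a < window or len_b < window:
        warnings.warn("promoter shorter than the scan window; no blocks reported")
        return []
    a = np.frombuffer(prom_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(prom_b.upper().encode(), dtype=np.uint8)
    blocks: list[ConservedBlock] = []
    for d in range(-band, band + 1):
        a_start = max(0, -d)
        b_start = a_start + d
        overlap = min(len_a - a_start, len_b - b_start)
        if overlap < window:
            continue
        eq = (a[a_start : a_start + overlap] == b[b_start : b_start + overlap])
        csum = np.concatenate([[0], np.cumsum(eq)])
        first = -(-a_start // step) * step  # smallest grid point >= a_start
        starts = np.arange(first, a_start + overlap - window + 1, step)
        if starts.size == 0:
            continue
        rel = starts - a_start
        ident = 100.0 * (csum[rel + window] - csum[rel]) / window
        passing = [int(s) for s, ok in zip(starts, ident >= min_identity) if ok]
        for s, e in _merge_windows(passing, window):
            # trim terminal chunks at random-match identity: they are window
            # overhang beyond the conserved block, not block sequence
            def _chunk_ident(lo: int, hi: int) -> float:
                return 100.0 * (csum[hi - a_start] - csum[lo - a_start]) / (hi - lo)

            while e - s > step and _chunk_ident(e - step, e) < edge_trim_identity:
                e -= step
            while e - s > step and _chunk_ident(s, s + step) < edge_trim_identity:
                s += step
            if e - s < min_block:
                continue
            block_ident = _chunk_ident(s, e)
            if block_ident < min_identity:
                continue
            blocks.append(
                ConservedBlock(
                    offset_a=s - len_a,
                    offset_b=s + d - len_b,
                    length=e - s,
                    identity=float(block_ident),
                )
            )
    # deduplicate near-duplicate blocks from neighbouring offsets
    blocks.sort(key=lambda bl: (-bl.identity, -bl.length, bl.offset_a, bl.offset_b))
    kept: list[ConservedBlock] = []
    for bl in blocks:
        redundant = False
        for other in kept:
            lo = max(bl.offset_a, other.offset_a)
            hi = min(bl.offset_a + bl.length, other.offset_a + other.length)
            if hi - lo > 0.5 * min(bl.length, other.length):
                redundant = True
                break
        if not redundant:
            kept.append(bl)
    kept.sort(key=lambda bl: (bl.offset_a, bl.offset_b))
    return kept


__all__ = ["ConservedBlock", "revcomp", "extract_promoter", "scan_conserved_blocks"]
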