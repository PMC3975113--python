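"""Synthetic genomes with planted, fully known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: multi-chromosome gene layouts with planted receptor clusters and
super-clusters at configurable gaps, small unannotated (SPUF) genes
interleaved inside clusters, annotated filler genes elsewhere, a duplicated
"twin-chromosome" cluster copy at a target protein identity, receptor
proteins with the canonical A-G domain architecture, promoters carrying a
planted conserved block between a designated SPUF/receptor pair, and paired
expression matrices (non-wounded / wounded) with log-normal noise and planted
inductions.

Everything is driven by integer-seeded numpy generators, one stream per
generated artifact (layout, proteins, chromosome sequence, expression), so
output is reproducible byte-for-byte for a given seed and adding genes to one
artifact does not perturb the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as rio
from .lrr import AA_ORDER, BACKGROUND, LRR_CONSENSUS
from .model import GeneModel, Genome


class ParameterError(ValueError):
    """Raised when generator parameters cannot be realized (e.g. overflow)."""


# ---------------------------------------------------------------------------
# protein construction
# ---------------------------------------------------------------------------

_BG_AA = np.array(list(AA_ORDER))
_BG_P = np.array([BACKGROUND[a] for a in AA_ORDER])
_BG_P = _BG_P / _BG_P.sum()

_SP_FILLER = "NQTDEP"        # n-region padding: hydrophilic, no small residues
_SP_CORE = "LIVF"            # h-region
_ISLAND_ALPHABET = "DENQSTGP"
_ACIDIC = "DDDEEESTNQG"
_TM_ALPHABET = "LIVF"
_TAIL_ALPHABET = "STNQDEKRGP"
_HYDROPHILIC = "DENQKRSTPGH"  # N-termini of non-secreted proteins


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _draw_bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BG_AA, size=n, p=_BG_P))


def _make_signal_peptide(rng: np.random.Generator) -> str:
    """Cleavable N-terminal signal: M + 2 basic + hydrophobic core + G.

    Total length is 20-28 aa; the terminal glycine is the small-residue
    cleavage site the detector looks for.
    """
    f = int(rng.integers(8, 17))
    return "M" + _draw(rng, "KR", 2) + _draw(rng, _SP_FILLER, f) + _draw(rng, _SP_CORE, 8) + "G"


def _instantiate_lrr(rng: np.random.Generator, p_sub: float) -> str:
    out = []
    for c in LRR_CONSENSUS:
        aa = _draw_bg(rng, 1) if c == "X" else c
        if p_sub > 0 and rng.random() < p_sub:
            aa = _draw_bg(rng, 1)
        out.append(aa)
    return "".join(out)


def _make_receptor(
    rng: np.random.Generator, n_lrr: int, p_sub: float
) -> tuple[str, int]:
    """Build one receptor protein; returns (sequence, signal-peptide length)."""
    if n_lrr < 1:
        raise ParameterError("n_lrr must be >= 1")
    sp = _make_signal_peptide(rng)
    cap = "CC" + _draw(rng, "NQTE", 4)
    island_after = math.ceil(0.75 * n_lrr)
    parts = [sp, cap]
    for k in range(n_lrr):
        parts.append(_instantiate_lrr(rng, p_sub))
        if k + 1 == island_after:
            parts.append(_draw(rng, _ISLAND_ALPHABET, 25))
    parts.append(_draw(rng, _ACIDIC, 20))           # D linker
    parts.append(_draw(rng, _TM_ALPHABET, 21))      # TM span
    parts.append(_draw(rng, _TAIL_ALPHABET, int(rng.integers(10, 25))))
    return "".join(parts), len(sp)


def make_receptor_protein(
    n_lrr: int, seed: int | None = None, p_sub: float = 0.15,
    rng: np.random.Generator | None = None,
) -> str:
    """Receptor protein with ``n_lrr`` tandem LRRs and canonical architecture.

    ``p_sub`` is the per-position substitution probability applied to the
    repeat copies (0 gives noiseless consensus repeats).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    seq, _ = _make_receptor(rng, n_lrr, p_sub)
    return seq


def make_spuf_protein(
    length: int, secreted: bool, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Small protein of unknown function; optionally with a signal peptide.

    Non-secreted proteins start with a strictly hydrophilic N-terminus so the
    secretion heuristic can never fire on them (a deliberate simplification
    that makes the planted secreted subset exactly recoverable).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if secreted:
        sp = _make_signal_peptide(rng)
        if length <= len(sp) + 10:
            length = len(sp) + 40
        return sp + _draw_bg(rng, length - len(sp))
    head = min(35, length)
    return "M" + _draw(rng, _HYDROPHILIC, head - 1) + _draw_bg(rng, length - head)


def _make_filler_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + _draw_bg(rng, length - 1)


def _make_truncated_lrr_protein(rng: np.random.Generator, n_repeats: int = 6) -> str:
    head = "M" + _draw(rng, _HYDROPHILIC, 34)
    reps = "".join(_instantiate_lrr(rng, 0.05) for _ in range(n_repeats))
    return head + reps + _draw_bg(rng, 70)


def mutate_protein(
    seq: str,
    fraction: float | None = None,
    n_mut: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    protect_end: int = 0,
) -> str:
    """Substitute an exact number of positions to different residues.

    ``fraction`` gives ``floor(fraction * len)`` substitutions; positions
    before ``protect_end`` (e.g. a signal peptide under purifying selection)
    are never touched.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_mut is None:
        if fraction is None:
            raise ValueError("give either fraction or n_mut")
        n_mut = int(fraction * len(seq))
    mutable = np.arange(protect_end, len(seq))
    if n_mut > len(mutable):
        raise ParameterError("more mutations requested than mutable positions")
    sites = rng.choice(mutable, size=n_mut, replace=False)
    chars = list(seq)
    for i in sites:
        new = chars[i]
        while new == chars[i]:
            new = str(rng.choice(_BG_AA, p=_BG_P))
        chars[i] = new
    return "".join(chars)


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """One planted receptor cluster.

    ``intra_gap`` is the exact end-to-start gap between consecutive receptor
    genes; ``spuf_per_gap`` SPUF genes are interleaved inside each gap and one
    annotated filler gene is added to every ``filler_every``-th gap.
    """

    n_receptors: int
    intra_gap: int = 10_000
    spuf_per_gap: int = 1
    filler_every: int = 3
    n_lrr: int = 20


@dataclass
class ChromosomePlan:
    length: int = 3_000_000
    clusters: list[ClusterSpec] = field(default_factory=list)
    cluster_gaps: list[int] = field(default_factory=list)
    n_singletons: int = 0
    n_filler: int = 60
    n_background_spuf: int = 18
    n_truncated_lrr: int = 0


@dataclass
class TwinSpec:
    """Copy one planted cluster to a second chromosome ("twin chromosomes")."""

    source_cluster: int = 0
    target_chrom: int = -1
    identity: float = 0.96
    gap_from_start: int = 500_000


@dataclass
class PromoterBlockSpec:
    """A conserved block shared between two promoters, relative to the ATG."""

    length: int = 300
    identity: float = 0.90
    offset: int = -1000


@dataclass
class GenomeParams:
    chromosomes: list[ChromosomePlan]
    p_sub: float = 0.15
    family_divergence: float = 0.05
    twin: TwinSpec | None = None
    spuf_families: list[tuple[int, float]] = field(default_factory=lambda: [(4, 0.80)])
    promoter_block: PromoterBlockSpec | None = field(default_factory=PromoterBlockSpec)
    risp_fold_change: float = 10.0
    receptor_fold_change: float = 1.8
    n_very_high: int = 3
    background_gap: tuple[int, int] = (2_000, 9_000)
    buffer: int = 60_000

    @classmethod
    def default(cls) -> "GenomeParams":
        """The reference study conditions: 3 chromosomes, ~280 genes,
        4 planted clusters (one a 96%-identity twin copy), 1 super-cluster."""
        return cls(
            chromosomes=[
                ChromosomePlan(
                    length=3_200_000,
                    clusters=[ClusterSpec(5), ClusterSpec(4)],
                    cluster_gaps=[400_000, 1_500_000],
                    n_filler=60,
                    n_background_spuf=18,
                ),
                ChromosomePlan(
                    length=3_000_000,
                    clusters=[ClusterSpec(4, intra_gap=12_000)],
                    cluster_gaps=[350_000],
                    n_singletons=1,
                    n_filler=60,
                    n_background_spuf=18,
                    n_truncated_lrr=2,
                ),
                ChromosomePlan(
                    length=3_000_000,
                    n_singletons=2,
                    n_filler=60,
                    n_background_spuf=18,
                ),
            ],
            twin=TwinSpec(source_cluster=2, target_chrom=2, identity=0.96),
        )

    @classmethod
    def noiseless(cls) -> "GenomeParams":
        """The default layout with all sequence-level noise switched off."""
        params = cls.default()
        params.p_sub = 0.0
        params.family_divergence = 0.0
        return params

    @classmethod
    def small(cls) -> "GenomeParams":
        """A reduced layout (~60 genes) for fast exploratory runs."""
        return cls(
            chromosomes=[
                ChromosomePlan(
                    length=2_000_000,
                    clusters=[ClusterSpec(3), ClusterSpec(2)],
                    cluster_gaps=[100_000, 1_500_000],
                    n_filler=12,
                    n_background_spuf=5,
                ),
                ChromosomePlan(
                    length=2_000_000,
                    clusters=[ClusterSpec(3, intra_gap=12_000)],
                    cluster_gaps=[150_000],
                    n_singletons=1,
                    n_filler=12,
                    n_background_spuf=5,
                    n_truncated_lrr=1,
                ),
            ],
            twin=TwinSpec(source_cluster=2, target_chrom=1, identity=0.96),
            spuf_families=[(3, 0.80)],
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic genome."""

    seed: int
    receptor_ids: list[str] = field(default_factory=list)
    singleton_receptor_ids: list[str] = field(default_factory=list)
    clusters: list[dict] = field(default_factory=list)
    superclusters: list[dict] = field(default_factory=list)
    spuf_ids: list[str] = field(default_factory=list)
    secreted_spuf_ids: list[str] = field(default_factory=list)
    truncated_lrr_ids: list[str] = field(default_factory=list)
    paralog_families: list[dict] = field(default_factory=list)
    twin: dict | None = None
    conserved_block: dict | None = None
    inductions: dict = field(default_factory=dict)
    baseline_overrides: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# placement machinery
# ---------------------------------------------------------------------------

_FILLER_ANNOTATIONS = [
    ("protein kinase family protein", ["PF00069"]),
    ("cytochrome p450", ["PF00067"]),
    ("pentatricopeptide repeat protein", ["PF01535"]),
    ("udp-glycosyltransferase", ["PF00201"]),
    ("myb transcription factor", ["PF00249"]),
    ("abc transporter family protein", ["PF00005"]),
    ("glycosyl hydrolase family protein", ["PF00232"]),
    ("serine-threonine protein kinase", ["PF00069"]),
    ("lectin receptor kinase", ["PF01453"]),
    ("heat shock protein 70", ["PF00012"]),
]

_RECEPTOR_ANNOTATION = (
    "leucine-rich repeat receptor-like protein",
    ["PF00560", "PF13855"],
)


@dataclass
class _Placed:
    pos: int
    protein: str
    kind: str                 # receptor | spuf | filler | truncated
    description: str = ""
    domain_hits: list[str] = field(default_factory=list)
    secreted: bool = False
    gene_id: str = ""

    @property
    def end(self) -> int:
        return self.pos + 3 * len(self.protein)


def _filler(rng: np.random.Generator) -> _Placed:
    desc, hits = _FILLER_ANNOTATIONS[int(rng.integers(len(_FILLER_ANNOTATIONS)))]
    prot = _make_filler_protein(rng, int(rng.integers(220, 600)))
    return _Placed(pos=0, protein=prot, kind="filler", description=desc, domain_hits=list(hits))


def _place_cluster(
    spec: ClusterSpec,
    start: int,
    prot_rng: np.random.Generator,
    params: GenomeParams,
    n_truncated: int = 0,
) -> tuple[list[_Placed], list[_Placed], int]:
    """Lay out one cluster; returns (receptors, interleaved genes, end)."""
    founder, sp_len = _make_receptor(prot_rng, spec.n_lrr, params.p_sub)
    receptors: list[_Placed] = []
    interleaved: list[_Placed] = []
    cursor = start
    trunc_left = n_truncated
    for k in range(spec.n_receptors):
        if params.family_divergence > 0:
            prot = mutate_protein(
                founder, fraction=params.family_divergence,
                rng=prot_rng, protect_end=sp_len,
            )
        else:
            prot = founder
        desc, hits = _RECEPTOR_ANNOTATION
        rec = _Placed(pos=cursor, protein=prot, kind="receptor",
                      description=desc, domain_hits=list(hits))
        receptors.append(rec)
        cursor = rec.end
        if k == spec.n_receptors - 1:
            break
        # interleave genes inside the gap to the next receptor
        items: list[_Placed] = []
        for s in range(spec.spuf_per_gap):
            secreted = k == 0 and s == 0  # first SPUF of the cluster is secreted
            prot_s = make_spuf_protein(int(prot_rng.integers(60, 190)),
                                       secreted=secreted, rng=prot_rng)
            items.append(_Placed(pos=0, protein=prot_s, kind="spuf", secreted=secreted))
        if spec.filler_every and (k % spec.filler_every == spec.filler_every - 1):
            items.append(_filler(prot_rng))
        if trunc_left > 0:
            items.append(_Placed(pos=0, protein=_make_truncated_lrr_protein(prot_rng),
                                 kind="truncated"))
            trunc_left -= 1
        n_items = len(items)
        for j, item in enumerate(items):
            mid = cursor + spec.intra_gap * (j + 1) // (n_items + 1)
            item.pos = mid - 3 * len(item.protein) // 2
        for j in range(n_items):
            prev_end = cursor if j == 0 else items[j - 1].end
            if items[j].pos <= prev_end or items[j].end >= cursor + spec.intra_gap:
                raise ParameterError(
                    f"intra-cluster gap {spec.intra_gap} too small for interleaved genes"
                )
        interleaved.extend(items)
        cursor += spec.intra_gap
    return receptors, interleaved, cursor


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_chromosome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    comp = np.empty_like(arr)
    comp[arr == ord("A")] = ord("T")
    comp[arr == ord("T")] = ord("A")
    comp[arr == ord("C")] = ord("G")
    comp[arr == ord("G")] = ord("C")
    return comp[::-1]


def _promoter_slice(arr: np.ndarray, gene: GeneModel, plen: int) -> np.ndarray:
    """Strand-aware promoter as a byte array, 5'->3', ending at the ATG."""
    if gene.strand == "+":
        return arr[gene.start - plen : gene.start].copy()
    return _revcomp_codes(arr[gene.end : gene.end + plen])


def _write_promoter_block(
    arr: np.ndarray, gene: GeneModel, plen: int, offset: int, block: np.ndarray
) -> None:
    """Write ``block`` into a promoter at ``offset`` (negative, rel. ATG)."""
    p0 = plen + offset
    L = len(block)
    if gene.strand == "+":
        s = gene.start - plen + p0
        arr[s : s + L] = block
    else:
        s = gene.end + (plen - p0 - L)
        arr[s : s + L] = _revcomp_codes(block)


def _mutate_bases(
    rng: np.random.Generator, block: np.ndarray, identity: float
) -> np.ndarray:
    out = block.copy()
    n_mut = round((1.0 - identity) * len(block))
    sites = rng.choice(len(block), size=n_mut, replace=False)
    for i in sites:
        new = out[i]
        while new == out[i]:
            new = _BASES[rng.integers(0, 4)]
        out[i] = new
    return out


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


def make_genome(
    params: GenomeParams, seed: int = 0
) -> tuple[Genome, SyntheticTruth]:
    """Generate a genome plus its :class:`SyntheticTruth`.

    Gene ids are assigned per chromosome in positional order.  Placement uses
    exactly the stated gaps; any gene that would not fit its chromosome raises
    :class:`ParameterError`.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11])
    layout_rng, prot_rng, seq_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    chrom_names = [f"chr{i + 1}" for i in range(len(params.chromosomes))]
    placed: dict[str, list[_Placed]] = {c: [] for c in chrom_names}
    cursors = {c: 0 for c in chrom_names}
    truth = SyntheticTruth(seed=int(seed))
    cluster_records: list[dict] = []  # {"chrom", "receptors": [_Placed], ...}

    # 1. planted clusters at their stated gaps
    for ci, plan in enumerate(params.chromosomes):
        chrom = chrom_names[ci]
        if len(plan.cluster_gaps) != len(plan.clusters):
            raise ParameterError(
                f"{chrom}: need one cluster_gap per cluster "
                f"({len(plan.cluster_gaps)} vs {len(plan.clusters)})"
            )
        trunc_left = plan.n_truncated_lrr
        for k, (spec, gap) in enumerate(zip(plan.clusters, plan.cluster_gaps)):
            start = cursors[chrom] + gap
            recs, inter, end = _place_cluster(
                spec, start, prot_rng, params, n_truncated=trunc_left if k == 0 else 0
            )
            if k == 0:
                trunc_left = 0
            if end > plan.length:
                raise ParameterError(f"{chrom}: cluster overflows chromosome")
            placed[chrom].extend(recs + inter)
            cursors[chrom] = end
            cluster_records.append(
                {"chrom": chrom, "receptors": recs, "interleaved": inter,
                 "intra_gap": spec.intra_gap, "sp_protect": True}
            )

    # 2. twin-chromosome duplication of one cluster
    if params.twin is not None:
        tw = params.twin
        if not 0 <= tw.source_cluster < len(cluster_records):
            raise ParameterError(f"twin source_cluster {tw.source_cluster} out of range")
        src = cluster_records[tw.source_cluster]
        tchrom = chrom_names[tw.target_chrom]
        base = cursors[tchrom] + tw.gap_from_start
        origin = src["receptors"][0].pos
        copies_r, copies_i = [], []
        for item in src["receptors"] + src["interleaved"]:
            # signal peptides evolve under purifying selection: protect them
            protect = 0
            if item.kind == "receptor" or (item.kind == "spuf" and item.secreted):
                protect = _signal_len(item.protein)
            n_mut = round((1.0 - tw.identity) * len(item.protein))
            prot = mutate_protein(item.protein, n_mut=n_mut, rng=prot_rng,
                                  protect_end=protect)
            copy = _Placed(
                pos=base + (item.pos - origin), protein=prot, kind=item.kind,
                description=item.description, domain_hits=list(item.domain_hits),
                secreted=item.secreted,
            )
            (copies_r if item.kind == "receptor" else copies_i).append(copy)
        end = max(c.end for c in copies_r + copies_i)
        if end > params.chromosomes[tw.target_chrom].length:
            raise ParameterError(f"{tchrom}: twin cluster overflows chromosome")
        placed[tchrom].extend(copies_r + copies_i)
        cursors[tchrom] = end
        cluster_records.append(
            {"chrom": tchrom, "receptors": copies_r, "interleaved": copies_i,
             "intra_gap": src["intra_gap"], "twin_of": tw.source_cluster}
        )

    # 3. background fill: singletons, fillers, background SPUFs, SPUF families
    family_members: list[list[_Placed]] = []
    for ci, plan in enumerate(params.chromosomes):
        chrom = chrom_names[ci]
        items: list[_Placed] = []
        for _ in range(plan.n_singletons):
            prot, _sp = _make_receptor(prot_rng, 20, params.p_sub)
            desc, hits = _RECEPTOR_ANNOTATION
            items.append(_Placed(pos=0, protein=prot, kind="singleton",
                                 description=desc, domain_hits=list(hits)))
        for _ in range(plan.n_filler):
            items.append(_filler(prot_rng))
        for _ in range(plan.n_background_spuf):
            prot = make_spuf_protein(int(prot_rng.integers(60, 190)),
                                     secreted=False, rng=prot_rng)
            items.append(_Placed(pos=0, protein=prot, kind="spuf"))
        if ci == 0:
            for size, identity in params.spuf_families:
                founder = make_spuf_protein(int(prot_rng.integers(100, 190)),
                                            secreted=False, rng=prot_rng)
                group = [_Placed(pos=0, protein=founder, kind="spuf")]
                n_mut = round((1.0 - identity) * len(founder))
                for _ in range(size - 1):
                    prot = mutate_protein(founder, n_mut=n_mut, rng=prot_rng)
                    group.append(_Placed(pos=0, protein=prot, kind="spuf"))
                items.extend(group)
                family_members.append(group)
        order = layout_rng.permutation(len(items))
        cursor = cursors[chrom] + params.buffer
        lo, hi = params.background_gap
        for idx in order:
            item = items[idx]
            gap = int(layout_rng.integers(lo, hi))
            if item.kind == "singleton":
                gap += params.buffer
            item.pos = cursor + gap
            cursor = item.end
            if item.kind == "singleton":
                cursor += params.buffer
        if cursor > plan.length:
            raise ParameterError(
                f"{chrom}: background genes overflow chromosome "
                f"({cursor} > {plan.length})"
            )
        cursors[chrom] = cursor
        placed[chrom].extend(items[i] for i in order)

    # 4. assign ids in positional order and build GeneModels
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    for ci, chrom in enumerate(chrom_names):
        placed[chrom].sort(key=lambda p: p.pos)
        prev_end = -1
        for n, item in enumerate(placed[chrom], start=1):
            if item.pos <= prev_end:
                raise ParameterError(f"{chrom}: overlapping gene placement")
            prev_end = item.end
            item.gene_id = f"SYN{ci + 1:02d}G{n * 10:05d}"
            strand = "+" if layout_rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=item.gene_id, chrom=chrom, strand=strand,
                    start=item.pos, end=item.end,
                    description=item.description,
                    domain_hits=list(item.domain_hits),
                    protein_length=len(item.protein),
                )
            )
            proteins[item.gene_id] = item.protein

    # 5. record truth: receptors, clusters, super-clusters, SPUFs
    for chrom in chrom_names:
        for item in placed[chrom]:
            if item.kind in ("receptor", "singleton"):
                truth.receptor_ids.append(item.gene_id)
            if item.kind == "singleton":
                truth.singleton_receptor_ids.append(item.gene_id)
            if item.kind == "spuf":
                truth.spuf_ids.append(item.gene_id)
                if item.secreted:
                    truth.secreted_spuf_ids.append(item.gene_id)
            if item.kind == "truncated":
                truth.truncated_lrr_ids.append(item.gene_id)
    for k, rec in enumerate(cluster_records):
        truth.clusters.append(
            {
                "cluster_id": f"C{k + 1}",
                "chrom": rec["chrom"],
                "members": [r.gene_id for r in rec["receptors"]],
                "intra_gap": rec["intra_gap"],
                "span": [rec["receptors"][0].pos, rec["receptors"][-1].end],
            }
        )
    by_chrom: dict[str, list[dict]] = {}
    for c in truth.clusters:
        by_chrom.setdefault(c["chrom"], []).append(c)
    sc_n = 0
    for chrom in chrom_names:
        chain: list[dict] = []
        for c in sorted(by_chrom.get(chrom, []), key=lambda c: c["span"][0]):
            if chain and c["span"][0] - chain[-1]["span"][1] < 2_000_000:
                chain.append(c)
            else:
                if len(chain) >= 2:
                    sc_n += 1
                    truth.superclusters.append(
                        {"sc_id": f"SC{sc_n}", "chrom": chrom,
                         "clusters": [c2["cluster_id"] for c2 in chain]}
                    )
                chain = [c]
        if len(chain) >= 2:
            sc_n += 1
            truth.superclusters.append(
                {"sc_id": f"SC{sc_n}", "chrom": chrom,
                 "clusters": [c2["cluster_id"] for c2 in chain]}
            )

    for group in family_members:
        truth.paralog_families.append(
            {"members": [g.gene_id for g in group], "identity": None}
        )
    if params.twin is not None:
        src = cluster_records[params.twin.source_cluster]
        copy = cluster_records[-1]
        truth.twin = {
            "source_cluster": truth.clusters[params.twin.source_cluster]["cluster_id"],
            "copy_cluster": truth.clusters[-1]["cluster_id"],
            "identity": params.twin.identity,
            "receptor_pairs": [
                [a.gene_id, b.gene_id]
                for a, b in zip(src["receptors"], copy["receptors"])
            ],
            "spuf_pairs": [
                [a.gene_id, b.gene_id]
                for a, b in zip(src["interleaved"], copy["interleaved"])
                if a.kind == "spuf"
            ],
        }
        for pair in truth.twin["spuf_pairs"]:
            truth.paralog_families.append(
                {"members": list(pair), "identity": params.twin.identity}
            )

    # 6. designated co-regulated SPUF/receptor pair ("RISP story")
    pair_cluster = cluster_records[params.twin.source_cluster] if params.twin else cluster_records[0]
    risp = next(i for i in pair_cluster["interleaved"] if i.kind == "spuf" and i.secreted)
    paired_receptor = pair_cluster["receptors"][0]
    truth.inductions = {
        risp.gene_id: params.risp_fold_change,
        paired_receptor.gene_id: params.receptor_fold_change,
    }
    truth.baseline_overrides = {risp.gene_id: 500.0, paired_receptor.gene_id: 4500.0}
    very_high = [i for i in placed[chrom_names[0]]
                 if i.kind == "spuf" and not i.secreted][: params.n_very_high]
    for item in very_high:
        truth.baseline_overrides[item.gene_id] = 12_000.0

    # 7. chromosome sequence + planted conserved promoter block
    chrom_arrays = {
        chrom: _random_chromosome(seq_rng, params.chromosomes[ci].length)
        for ci, chrom in enumerate(chrom_names)
    }
    genome = Genome(
        chromosomes={c: params.chromosomes[i].length for i, c in enumerate(chrom_names)},
        genes=genes,
        proteins=proteins,
    )
    if params.promoter_block is not None:
        pb = params.promoter_block
        plen = -pb.offset
        index = genome.gene_index()
        gene_a = index[risp.gene_id]
        gene_b = index[paired_receptor.gene_id]
        block = _promoter_slice(chrom_arrays[gene_a.chrom], gene_a, plen)[: pb.length]
        mutated = _mutate_bases(seq_rng, block, pb.identity)
        _write_promoter_block(chrom_arrays[gene_b.chrom], gene_b, plen, pb.offset, mutated)
        truth.conserved_block = {
            "gene_a": gene_a.gene_id,
            "gene_b": gene_b.gene_id,
            "offset": pb.offset,
            "length": pb.length,
            "identity": 100.0 * pb.identity,
        }
    genome.genomic_seq = {
        chrom: arr.tobytes().decode("ascii") for chrom, arr in chrom_arrays.items()
    }
    return genome, truth


def _signal_len(protein: str) -> int:
    """Length of the generator-planted signal peptide (M + 2 basic + filler +
    8 core + G); recovered from the construction layout."""
    # core of 8 hydrophobics ends right before the terminal G of the peptide
    from .lrr import detect_signal_peptide

    sp = detect_signal_peptide(protein)
    return sp[1] if sp else 0


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def make_expression(
    genome: Genome,
    truth: SyntheticTruth,
    n_cond: int = 6,
    noise_sd: float = 0.2,
    seed: int | None = None,
    baseline_median: float = 500.0,
    baseline_sigma: float = 1.0,
):
    """Paired expression matrices (non-wounded, wounded) with planted inductions.

    Per-gene baselines are log-normal with the stated median; a planted
    induction multiplies the wounded-treatment mean by its fold change, so the
    expectation of the wounded/non-wounded mean ratio equals the planted fold
    change.  ``noise_sd`` is the standard deviation of per-cell log-normal
    multiplicative noise; 0 gives exact, noiseless intensities.
    """
    import pandas as pd

    if seed is None:
        seed = truth.seed
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 29])
    rb, rn = (np.random.default_rng(s) for s in ss.spawn(2))
    ids = [g.gene_id for g in genome.genes]
    base = baseline_median * np.exp(rb.normal(0.0, baseline_sigma, size=len(ids)))
    for i, gid in enumerate(ids):
        if gid in truth.baseline_overrides:
            base[i] = truth.baseline_overrides[gid]
    fc = np.array([truth.inductions.get(gid, 1.0) for gid in ids])
    shape = (len(ids), n_cond)
    if noise_sd > 0:
        noise_nw = np.exp(rn.normal(0.0, noise_sd, size=shape))
        noise_w = np.exp(rn.normal(0.0, noise_sd, size=shape))
    else:
        noise_nw = noise_w = np.ones(shape)
    cols = [f"h{18 + 6 * j}" for j in range(n_cond)]
    nw = pd.DataFrame(base[:, None] * noise_nw, index=ids, columns=cols)
    w = pd.DataFrame((base * fc)[:, None] * noise_w, index=ids, columns=cols)
    nw.index.name = w.index.name = "gene_id"
    return nw, w


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------


def write_bundle(
    genome: Genome,
    truth: SyntheticTruth,
    outdir: str | os.PathLike,
    n_cond: int = 6,
    noise_sd: float = 0.2,
) -> dict[str, str]:
    """Write the full synthetic bundle (GFF3, FASTAs, TSVs, truth JSON)."""
    from .promoter import extract_promoter

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gff3": os.path.join(outdir, "genome.gff3"),
        "proteins": os.path.join(outdir, "proteins.fasta"),
        "genome_fasta": os.path.join(outdir, "genome.fasta"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "promoters": os.path.join(outdir, "promoters.fasta"),
        "expression_nonwounded": os.path.join(outdir, "expression_nonwounded.tsv"),
        "expression_wounded": os.path.join(outdir, "expression_wounded.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    rio.write_gff3(genome, paths["gff3"])
    rio.write_fasta(genome.proteins, paths["proteins"])
    if genome.genomic_seq is not None:
        rio.write_fasta(genome.genomic_seq, paths["genome_fasta"])
        promoters = {
            g.gene_id: extract_promoter(genome, g.gene_id, length=1000)
            for g in genome.genes
        }
        rio.write_fasta(promoters, paths["promoters"])
    rio.write_annotation_table(genome, paths["annotation"])
    nw, w = make_expression(genome, truth, n_cond=n_cond, noise_sd=noise_sd)
    rio.write_expression(nw, paths["expression_nonwounded"])
    rio.write_expression(w, paths["expression_wounded"])
    truth.to_json(paths["truth"])
    return paths


__all__ = [
    "ParameterError",
    "ClusterSpec",
    "ChromosomePlan",
    "TwinSpec",
    "PromoterBlockSpec",
    "GenomeParams",
    "SyntheticTruth",
    "make_receptor_protein",
    "make_spuf_protein",
    "mutate_protein",
    "make_genome",
    "make_expression",
    "write_bundle",
]
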