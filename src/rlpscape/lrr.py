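"""Receptor annotation from protein sequence alone.

An LRR-RLP (leucine-rich-repeat receptor-like protein) is recognized here by
rule-based sequence heuristics: an N-terminal signal peptide, a tandem array
of more than 15 extracellular LRRs, a transmembrane span, and a short
cytoplasmic tail (no kinase).  The canonical extracellular architecture is
segmented into the classical Cf-9-like domains:

    A  signal peptide
    B  Cys-containing cap between the signal peptide and the first repeat
    C1 N-terminal LRR block
    C2 non-LRR "island" interrupting the repeat array
    C3 C-terminal (conserved) LRR block
    D  linker between the last repeat and the membrane
    E  optional acidic stretch (folded into D by default)
    F  transmembrane span
    G  cytoplasmic tail

LRR repeats are detected with a 24-column position-weight matrix over the
plant extracytoplasmic LRR consensus (``LxxLxxLxLxxNxLSGxIPxxLGx``); the
profile ships as a plain TSV so users can swap in their own.  Signal-peptide
and transmembrane calls use Kyte–Doolittle hydropathy rules.  These stand-ins
produce a deterministic, dependency-free binary verdict per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

Interval = tuple[int, int]

#: Kyte–Doolittle hydropathy scale.
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson–Robinson amino-acid background frequencies (renormalized).
BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}
_BG_TOTAL = sum(BACKGROUND.values())
BACKGROUND = {a: v / _BG_TOTAL for a, v in BACKGROUND.items()}

#: 24-residue plant extracytoplasmic LRR consensus; ``X`` = unconstrained.
LRR_CONSENSUS = "LXXLXXLXLXXNXLSGXIPXXLGX"
LRR_PERIOD = len(LRR_CONSENSUS)

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


def default_profile_path():
    return resources.files("rlpscape").joinpath("data/lrr_profile.tsv")


def load_lrr_profile(path=None) -> np.ndarray:
    """Load a 24 x 20 LRR profile and return per-position log-odds scores.

    The TSV has a header of single-letter amino acids, one ``background`` row
    of frequencies, and 24 position rows of probabilities.  Scores are
    ``log2(p / background)``; a 21st column of zeros absorbs unknown residues.
    """
    if path is None:
        with resources.as_file(default_profile_path()) as p:
            raw = np.loadtxt(p, dtype=str, delimiter="\t")
    else:
        raw = np.loadtxt(path, dtype=str, delimiter="\t")
    header = list(raw[0][1:])
    if header != list(AA_ORDER):
        raise ValueError("LRR profile columns must be in alphabet order " + AA_ORDER)
    bg = raw[1][1:].astype(float)
    probs = raw[2:, 1:].astype(float)
    if probs.shape != (LRR_PERIOD, len(AA_ORDER)):
        raise ValueError(f"LRR profile must have {LRR_PERIOD} position rows")
    logodds = np.log2(probs / bg)
    # extra column scores 0 for residues outside the 20-letter alphabet
    return np.hstack([logodds, np.zeros((LRR_PERIOD, 1))])


_DEFAULT_PROFILE: np.ndarray | None = None


def _profile(profile) -> np.ndarray:
    global _DEFAULT_PROFILE
    if profile is not None:
        return profile
    if _DEFAULT_PROFILE is None:
        _DEFAULT_PROFILE = load_lrr_profile()
    return _DEFAULT_PROFILE


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, len(AA_ORDER)) for a in seq], dtype=np.int64)


def window_scores(seq: str, profile=None) -> np.ndarray:
    """Log-odds score of every 24-residue window (vectorized PWM scan)."""
    L = _profile(profile)
    codes = _encode(seq)
    n = len(codes) - LRR_PERIOD + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(LRR_PERIOD):
        scores += L[j][codes[j : j + n]]
    return scores


def scan_lrr_repeats(seq: str, profile=None, score_min: float = 10.0) -> list[Interval]:
    """Greedy left-to-right scan for non-overlapping LRR repeats.

    A window is accepted when its profile log-odds score reaches
    ``score_min``; acceptance advances the scan by one full repeat period so
    repeats never overlap.  Returns sorted ``[start, end)`` intervals.
    """
    scores = window_scores(seq, profile)
    repeats: list[Interval] = []
    i = 0
    while i < len(scores):
        if scores[i] >= score_min:
            repeats.append((i, i + LRR_PERIOD))
            i += LRR_PERIOD
        else:
            i += 1
    return repeats


_SMALL = set("AGSC")
_BASIC = set("KR")


def detect_signal_peptide(
    seq: str,
    kd_min: float = 1.5,
    min_cleavage: int = 15,
    max_cleavage: int = 35,
) -> Interval | None:
    """Rule-based secretion signal-peptide call on the N-terminus.

    Requires, within the first 35 residues, at least one basic residue (K/R)
    at positions 2-6 (the n-region charge) and a hydrophobic stretch of >= 6
    residues with mean Kyte-Doolittle hydropathy above ``kd_min`` (the
    h-region).  The cleavage site is placed after the first small residue
    (A/G/S/C) that follows the hydrophobic core.  Returns ``[0, c)`` with
    ``15 <= c <= 35`` or ``None``; sequences shorter than 30 residues are
    never called.
    """
    if len(seq) < 30:
        return None
    head = seq[:35]
    if not any(a in _BASIC for a in head[1:6]):
        return None
    kd = np.array([KD.get(a, 0.0) for a in head])
    core_start = None
    for s in range(len(head) - 6 + 1):
        if kd[s : s + 6].mean() > kd_min:
            core_start = s
            break
    if core_start is None:
        return None
    core_end = core_start + 6
    while core_end < len(head) and kd[core_end] > kd_min:
        core_end += 1
    for j in range(core_end, len(head)):
        if head[j] in _SMALL:
            c = j + 1
            if c < min_cleavage:
                continue
            if c > max_cleavage:
                break
            return (0, c)
    return None


def detect_tm(seq: str, window: int = 19, kd_min: float = 1.6) -> Interval | None:
    """Highest-scoring hydropathy window in the C-terminal 40% of the protein.

    Returns the window as an interval iff its mean Kyte-Doolittle value is at
    least ``kd_min``; ties go to the leftmost window.
    """
    n = len(seq)
    if n < window:
        return None
    lo = int(np.ceil(0.6 * n))
    lo = min(lo, n - window)
    kd = np.array([KD.get(a, 0.0) for a in seq])
    csum = np.concatenate([[0.0], np.cumsum(kd)])
    starts = np.arange(lo, n - window + 1)
    means = (csum[starts + window] - csum[starts]) / window
    best = int(np.argmax(means))
    if means[best] < kd_min:
        return None
    s = int(starts[best])
    return (s, s + window)


def segment_domains(
    seq: str,
    sp: Interval | None,
    repeats: list[Interval],
    tm: Interval | None,
    island_min: int = 15,
    e_len: int = 0,
) -> dict[str, Interval]:
    """Assign the canonical A..G domain intervals from the detected parts.

    The repeat array is split at the largest inter-repeat gap of at least
    ``island_min`` residues: repeats before the gap form C1, the gap itself is
    the C2 island, repeats after it form C3.  With no qualifying gap all
    repeats are C1 and C2/C3 are absent.  Missing signal peptide or TM yields
    a partial map.
    """
    domains: dict[str, Interval] = {}
    if sp is not None:
        domains["A"] = sp
    if repeats:
        first = repeats[0][0]
        if sp is not None and sp[1] < first:
            domains["B"] = (sp[1], first)
        # largest inter-repeat gap >= island_min splits C1 | C2 | C3
        split = None
        best_gap = island_min - 1
        for k in range(len(repeats) - 1):
            gap = repeats[k + 1][0] - repeats[k][1]
            if gap > best_gap:
                best_gap = gap
                split = k
        if split is None:
            domains["C1"] = (repeats[0][0], repeats[-1][1])
        else:
            domains["C1"] = (repeats[0][0], repeats[split][1])
            domains["C2"] = (repeats[split][1], repeats[split + 1][0])
            domains["C3"] = (repeats[split + 1][0], repeats[-1][1])
        if tm is not None and repeats[-1][1] < tm[0]:
            d_end = tm[0] - e_len
            if repeats[-1][1] < d_end:
                domains["D"] = (repeats[-1][1], d_end)
            if e_len > 0 and d_end < tm[0]:
                domains["E"] = (d_end, tm[0])
    if tm is not None:
        domains["F"] = tm
        if tm[1] < len(seq):
            domains["G"] = (tm[1], len(seq))
    return domains


@dataclass
class ReceptorAnnotation:
    """Per-protein domain segmentation and the receptor verdict."""

    gene_id: str
    signal_peptide: Interval | None = None
    lrr_repeats: list[Interval] = field(default_factory=list)
    island: Interval | None = None
    domains: dict[str, Interval] = field(default_factory=dict)
    tm: Interval | None = None
    cytoplasmic_tail_len: int = 0
    is_lrr_rlp: bool = False
    c3d_seq: str = ""

    @property
    def lrr_count(self) -> int:
        return len(self.lrr_repeats)


def classify_receptor(
    annotation: ReceptorAnnotation, min_lrr: int = 15, tail_max: int = 30
) -> bool:
    """Receptor verdict: strictly more than ``min_lrr`` repeats, the canonical
    A (signal peptide) and F (transmembrane) domains present, and a
    cytoplasmic tail shorter than ``tail_max`` residues (the tail bound is
    what distinguishes an RLP from a kinase-bearing RLK)."""
    return (
        annotation.lrr_count > min_lrr
        and "A" in annotation.domains
        and "F" in annotation.domains
        and annotation.cytoplasmic_tail_len < tail_max
    )


def annotate_protein(
    gene_id: str,
    seq: str,
    profile=None,
    score_min: float = 10.0,
    min_lrr: int = 15,
    tail_max: int = 30,
    island_min: int = 15,
) -> ReceptorAnnotation:
    """Run the full detection cascade on one protein sequence."""
    sp = detect_signal_peptide(seq)
    repeats = scan_lrr_repeats(seq, profile=profile, score_min=score_min)
    tm = detect_tm(seq)
    domains = segment_domains(seq, sp, repeats, tm, island_min=island_min)
    tail_len = len(seq) - tm[1] if tm is not None else len(seq)
    c3d = ""
    if "C3" in domains and "D" in domains:
        c3 = domains["C3"]
        d = domains["D"]
        c3d = seq[c3[0] : c3[1]] + seq[d[0] : d[1]]
    ann = ReceptorAnnotation(
        gene_id=gene_id,
        signal_peptide=sp,
        lrr_repeats=repeats,
        island=domains.get("C2"),
        domains=domains,
        tm=tm,
        cytoplasmic_tail_len=tail_len,
        c3d_seq=c3d,
    )
    ann.is_lrr_rlp = classify_receptor(ann, min_lrr=min_lrr, tail_max=tail_max)
    return ann


def annotate_proteome(proteins: dict[str, str], **kwargs) -> dict[str, ReceptorAnnotation]:
    """Annotate every protein; returns ``{gene_id: ReceptorAnnotation}``."""
    profile = kwargs.pop("profile", None)
    profile = _profile(profile)
    return {
        gid: annotate_protein(gid, seq, profile=profile, **kwargs)
        for gid, seq in proteins.items()
    }


__all__ = [
    "KD",
    "AA_ORDER",
    "BACKGROUND",
    "LRR_CONSENSUS",
    "LRR_PERIOD",
    "load_lrr_profile",
    "window_scores",
    "scan_lrr_repeats",
    "detect_signal_peptide",
    "detect_tm",
    "segment_domains",
    "ReceptorAnnotation",
    "classify_receptor",
    "annotate_protein",
    "annotate_proteome",
]
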