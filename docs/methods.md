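# Methods

This note documents the models and procedures implemented in `rlpscape`, the
reasoning behind the default parameters, what the synthetic-data generator
does and does not emulate, and the package's numerical conventions.

## Coordinates and data model

All intervals are 0-based, half-open, on the forward chromosome strand;
GFF3's 1-based inclusive convention is converted at the I/O boundary and
nowhere else, so interval length is `end - start` throughout.  A gene's span
is the outermost gene-feature interval — the analysis operates at gene-model
granularity and never descends into mRNA/CDS structure.  Description
matching is case-insensitive and whitespace-normalized.

## Receptor annotation

An LRR-RLP is called from protein sequence alone, with no external
predictors, by four rule-based detectors:

* **Signal peptide.**  Within the first 35 residues: at least one K/R at
  positions 2–6 (n-region charge), a hydrophobic stretch of ≥6 residues with
  mean Kyte–Doolittle hydropathy > 1.5 (h-region), and a cleavage site after
  the first small residue (A/G/S/C) following that core, constrained to
  15–35 aa.  This is a deliberately transparent stand-in for black-box
  secretion predictors: the analysis only ever consumes the binary
  present/absent flag.
* **LRR repeats.**  A greedy left-to-right scan with a 24-column
  position-weight matrix over the plant extracytoplasmic LRR consensus
  `LxxLxxLxLxxNxLSGxIPxxLGx` (x = background).  A window whose log₂-odds
  score reaches `score_min` (default 10 bits) is accepted and the scan jumps
  one full period, so repeats never overlap.  At the default cut-off a
  perfect consensus copy scores ≈36 bits while random background windows
  average ≈−17 bits (SD ≈4), so false repeats in unrelated proteins are
  practically impossible and repeats carrying the generator's default 15%
  substitution noise are still detected with >99% per-repeat sensitivity.
  The profile ships as a plain TSV (`rlpscape/data/lrr_profile.tsv`,
  consensus weight 0.7 mixed with 0.3 background) and can be swapped.
* **Transmembrane span.**  The highest-scoring 19-residue Kyte–Doolittle
  window in the C-terminal 40% of the protein, reported iff its mean is
  ≥1.6.  Restricting to the C-terminus prevents the hydrophobic repeat array
  from shadowing the genuine membrane anchor.
* **Domain segmentation.**  A = signal peptide; B = gap to the first repeat;
  the repeat array is split at the largest inter-repeat gap ≥15 aa into C1
  (island) C3; D runs from the last repeat to the membrane; F is the TM
  span; G the cytoplasmic tail.  An acidic E domain can be split out of D by
  setting `e_len > 0`; by default it is folded into D, since nothing
  downstream distinguishes them.

The verdict is *receptor* iff strictly more than `min_lrr` = 15 repeats were
found, domains A and F are present, and the tail G is shorter than 30 aa.
The canonical-domain requirement is operationalized as {A, F, G bound, ≥1
LRR block}: B, C2 and E are annotated but not required, because their
presence varies across genuine receptors and no per-domain test exists.  The
repeat bound is strict (16 repeats pass, 15 do not) and configurable; the
30 aa tail bound is what separates an RLP from a kinase-carrying RLK.  The
verdict is monotone in the number of detected repeats.

## Cluster architecture

Receptor genes on one chromosome chain into a **cluster** by single linkage
when consecutive boundary gaps (`next.start − prev.end`) are ≤50 kb; chains
of ≥2 genes are clusters, the rest singletons.  The "within a 50 kb stretch"
rule is interpreted as a per-gap bound, not a total-span cap — clusters of
up to seven members are impossible under a hard 50 kb span.  The gap bound
is inclusive (a 50 kb stretch includes its endpoint), whereas
**super-clusters** chain cluster spans at gaps *strictly* below 2 Mb
("separated by less than 2 Mb").  Both bounds are configuration fields.

An **associated gene** is any gene whose span overlaps the window padding a
receptor by 25 kb on both sides (any-overlap of half-open intervals, so a
gene ending exactly 25 000 bp away is outside).  Receptors are never
associated genes — the associated set is by construction the non-receptor
content of receptor neighbourhoods.  Per-receptor lists (with signed
distances) and the deduplicated union are both reported, together with the
mean ± SD of per-receptor counts: the two statistics answer different
questions (genes shared by two receptor windows count once in the union but
twice in the mean) and are not mutually derivable.

The architecture summary reports the share of the family contained in the
k largest clusters-or-super-clusters (a super-cluster counts as one unit;
default k = 9), rounded half-up to an integer percentage.

## SPUF analysis

A **SPUF** is a protein strictly shorter than 200 aa whose gene has an
empty/unknown description (whitelist: "", "unknown", "hypothetical protein",
"expressed protein"; configurable — annotation pipelines differ in how they
spell "no annotation") and no protein-domain hits.  Secretion is the
signal-peptide flag above.

Paralogy is scored by Smith–Waterman local alignment (BLOSUM62, gap open 11,
extend 1) normalized by the shorter sequence length; a pair is paralogous at
normalized score ≥1.0.  This emulates a stringent Blastp E-value cut at desk
scale without a database dependency; the exact Karlin–Altschul calibration
is intentionally out of scope and the cut-off is exposed.  Random 100-aa
pairs score ≈0.3–0.6 normalized while 80%-identity relatives score ≈3–4, so
the operating point is far from both failure modes.  Families are connected
components of the paralogy graph over the query set; homologs "in another
species" are counted against a user-supplied second proteome with the same
score.  Genes encoding 1–15 LRR repeats (receptor relics/truncations) are
tagged as a separate class with no receptor verdict.

**Enrichment.**  Three percentages are reported: SPUFs among all associated
genes, SPUFs among all non-receptor genes (genome background), and SPUFs
among the gene content of the k largest units with receptors excluded.  On
top of the raw percentages — which is all the original style of analysis
prints — a permutation test relabels the receptor anchors uniformly among
all gene positions, recomputes the associated-SPUF percentage, and reports
`p = (1 + #{perm ≥ observed}) / (1 + n_perm)`.  The add-one form keeps p in
(0, 1] and super-uniform under the null (verified by simulation); the
permuted statistic treats the former receptors as ordinary genes, which is
the exchangeability the null requires.  The permutation test is flagged in
every report as an addition beyond the source analysis.

## Phylogeny vs. genomic location

Only the conserved C3–D region of each receptor is alignable family-wide, so
trees are built from pairwise global-alignment identities of the
concatenated C3+D sequences (end gaps free and excluded from the identity
denominator), with distance `d = 1 − identity/100`.  The tree is canonical
neighbor joining: Saitou–Nei Q-criterion, standard branch-length formulas,
ties broken by the smallest (i, j) index pair, negative branch lengths
clamped to zero, and an explicit three-taxon closed form at the end.  NJ
recovers additive metrics exactly (tested to 1e-9 against path-length
oracles and cross-checked against an independent NJ implementation).

Concordance between phylogeny and genomic location cuts the tree at its
k − 1 longest internal branches (ties broken by the lexicographically
smallest leaf below the branch) and scores the leaf partition against
cluster labels with the adjusted Rand index.  k is a parameter, defaulting
to the number of genomic clusters — the natural cut when the question is
"do clusters form clades"; isolating a single-leaf clade is impossible by
internal-edge cuts, so singletons are excluded from the score.  One caveat
discovered on synthetic data and expected in real data: when a cluster was
duplicated *recently* relative to within-cluster divergence (the
twin-chromosome scenario: a 96%-identity copy over ~10% within-cluster
divergence), each gene's nearest relative is its ortholog on the twin
chromosome, the two clusters interleave into one clade, and cluster-label
concordance saturates near 0.7; labelled by duplication lineage the
concordance returns to 1.  This mirrors the real pattern where a cluster
and its twin-chromosome copy share one clade.

## Expression analysis

Each treatment's level is the equal-weight mean over its (default six)
conditions; no between-array normalization is applied, matching the design
where both treatments come from identical array platforms.  A gene is
*expressed* when either treatment mean exceeds the background threshold
(default 200 intensity units — the source analysis never prints its
threshold, so this conservative default is exposed and echoed in output
headers).  The category is a step function of the larger treatment mean:
≤4000 low/medium, 4000–10000 higher, >10000 very high.  Fold change is
`(mean_W + c) / (mean_NW + c)` with pseudocount c = 1.0 to stabilize ratios
at low intensity; induction bands are *slight* at FC ≥ 1.5 and *strong* at
FC ≥ 5, chosen so that "slightly (<2-fold)" and "strongly (~10-fold)"
induced genes land in the intended bands with margin.  With c → 0 the fold
change is exactly scale-invariant.  OLS regression of wounded on
non-wounded means (per gene set) uses the closed-form solution; a constant
response returns slope 0, r² 0 rather than NaN.

Co-expressed pairs are, per cluster, every (member receptor, associated
SPUF) pair with both genes above background; when ≥4 paired conditions
exist, the Pearson correlation across all paired conditions of both
treatments is attached.

## Promoter conservation

Promoters are the 1 kb upstream of the translation start, strand-aware,
truncated with a warning at chromosome edges; offsets are reported relative
to the ATG (negative), the only anchor available without TSS annotation.
Conservation between two promoters is scanned without alignment: for every
relative offset within a ±50 bp band the sequences are laid side by side and
100-bp windows every 10 bp with ≥85% identity are merged into blocks.
Terminal 10-bp chunks of a merged block below 50% identity are trimmed —
they are window overhang into unrelated sequence (random DNA matches at
~25%), not block sequence — and the block identity is then recomputed over
the trimmed extent; blocks shorter than 200 bp or below the identity floor
are discarded, and near-duplicate blocks from neighbouring offsets collapse
onto the best-identity one.  The banded scan assumes co-linear promoter
elements (no large indels between the two copies), which is the regime the
method targets; defaults (200 bp, 85%) are set permissive of a ~300 bp,
~90% target and all are exposed.  On random 1 kb pairs the expected window
identity is 25% (SD ≈4), some 14 standard deviations below the floor, so
false blocks are effectively impossible.

## The synthetic-data generator

`rlpscape.simulate` is first-class, tested code that plants every structure
the analysis looks for, with the planted truth emitted alongside:

* **Layout.**  The default (`GenomeParams.default()`) builds three 3 Mb
  chromosomes with ~280 genes: four receptor clusters (5+4 on chromosome 1,
  1.5 Mb apart — one super-cluster; 4 on chromosome 2; and a copy of that
  cluster on chromosome 3 at 96% protein identity, the twin-chromosome
  scenario), three singleton receptors, one SPUF interleaved in every
  intra-cluster gap (10–12 kb exact gaps), annotated filler genes, ~18
  background SPUFs per chromosome placed ≥60 kb away from any receptor, a
  planted 4-member SPUF paralog family at 80% identity, and two
  truncated-LRR relic genes inside a cluster.  Placement uses the stated
  gaps exactly; anything that does not fit raises a parameter error.
* **Proteins.**  Receptors follow the full A–G construction: signal peptide
  (M + 2 basic + hydrophobic core + glycine cleavage site, 20–28 aa),
  Cys-pair cap, n tandem LRR consensus copies at per-position substitution
  rate `p_sub` (default 0.15), a 25-aa island after repeat ⌈0.75 n⌉, a 20-aa
  acidic linker, a 21-aa hydrophobic TM and a <30 aa tail.  Cluster members
  diverge 5% from a cluster founder; duplicated copies mutate an exact
  count of residues to hit the target identity.  Signal peptides are
  protected from divergence mutations (purifying selection on targeting
  signals), and non-secreted proteins start with strictly hydrophilic
  N-termini — a deliberate idealization that makes the planted secreted
  subset exactly recoverable and cleanly separates detector calibration
  from generator noise.
* **Sequence and promoters.**  Chromosomes are i.i.d. random DNA; gene
  length is 3× protein length (no introns — codon-level realism is a
  non-goal).  The designated RISP-like SPUF and its adjacent receptor share
  a planted conserved block: 300 bp at 90% identity (exact mutation count)
  spanning offsets −1000…−700 in both promoters.
* **Expression.**  Per-gene baselines are log-normal (median 500, σ = 1.0 —
  calibrated so the 4000/10000 category bounds are populated), with planted
  overrides: the RISP analogue at 500 with a 10-fold wounding induction,
  its receptor at 4500 with 1.8-fold, three very-high SPUFs at 12 000.
  Cells carry log-normal multiplicative noise (σ configurable); the
  expected wounded/non-wounded mean ratio equals the planted fold change,
  and σ = 0 reproduces it exactly.
* **Determinism.**  All randomness flows from one integer master seed
  through independent spawned streams per artifact (layout, proteins,
  chromosome sequence, expression), so identical seeds give byte-identical
  bundles and adding genes does not perturb expression draws.

**What passing tests do and do not show.**  The generator emulates the
*statistical geometry* the pipeline assumes — gap structure, size/annotation
contrasts, repeat architecture, promoter co-linearity — not real genomes:
no introns or UTRs, no annotation errors or chimeric gene models, no
GC/repeat structure in the DNA, idealized N-termini, and array noise that is
purely multiplicative log-normal.  Exact recovery on synthetic data
therefore validates the algorithms and their thresholds against their own
stated assumptions; on real annotation the same thresholds inherit the
usual uncertainty of gene models and functional descriptions (the original
analysis needed manual correction of a handful of models, which is exactly
the kind of noise the generator omits).

## Problem sizes and numerical conventions

The test suite and the acceptance script run the reference layout
(~280 genes, 20 receptors), 50–100 replicate seeds for the stochastic
recovery checks, 100 random additive matrices (6–10 taxa) for NJ, 1000
permutations for the headline enrichment p-value and 200×200 for its null
calibration — sizes chosen so the whole analysis reproduces in minutes on a
single core while keeping every Monte-Carlo check comfortably away from its
threshold.  Percentages print with half-up rounding (one decimal, or
integer for family-share figures).  Ties are broken deterministically
everywhere (smallest index pair in NJ, leftmost window in TM detection,
lexicographic leaf sets in tree cutting), so every report is reproducible
byte-for-byte from (inputs, config, seed).

## Known limitations

* The signal-peptide and TM heuristics trade sensitivity on real proteomes
  for transparency and determinism; on borderline real sequences a modern
  predictor will disagree.
* The length-normalized alignment score is not an E-value; extremely short
  or compositionally biased queries shift its operating point.
* The banded promoter scan cannot see conserved blocks displaced by more
  than the band width or broken by indels larger than the window step.
* Clade/locus concordance is undefined for singleton receptors (no internal
  edge isolates a single leaf) and saturates below 1 for very recent
  cluster duplications, as discussed above.
* The expression model tests mean-ratio recovery, not differential-expression
  inference with replicate variance models, which is out of scope.
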