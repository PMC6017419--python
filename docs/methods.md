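# Methods

## Problem setting

Given a labeled corpus of RNA-protein chain pairs (label 1 = interacting,
0 = not), learn a classifier that predicts interaction for new pairs.
Both chains carry two information channels: the residue sequence and the
secondary structure. `rpimer` encodes each channel as a string over a
small discrete alphabet and derives two families of features from those
strings.

## Encodings

**RNA sequence.** Upper-cased, T→U, and every symbol outside {A,U,C,G}
mapped to X, the conventional marker for an unknown nucleotide. The map is
total and idempotent, so arbitrary input FASTA is accepted.

**RNA structure.** Nested dot-bracket structures (pseudoknot tiers are
rejected) are decomposed into secondary-structure elements (SSEs):

* *Stem* — a maximal run of stacked pairs (i,j),(i+1,j−1),…; any
  interruption, even a 1-nt bulge, ends the run and starts a new Stem.
  Stem length is counted in base pairs (a flag switches to nucleotides).
* *Loop* — a hairpin interior; length in unpaired nucleotides.
* *InternalLoop* — unpaired runs on both strands between two helices,
  one element, length = sum of both runs.
* *Bulge* — an unpaired run on exactly one strand between two helices.
* *Other* — exterior strands and multiloop interiors, one element per
  maximal unpaired run.

Each element receives a length class from per-type integer cutoffs
(defaults: Stem 1–3/4–5/≥6 bp, Bulge 1/2/≥3, Loop 1–4/5–6/≥7, Internal
1–2/3–5/≥6, Other 1–2/3–5/≥6). `fit_length_classes` re-estimates cutoffs
from observed element lengths by exhaustive search over integer cutoff
pairs, minimizing the maximum deviation of any class mass from 1/3
(ties toward smaller cutoffs; constant lengths collapse to all-Short).
Class boundaries are therefore approximately the empirical tertiles, so
the three classes are near-equiprobable on the fitting corpus.

Multiloop interiors are classed Other rather than as loops: they are
"non-classified single strands" from the element taxonomy's viewpoint.
Stems measured in base pairs keep the default stem cutoffs meaningful for
helices; both choices are configurable because the taxonomy itself does
not force them.

**Protein sequence.** The 20 amino acids reduce to 7 groups by dipole
moment and side-chain volume: {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W},
{R,K}, {D,E}, {C}, serialized as digits 1–7. Non-canonical residues
(B, Z, X, U, \*) are dropped with a logged warning and a 1-based position
map so structure strings can be realigned.

**Protein structure.** Backbone (φ, ψ) dihedrals — computed from N/CA/C
coordinates (IUPAC sign convention, cross-checked against Bio.PDB) or read
from a TSV — are discretized by a codebook of 7 labeled rectangle sets on
the (φ, ψ) torus, serialized as letters a–g so the two 7-symbol protein
alphabets stay disjoint. The shipped default codebook is a **synthetic
stand-in**: round-number rectangles around the conventional basins
(right-handed helix, β, PPII, left-handed helix, extended ψ-tail,
turn-like, residual fallback). Any published clustering can be substituted
as a TSV via `load_codebook`; regions may wrap the ±180° seam, first
matching region wins, and points outside all regions take the fallback
code.

## Feature-based model

Per RNA, the relative frequency of each of the 75 joint (nucleotide, SSE
type, length class) symbols; per protein, of each of the 49 (group, code)
combinations; per pair, the 124-dim concatenation. Frequencies
(count/length) are the default because they remove chain-length
confounds; raw counts sit behind a flag since either normalization is
defensible. Feature order is fixed lexicographically (A<C<G<U<X; Stem <
Loop < InternalLoop < Bulge < Other; Short < Medium < Long; group 1–7;
code a–g).

## String-based models and richness

For k = 2…5, every substring β is counted with overlap over the
positive-pair corpus (γ) and negative-pair corpus (λ) of each of the four
representations. A chain in m pairs is counted m times: richness compares
pair populations, not unique chains. The smoothed richness
R(β) = (γ+1)/(λ+1) satisfies R(a,b)·R(b,a) = 1, is strictly monotone in
each count, and equals 1 when both counts are 0. Selection keeps β with
log₂ R ≥ τ (positive set) or ≤ −τ (negative set); default τ = 1 requires
a two-fold smoothed imbalance, comfortably away from the uninformative
R ≈ 1 region. An `exclusive` mode instead keeps substrings seen only on
one side. Feature values are the k-mer's overlapping occurrence count in
the pair's string, divided by string length (raw counts behind a flag).
Features are individual selected k-mers per representation, concatenated
in model order (QQ, SS, QS, SQ; QSQS = all four blocks) — not the
cross-product of RNA × protein k-mers, which would square the
dimensionality.

Counting is one hash-tally pass per k over each string: linear in total
corpus length for the fixed k-range, and bit-identical (tested against an
independent nested-loop oracle) to a naive sliding-window count. The
contract is the complexity and oracle equality, not a specific index
structure.

The SSE enrichment report counts the 15 per-element codes over positive
vs negative structure strings; whole-corpus columns use the plain ratio
γ/λ (∞ flagged when λ = 0), top-k-mer-list columns use the smoothed
richness; a dominance label requires |log₂ ratio| > margin (default 0.5)
with the same sign in both columns.

## Classification and evaluation

RBF-kernel SVM (reference parameters C = 2⁵, γ = 2⁻⁷ for string models;
C = 2⁷, γ = 2⁻¹¹ for the 124-dim descriptors) and a 200-tree random
forest, via scikit-learn. Evaluation is stratified 10-fold CV with seeded
shuffling; confusion counts are pooled over folds; AUC is the rank-based
(Mann–Whitney) area over pooled scores (SVM decision values, RF positive
vote fractions), with the fold-mean AUC reported alongside since pooling
conventions vary. PRE, REC, ACC, FSC follow the standard confusion-count
formulas; zero-denominator metrics are reported as 0 with an explicit
flag rather than NaN so reports serialize cleanly.

## Synthetic corpora

`rpimer.synth` generates labeled pairs from a seed: i.i.d. uniform
background sequences (the simplest null, under which richness
concentrates near 1 absent signal), motifs overwritten at a uniform
position with probability p_pos in positives / p_neg in negatives
(defaults 0.9 / 0.05), structures from a stochastic nested grammar
(stems of 1–3 stacked pairs extended or interrupted by bulges, internal
loops and multiloop branch points with configurable probabilities,
hairpin loops ≥ 3 nt, exterior single strands), and dihedrals sampled
from a mixture over codebook regions (default dominated by helix and β).
Default corpus sizes used in the pipeline-recovery tests: 200 positive +
200 negative pairs, RNA 80–160 nt, protein 120–250 aa.

What the generator does *not* emulate: realistic base composition or
thermodynamic structure, shared chains across pairs, homology, or any
coupling between structure and label. Passing tests therefore demonstrate
that the machinery recovers planted sequence-level signal and that every
stage honors its contracts — not that benchmark-level accuracy transfers
to real interaction data.

## Numerical and degenerate-input choices

Angles live in (−180°, 180°]; +180 and −180 are the same torus point.
Empty strings yield all-zero feature vectors. Chain termini and neighbors
of residues with missing backbone atoms carry no complete (φ, ψ) pair and
are omitted with a position map; the 49-dim protein vector aligns group
and code strings on shared residue indices. Dot-bracket parse errors
carry the 1-based offending position. All randomness flows from explicit
integer seeds; same seed + same inputs reproduces artifacts
byte-for-byte.

## Known limitations

* With frequency-normalized string features, the reference SVM kernel
  width (γ = 2⁻⁷) underfits: on the 400-pair planted corpus it ranks
  well (pooled AUC 0.98) but classifies at ACC ≈ 0.77, while the random
  forest reaches ACC ≈ 0.93 and an SVM on raw counts ≈ 0.95. The
  reference (C, γ) pairs were evidently tuned for a particular feature
  scaling; rescale or switch classifier when normalization changes.
* The default Ramachandran codebook is a stand-in, not a published
  clustering; substitute a real region table for structure-sensitive work.
* Pseudoknots and non-nested structures are rejected, and protein
  secondary structure is never predicted from sequence — dihedrals (or
  code strings) must be supplied.
* The optional RNAfold wrapper (`RNAfold` on PATH) is a convenience for
  users without structures; no test or default path depends on it.
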