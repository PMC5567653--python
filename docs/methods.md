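# Methods

## The CSI model

A conserved signature indel is operationalised as a cluster of
overlapping gap runs (an *indel locus*) that satisfies two rules:

1. **Flank conservation.**  Each side of the locus must contain at
   least `min_conserved = 5` conserved columns within a window of
   `window = 30` columns.  The criterion in the source methodology is
   "5–6 conserved residues in the neighbouring 30–40 amino acids"; we
   take the permissive ends (5 within 30) as defaults and expose both
   as parameters.  A column counts as conserved when its consensus
   residue frequency over canonical residues is at least
   `threshold = 0.8` and no *vetoing* row is gapped there.  The veto
   set is the rows that are un-gapped at the locus: rows carrying the
   indel may legitimately have disturbed flanks, so their gaps do not
   veto, but their residues still enter the consensus.  For a
   variable-length insert locus every carrier row has some gap inside
   the hull and the veto set can be empty; conservation then rests on
   the consensus criterion alone.
2. **Group specificity.**  With rows partitioned by class (or isozyme,
   or custom groups), each group's state at the locus is summarised by
   its residues-present count (`hull width − gaps`).  The *background*
   is whichever side — groups uniformly carrying the full segment, or
   groups uniformly lacking it — contains more groups (ties fall back
   to row counts; a tie on both is unclassified).  The remaining
   groups are the signature carriers: one carrier ⇒ `group_specific`;
   several with identical lengths ⇒ `shared_by_groups`; several with
   different uniform lengths ⇒ `paired_lengths`.  Insert lengths may
   vary within a carrier group (reported as a min–max range, e.g.
   16–24); deletion lengths must be group-uniform.  `exceptions`
   (default 0) allows that many rows to deviate before a locus is
   declared unclassified; the default reads "specifically present" as
   exceptionless.

Polarity (`insert_relative` / `deletion_relative`) is purely relative
to the compared set: the eukaryotic DGK catalytic domain has no
suitable outgroup, so no ancestral state is inferred, and every report
carries that caveat.  Terminal gap runs are never candidates (they
reflect fragment boundaries).  Calls match a truth or reference locus
when the column hulls overlap within ±3 columns, reflecting the
acknowledged placement uncertainty of indels between diverged
sequences.

## Phylogeny

Distances are pairwise maximum-likelihood estimates under the JTT
model: the 190 published exchangeabilities and equilibrium frequencies
are embedded as integers (checksum 18873, asserted in the tests), the
rate matrix is normalised to one expected substitution per site per
unit time, and `d(i,j)` maximises `∑_ab N_ab log P_ab(t)` over `t ∈
[0, 10]` with pairwise gap deletion (saturated pairs cap at 10 with a
warning).  The scalar optimiser is a coarse log-spaced grid followed by
bounded Brent refinement; the all-pairs matrix uses the same grid with
parabolic refinement in log-t, vectorised over pairs (the two agree to
well under 1%).  Trees are Saitou–Nei neighbour joining with
Q-criterion ties broken on the lowest index pair and negative branch
lengths clamped to zero; NJ is exact on additive matrices (tested
against brute-force topology enumeration and scikit-bio).  Bootstrap
supports are the percentage of column-resampled replicates containing
each internal bipartition of the point tree; midpoint rooting places
the root halfway along the longest leaf-to-leaf path, ties broken on
the lexicographically smallest leaf pair.  The optional
`tree_log_likelihood` is standard Felsenstein pruning with no rate
heterogeneity; it exists for relative comparisons of fixed topologies,
not to reproduce any particular search engine's likelihood.  A full ML
tree search is deliberately out of scope: the reproducible surface of
the published analysis is topology-level (class clusters, κ/ζ
polyphyly, ε/θ rooting order), which distance NJ recovers
deterministically.

## Simulator

`simulate_family` draws a root sequence from JTT equilibrium, evolves
it along the guide tree by exact per-site Gillespie simulation
(state-dependent exponential waiting times, so realised substitution
counts per branch are recorded and are Poisson-consistent with branch
length), and then plants indels post hoc: an insert is a block of
columns simulated only over its clade's subtree (segments within a
block model clade-internal length variation, such as a secondary
expansion in a subclade); a deletion gaps existing columns in the
clade's rows.  Planting on the stem rather than via a stochastic indel
process trades indel-model realism for exact ground truth, which is
what a scanner benchmark needs.  Flank-mask columns around each
planted locus are held invariant; decoy gap runs (single-row,
non-clade-consistent) can be planted with or without scrambled flanks.
Draw order is fixed (root, core branches in preorder, insert segments
in listed order, decoy scrambles) so output is byte-deterministic per
seed.

## The bundled DGK-like fixture

`make_dgk_like_fixture` emulates the study conditions of the published
catalytic-domain analysis: 50 sequences (10 isozymes × 5 vertebrate
groups), an alignment of exactly 364 columns with 260 gap-free
columns, and the signature inventory with its printed lengths and
class assignments (16–24 aa class I insert with α/γ subclade
extensions; 2/4 aa paired class I/IV inserts; 1 aa shared class I+IV
deletion; 5 aa and 2 aa class I deletions; 8 aa class III deletion;
1–2 aa ε/θ events; a 3/4 aa paired ε/θ deletion locus; the ATP motif
G-A-G-T-L-G with Ser replacing the last Gly in mammalian κ only).
Twelve single-row decoy runs account for the remaining gapped columns,
as non-signature alignment noise does in real alignments; they are
rejected by the specificity stage.  The column arithmetic
(364 = 328 core + 36 insert columns; 104 gapped = 36 + 23 deletion +
45 decoy) is asserted at generation time.

The guide tree encodes the qualitative structure the analysis should
recover: five classes on long (0.24) stems; κ and ζ each split into
two clusters separated by 0.14 edges (so they branch polyphyletically
while δ+η and ι stay monophyletic); ε and θ on the deepest stems above
a long (0.55) junction edge; and a 0.005 edge joining classes I and
IV.  Two geometry points deserve note.  First, the invariant flank
masks (106 of the 364 columns) dilute per-column divergence, so
uniform-rate JTT distances read roughly half the nominal branch-length
scale and compress deep paths further; branch lengths were chosen,
and verified across >40 simulation seeds before the tests were frozen,
so that every marker edge stays clearly above that noise floor.
Second, the bootstrap support of the I+IV association is dominated by
whether the simulation happens to place a supporting substitution on
its tiny connecting edge: across seeds it ranges from ~15 to ~85 with
a mean near 50, matching the weakly supported association (51%) the
fixture emulates — it is a realisation-level quantity, not a fixed
property of the geometry.

## Classifier

Smith–Waterman local alignment is delegated to Biopython's
`PairwiseAligner` with BLOSUM62 and BLAST-convention affine gaps (a
gap of length k costs 11 + k, i.e. `open_gap_score = −12`,
`extend_gap_score = −1`); the test suite checks it against exhaustive
alignment enumeration on short strings.  `U` is scored as `C`
(BLOSUM62 has no selenocysteine column).  The confidence thresholds —
score ≥ 40% of the query self-score, margin over the runner-up isozyme
≥ 5% — are heuristics, exposed as parameters, since a similarity
survey offers no principled cutoff.  The presence/absence matrix marks
`+` when every surveyed species in a taxon group has a confident
assignment for an isozyme, `+/-` when some do, `-` when none do.

## Problem sizes and tolerances

The default test and acceptance runs use the 50-taxon fixture with 100
bootstrap replicates, a 20-seed scanner benchmark, pairwise-distance
recovery at sequence length 10⁴ (tolerance ±0.02 around t = 0.1,
about 5 standard errors), pruning-vs-enumeration agreement at 1e-10,
and 40 classifier queries evolved at 0.2 substitutions/site.  These
sizes keep a full run in the tens of seconds while leaving every
assertion far from its noise floor.

## What passing tests do and do not show

The simulator produces clean, column-consistent alignments with
invariant flanks and exactly clade-consistent indels.  Real alignments
add alignment error, rate heterogeneity across sites, lineage-specific
rate variation, and flanks that are conserved rather than frozen.
Perfect scanner precision/recall on the fixture therefore validates
the bookkeeping and the classification logic, not robustness to
misalignment; the ±3-column matching tolerance and the exposed
`exceptions`/threshold parameters are the knobs a real analysis would
loosen.  Likewise the phylogeny checks validate that NJ+bootstrap
recovers structure that is genuinely present at these depths, not that
it could resolve the much older divergences of a real family under
rate heterogeneity the distance model ignores.

## Known limitations

No rate heterogeneity (gamma categories) in distances, likelihood or
simulation; no stochastic indel process; no ML topology search; no
E-value statistics in the classifier; alignment construction is out of
scope (alignments are consumed, not built).
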