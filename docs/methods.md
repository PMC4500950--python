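# Methods

This note documents the models, parameter choices and numerical decisions
behind `chromnet`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and inputs

All genomic intervals are BED-native: 0-based, half-open `[start, end)`.
Conversions from 1-based inclusive inputs shift the start by −1 exactly
once, at read time. Peak files may be plain BED (summit = interval
midpoint) or narrowPeak (summit from column 10 when present and
non-negative; narrowPeak writes −1 for "no summit called"). Extra columns
beyond those named in the readers are ignored. Genes lacking a strand are
treated as '+' with a logged warning.

## Network construction

Binding sites are `tfbs_width_bp` (default 40) windows centered on peak
summits, clipped at the chromosome origin. A site is kept when it overlaps
a DNase hypersensitive site by ≥ 1 bp, and a TF→gene edge exists when a
retained site overlaps the gene's promoter (`promoter_up_bp` = 500,
`promoter_down_bp` = 500, strand-aware) by ≥ 1 bp. Overlap-vs-containment
is genuinely ambiguous for both filters; ≥ 1 bp overlap is the default
because a 40-bp site against a 1-kb promoter makes the distinction minor
and overlap is the standard convention — a `containment` flag switches to
full containment for both. One TSS per gene id is assumed; callers wanting
per-transcript promoters pre-expand the annotation. Self-edges (a TF bound
at its own promoter) are kept in the network but excluded from triad
enumeration.

## Promoter chromatin states

Four broad states are used: strong activity, weak activity, poised
(bivalent) and repressed. The default collapse of a 15-state vocabulary
maps active promoter and strong enhancers to strong activity, weak
promoter/enhancers to weak activity, the poised promoter to poised, and
every remaining label (Polycomb repressed, heterochromatin/low signal,
insulator, the transcription-associated states, repetitive/CNV) to
repressed. The placement of transcription-associated labels is debatable,
so the map is configuration, not code.

Assignment maximizes base-level fold enrichment `(aₛ/b)/(cₛ/d)`; the
genome-wide normalization keeps rare states competitive. Numerical edge
cases: a state absent genome-wide is skipped (enrichment undefined, logged);
a promoter with zero segment coverage is labeled repressed ("low signal")
with a warning; exact ties are broken by the fixed priority strong >
poised > weak > repressed, chosen to favor the most information-rich
labels and keep output deterministic.

## Colored triad census

Structures are the 13 weakly connected 3-node digraphs (no self-loops,
antiparallel pairs allowed). A colored class is canonical under the joint
minimization of (structure code, coloring) over node permutations, which
equals the orbit representative under the structure's automorphism group.
For speed the canonical map over all 64 adjacency configurations × color
triples is precomputed once per number of distinct colors; color indices
follow the lexicographic order of the color values so the table agrees
with direct minimization. Census enumeration walks undirected edges and
unions endpoint neighborhoods, counting each weakly connected induced
triple exactly once (FANMOD-style induced-subgraph convention).

## Randomization null

Randomized replicates preserve, exactly: every node's in- and out-degree,
every TF's per-state target count vector, node states, and the two-node
subgraph (mutual-dyad) census. The sampler attempts `swap_factor × |E|`
(default 10×, a standard mixing heuristic; unspecified in the original
procedure and logged) constrained double-edge swaps per replicate:

- simple edges `(u→v, x→y) → (u→y, x→v)` only when `state(v) = state(y)`,
  all four nodes distinct, no duplicate or self-loop created, and neither
  created edge's reverse exists (so no mutual dyad appears or disappears);
- mutual dyads swap only against other mutual dyads, as units, under the
  pairing(s) whose endpoint states match; when both pairings are legal one
  is chosen by coin flip.

Illegal proposals are rejected without replacement. The exactness of all
four invariants is asserted per-replicate in the test suite.

Empirical P for a colored class is the plain fraction of replicates whose
count reaches the real count (no pseudo-count; resolution 1/n_random,
default 1/500). Significance additionally requires the real count to
exceed the randomized mean by more than 5%. Only classes observed in the
real network are tested.

## Mutual exclusivity

`S_M` is the fraction of state compositions coupled to exactly one motif
structure (or cell type). The null permutes entries independently within
every column (column sums exact), 10,000 permutations by default; P is the
fraction of permutations with `S_M` at least the observed value. Rows that
become all-zero under permutation contribute 0. The plain-fraction
estimator is slightly anti-conservative relative to the (n+1)-corrected
version; the calibration tests bound it by the exact exchangeability bound
`P(p ≤ α) ≤ (⌊αn⌋+1)/(n+1)`.

## Expression comparisons, enrichment, specificity

Targets shared between colored FFL classes are removed before pairwise
Wilcoxon rank-sum tests (exact null for small tie-free samples, normal
approximation with tie correction otherwise; groups under 3 are skipped).
Activator/repressor roles are an input table, applied to all of a TF's
targets, defining FFL types I–IV by the roles of the two TFs. Gene-set
enrichment is the upper-tail hypergeometric probability with
Benjamini–Hochberg FDR across terms; gene sets are flat files (no ontology
graph handling). The cell-type specificity score is the expression
fraction across cell lines, with strict `S > 0.85` for specificity.

## Two-condition comparison

Source-condition FFLs partition into no-change (all 3 edges retained) and
edge-loss; edge-gain instances come from the end condition with < 3 edges
in the source. States are promoter properties, not network properties: a
gene absent from one condition's network still takes that condition's
gene-state table entry; instances lacking a state in either condition are
flagged and excluded from transition counts.

The transition test builds, per change group, `n_transition_perms`
(default 1,000) artificial instance sets matching the real group size,
sampling top/intermediate genes uniformly from the source TF pool and
bottom genes from the target pool, three distinct genes per triple, edges
not required. P is the fraction of artificial sets whose transition
frequency reaches the real one (ties count against significance). The
empirical fraction can be 0; the output carries an explicit resolution
floor `1/n_perm` and no extrapolation below it. Within-state "transitions"
are counted and tested like any other cell; unobserved cross-state cells
are not enumerated in the output (their p is 1 by construction).
Artificial sets match the real group's size only — they are not themselves
re-classified into change groups.

## Prioritization

The state-change matrix is symmetric with zero diagonal: activation
(strong/weak) ↔ repression (poised/repressed) scores 10, poised ↔
repressed 5, strong ↔ weak 3; a flat 5 is added once per structurally
changed instance (not per edge). Identity transitions score 0 — any
positive identity score would reward inert genes. A gene's summary score
pools all deduplicated instances containing it at any position
(deduplication key: the ordered triple, so a triple extracted from both
conditions is scored once). Ranks are dense min-ranks over descending
scores with gene-id tie order for determinism. Uniformly scaling the
matrix provably rescales scores and leaves ranks unchanged (tested);
robustness under ±1 perturbation of the 3/5 entries is reported by the
rank-stability test machinery but not asserted, since small perturbations
can legitimately reorder near-ties.

## Synthetic data: what it emulates, and what it does not

The generator lays promoters on a disjoint tiling (2-kb gene spacing, 1-kb
promoters) so recovery checks are exact by construction: every planted
edge's peak summit window falls inside the target promoter and inside a
DHS; every promoter is fully covered by a segment of the gene's planted
state, with inter-promoter gaps cycling through all four states so each
has genome-wide mass; decoy peaks are placed strictly between promoters to
exercise the DHS filter. Background TF out-degrees follow a clipped zipf
law (default exponent 2.0, a typical regulatory-network tail), planted
motif instances occupy dedicated nodes so planted counts are exact lower
bounds, and log2 expression is drawn per state with means 8/6/4/3 (strong/
weak/poised/repressed, SD 1) mirroring the observed expression gradient
across promoter classes. Gene states default to frequencies
(0.35, 0.25, 0.15, 0.25) so every class is populated while poised stays
the rarest, as in real promoter annotations. Condition pairs apply planted
per-position state flips, background flips, and single-edge losses/gains
per planted FFL, all recorded in a truth table.

None of this reproduces real data's messiness: overlapping promoters,
partial segment coverage, peaks spanning multiple promoters, replicate
noise, or distal regulation. Passing recovery tests therefore demonstrates
correctness of the algorithms under their stated assumptions, not
robustness to annotation ambiguity; the fold-enrichment tie-break and
zero-coverage policies exist precisely for the messy cases the generator
avoids.

## Problem sizes in the test and acceptance runs

The test suite and acceptance script use networks of roughly 200–2,500
genes, 100–500 randomization replicates, and 500–10,000 permutations —
sizes chosen so planted effects are unambiguous against binomial noise
while each check re-derives its expectation from an independent oracle or
planted truth. Procedure defaults (500 randomized networks, 10,000
exclusivity permutations, 1,000 transition permutations, α = 0.05) remain
the published values and are what `PipelineConfig` applies when no
override is given.

## Known limitations

- The 15→4 state map beyond the six explicitly named labels is a
  convention (configurable), and transcription-associated states arguably
  deserve their own class.
- The census is exact but enumerative; networks with ~10⁵ edges and dense
  neighborhoods will be slow in pure Python.
- The transition test's artificial instances ignore network topology by
  design (uniform pool sampling), so its null reflects gene-pool state
  composition, not wiring.
- Edge-gain instances are detected through induced FFL extraction in the
  end condition; FFLs embedded in denser subgraphs (extra edges among the
  same triple) are counted under their actual induced structure, not as
  FFLs.
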