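# Methods

## The problem

Morphological matrices are hierarchical: when a structure is absent, the
characters describing its parts and properties have no applicable state.
Standard parsimony programs score such cells as missing data, i.e. as "any
state", which lets ancestral-state reconstruction invent states for
structures that do not exist.  On trees that imply multiple independent
origins of the controlling structure, this phantom information can favour
one topology over another even though no observable difference separates
them.  `depclad` implements the composite-character treatment of this
problem: each dependency complex becomes one character over
dependency-consistent state tuples, scored with a generated step matrix, so
the analysis optimizes the complex as a whole and never pays for changes of
inapplicable constituents.

## Dependency model

A dependency link `(controller, enabling states, dependent)` means the
dependent is applicable only while the controller shows an enabling state —
a negative downstream dependency.  A character with several controllers is
applicable only when all of them enable (nested anatomy implies
conjunction).  Single-state dependencies restrict only the listed dependent
states rather than the whole character.  Links are declared at the start of
character statements; the default grammar token is `[C.S>this]` (`C` 1-based
controller, `S` comma-separated enabling states; `[C.S>this.D]` restricts
states `D`).  The grammar is a configurable regular expression because
annotation conventions vary between matrices.  The link relation must be
acyclic; cycles are reported with the offending characters.  Serial
homologue blocks list positionally ordered characters sharing one state set;
a streak-constrained block additionally restricts reconstructions to
contiguous runs of presence.

Automated scoring enforcement rewrites a dependent cell to inapplicable
whenever some controller is scored a definite non-enabling state, cascading
in dependency order; controllers scored as missing never trigger a rewrite
(the observation cannot be decided).  Enforcement is idempotent and touches
only dependent cells.

## Composite characters and step costs

A complex's states are all tuples over member state codes in which a
dependent entry is inapplicable exactly when a controller entry is
non-enabling.  The direct cost between two tuples sums, over members
applicable in both, the member's weight if its state differs; members that
gain or lose applicability contribute nothing (the controller's own change
carries that cost).  Members of a serial block that change concurrently are
charged `w·(1 + (m−1)·d)` for `m` changes, with discount `d = 1/10` by
default — on a ten-fold upweighted matrix this makes each extra concurrent
change cost exactly one raw step, and all costs stay exact rationals in
tenths.  A Floyd–Warshall metric closure is applied afterwards so that no
direct cost exceeds an indirect route; the resulting matrix is symmetric,
zero-diagonal and triangle-consistent, as generalized parsimony requires.

Two consequences are worth noting.  First, a degenerate complex of one
character reproduces Fitch costs exactly (`w·(1−δ)`), so the composite path
is a strict generalization.  Second, for complexes with several dependents
the metric closure makes "lose the controller, regain it" a two-step route
that refreshes every dependent at once; reconstructions around taxa with
wholly unknown complexes can therefore prefer absence more readily than
TNT's xlinks implementation, whose nonhomology accounting is not public.
Scores on complexes with three or more hierarchy levels may differ from TNT
for the same reason; the tuple + step-matrix semantics defined here is the
implemented contract.

Taxon cells map to the subset of compatible tuples: missing cells leave all
entries free, polymorphic cells any listed state, inapplicable cells force
the inapplicable entry.  An empty compatible set means the scoring is
internally inconsistent and is reported as an error naming the taxon.

## Scoring

Independent characters are scored by Fitch's unordered-parsimony pass
(bitmask implementation; missing, inapplicable and polymorphic cells are
ambiguity sets), composites by Sankoff dynamic programming over the step
matrix; both fall back to a unit-cost Sankoff on multifurcating trees.
The DP runs on exact integer cost matrices (costs × a common denominator),
and all per-tree totals under equal weighting are exact rationals, so tied
trees are tied exactly, never within a float tolerance.  For search-speed,
all composites are padded into one vectorized DP per tree.

Homoplasy is `h = steps − min`, where the tree-independent minimum is
(observed distinct states − 1) for unordered characters and the exact
minimum Steiner-tree cost of the forced taxon states under the step matrix
for composites (Dreyfus–Wagner up to 10 terminals; a minimum-spanning-tree
bound beyond that, with h clamped at 0 since an MST can overshoot).
Implied weighting minimizes Σ h/(h+k); a composite over n constituents
contributes `n·(h̄/(h̄+k))` with `h̄ = h/n` — the fit of its averaged
homoplasy counted once per constituent.  With ten-fold upweighted members,
composite homoplasy is normalized back to raw step units by the common
member weight, so k values remain comparable across treatments.  IW totals
are floats rounded to 10 decimals so that plateau ties compare equal.

The automatic `sk` solves `(k+h_max)/k = N` for the maximum admitted weight
ratio N (default 15), giving `k = h_max/(N−1)`; `h_max` is the largest
per-constituent homoplasy measured on the best equal-weights trees of the
same dataset.  Whether TNT's automatic k uses the same `h_max` definition
is not documented; a `--k-value` override is provided.

## Search

The multistart driver runs replicates of random-addition start + steepest
branch swapping (NNI, SPR or TBR), optionally perturbed by a parsimony
ratchet (upweight a random ~25% of characters two-fold, swap, restore,
swap) and by drift (accept random rearrangements within a 2% relative score
tolerance for a fixed number of moves, then re-optimize), stopping early
when the best score has been hit independently the required number of
times.  All randomness flows from one seeded generator; identical
configurations replay identically.  Equally best trees encountered at the
final score are all retained.  Before deduplication, internal branches
whose contraction provably leaves the score unchanged are collapsed
(greedily, re-verifying after each contraction), matching the intent of a
minimum-length-zero collapse rule; the rule is configurable off.
TNT's sectorial-search strategies are not implemented.

Bootstrap support resamples the original characters with replacement;
composites are rebuilt per pseudo-replicate from the resampled
multiplicities (a character drawn twice doubles its weight, a character not
drawn contributes nothing), and bipartition frequencies are taken from the
strict consensus of each replicate's best trees.

The tree collection stores trees deduplicated under unrooted topological
identity with per-analysis provenance.  After each analysis its best trees
enter the collection and a TBR round seeded from collection members adds
any equal-or-better distinct trees; the pipeline then loops TBR-only
cross-checks of every analysis (skipping trees an analysis already holds,
which are local optima of its own scorer) — including trees cross-seeded
from other dataset variants with the same taxa — until a full pass adds
nothing.  Termination is guaranteed by the finite topology space and
monotone growth.

## Tree comparison and congruence selection

Distances are normalized Robinson–Foulds: the count of bipartitions in
exactly one tree divided by `2(n−3)`, the number of internal bipartitions
of two binary trees on n leaves (at n = 35 all values are multiples of
1/64; displayed values round half-up to two decimals, so 0.125 prints as
0.13).  Only fully resolved MPTs enter distance matrices; consensus trees
do not.  The congruence selection keeps every anchor-analysis MPT
(typically the two sk runs, with and without composites) plus, from each
other batch, the tree(s) with the minimum nRF to *any* anchor tree, ties
all kept, and returns their strict consensus.  The alternative reading —
closest to all anchors jointly — was considered and rejected because a tie
against either anchor already marks the tree as maximally congruent with
the anchor set.

## Synthetic data

The generator evolves characters along a known (or random) tree under a
fixed-number-of-changes model: per character a Poisson-distributed number
of changes is placed on distinct random edges and states propagate from a
random root state, so the truth ledger holds exact integer change counts
rather than clock expectations.  Dependent characters evolve only inside
tree regions where all their controllers are present and are freely
re-instantiated at each gain (gains are recorded separately, since a
reconstruction may need up to changes + gains steps); streak blocks evolve
by single boundary moves of a contiguous run.  Dependency complexes are
stars or chains of 2–5 characters until ~67% of characters participate —
the proportion found in densely annotated real matrices — and missing data
are injected uniformly at 12.85% by default (the proportion typical of a
curated matrix of this scale), with an optional per-taxon skew emulating a
poorly known taxon.  Defaults are 10 taxa × 40 characters with one
expected change per character.

What the generator does not emulate: correlated missingness across
characters of one organ system, character-state frequencies biased by
conceptualization choices, and any anatomical realism — fixtures are
structural stand-ins.  Passing tests therefore show that the algorithms
honour the declared dependency structure and recover trees when the signal
is adequate, not that any particular empirical matrix is well analysed.

The tail/colour fixture freezes an eight-taxon configuration, found by
exhaustive enumeration of all 10395 topologies, in which two two-origin
topologies tie exactly under composite scoring and differ by one step under
inapplicable-as-missing scoring.  The uniramous-pleopod fixture encodes an
endopod complex and an exopod complex with one taxon of ambiguous ramus
identity in three scoring variants, demonstrating that scoring both
controllers as missing admits optimal reconstructions with both rami
present — anatomically impossible — while the adopted exopod-present
scoring excludes the endopod reading.

## Sizes used in the shipped experiments

The test suite and the acceptance script keep all searches on 6–10-taxon
matrices with 12–150 characters, where exhaustive enumeration (≤ 945
topologies at 7 taxa) is available as an oracle and the full 54-analysis
protocol completes in tens of seconds.  The true-tree recovery experiment
uses 10 taxa × 150 characters at one expected change per character: at the
generator's default 40 characters the parsimony optimum genuinely differs
from the generating tree (the data, not the search, are the limit), so the
recovery claim is evaluated where the optimum is identifiable.  The
full-size structural statistics (35 × 207 cells, missing fraction,
dependent-character fraction) are computed on a generated matrix of exactly
that shape.

## Known limitations

* Cost semantics for ≥3-level hierarchies may differ from TNT's xlinks
  (nonhomology accounting unpublished); the Maddison-type neutrality
  properties hold by construction.
* The drift rule is a simplified analogue of TNT's (bounded relative-score
  acceptance), and `norss/noxss/nocss` sectorial options are out of scope.
* The minimum-spanning-tree fallback for composite minimum cost is an upper
  bound; homoplasy is clamped at zero if it overshoots (only reachable with
  more than 10 distinct forced states in one complex).
* Matrix I/O targets the TNT dialect as exported by MorphoBank plus NEXUS
  standard blocks; interleaved TNT blocks and continuous characters are not
  supported.
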