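# depclad — dependency-aware morphological parsimony

`depclad` is a toolkit for parsimony analysis of morphological character
matrices in which characters depend on one another ontologically: a "tail
colour" character has no state when the "tail" character is absent, limb
substructures vanish with the limb, serially repeated structures transform
jointly.  It is aimed at morphological systematists who want to analyse such
matrices without conflating *inapplicable* with *unknown*, and at
methodologists comparing weighting schemes on the same data.

## What it does

**Composite characters for inapplicables.**  Dependency complexes (a
controlling character plus its dependents, declared with in-statement
annotations like `[12.1>this]`) are flattened into single characters whose
states are the dependency-consistent tuples of constituent states, scored by
generalized (Sankoff) parsimony under a generated step matrix.  The cost
rule charges a controller's change with its own weight and instantiates
dependent states for free at a gain, so two independent gains of a structure
with different dependent states cost exactly two steps — no phantom steps
from colours of absent tails.  Serial-homologue blocks charge *m* concurrent
homomorph changes `w·(1+(m−1)/10)` instead of `m·w`, optionally restricted
to contiguous "streaks".

**Equal and implied weighting with automatic k.**  Implied weighting (IW)
minimizes Σ h/(h+k) over characters, where h is homoplasy (steps above the
character's minimum) and k the concavity constant.  A composite over n
constituents contributes `n·(h̄/(h̄+k))` with `h̄ = h/n`.  The automatic
`sk` is chosen so a homoplasy-free character outweighs the most homoplastic
one by exactly a ratio N (default 15): `k = h_max/(N−1)`.

**Search, bootstrap, consensus.**  Random-addition starts, NNI/SPR/TBR
branch swapping, ratchet and drift perturbation, a hits-based multistart
driver, bootstrap resampling of the original characters (composites rebuilt
per replicate), strict consensus, and a deduplicated `TreeCollection` that
cross-checks analyses with TBR rounds until closure.

**Congruence analysis.**  Normalized Robinson–Foulds distances
(`RF / 2(n−3)`), labelled distance matrices with CSV/SVG output, and
congruence-based selection of the most mutually similar trees across
analyses for a combined strict consensus.

**Synthetic data with exact truth.**  A generator evolves matrices on known
trees with dependency complexes, serial blocks and missing data under a
fixed-number-of-changes model, so every test can compare against exact
bookkeeping.

## Worked example

`examples/maddison_neutrality.py` builds the classic eight-taxon
tail/colour fixture — two red-tailed taxa, two blue-tailed taxa, four
tailless — and scores two topologies that both imply two independent tail
origins:

```
composite states: ['0-', '10', '11']

topology      composite cost  missing-data steps
A                          3                   3
B                          3                   4
```

The composite treatment assigns both topologies cost 3 (two gains plus one
additional transformation), because colours of independently gained tails
carry no comparative information.  Scoring the inapplicable colour cells as
missing data instead reconstructs colours for tailless ancestors and makes
topology B one step longer — a preference built purely on an artifact.

Other examples: `dependency_translation.py` (annotations → validated graph →
emitted `xlinks`-style commands), `kvalue_sweep.py` (EW + IW across k + sk
on one dataset), `congruence_selection.py` (nRF matrix and congruent-MPT
consensus).  A thin CLI mirrors the library: `depclad validate | score |
search | kbrowse | bootstrap | consensus | treedist | select-congruent`.

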