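# Methods

This note documents the models, algorithms, and design choices behind
`pseudoext`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where the edges are.

## Characters and matrices

Characters are discrete, unordered, and equally weighted, with at most ten
states (`0`–`9`).  `?` marks missing data and `-` marks inapplicability;
both are stored distinctly because the ancestor-repair step needs the
difference, but all parsimony computations treat both as the universal state
set — the effective behavior of standard parsimony programs for unordered
characters.  Reading a matrix preserves raw polymorphism tokens (`(01)`,
`{01}`, `0/1`) and letter states; `recode_for_analysis` maps them to `?` and
reports exactly which cells and characters were touched, so holders of a
source matrix can audit the preparation.  A character is *constant* — and
removed before analysis — when at most one distinct state is observed in its
column, ignoring `?` and `-`.  Recoding runs before constant removal: turning
polymorphisms into `?` can only create constants, never rescue them.
Character indices are 1-based everywhere a user sees them.

## Parsimony scoring

`fitch_length` is the minimum number of state changes on a tree.  Binary
trees use a vectorized Fitch pass over 10-bit state masks; polytomous trees
use a unit-cost dynamic program (Sankoff with 0/1 costs), which is exact for
any tree shape.  Both routes are tested against exhaustive enumeration of
all internal-node assignments on small trees.

The search scores candidate placements incrementally.  For an edge *e* with
down-set `D_e` and up-set `U_e` (the Fitch state sets of the two sides of
the edge), attaching a pruned piece with root set `S` and internal cost
`c_P` yields an exact new length

```
len(e) = L_R + c_P + #{characters with fitch(D_e, U_e) & S = 0}
```

where `L_R` is the length of the receiving tree and `fitch(a, b)` is the
intersection-else-union combine.  This makes one sweep of branch swapping a
handful of vectorized array operations per pruned subtree.

## Heuristic search

`heuristic_search` is the classic two-phase heuristic: seeded random-addition
-sequence stepwise insertion (each taxon goes to the length-minimizing,
constraint-satisfying edge; ties to the first minimal edge in traversal
order) followed by first-improvement hill climbing with a configurable
neighborhood.  `spr` moves prune any subtree and regraft it on any edge; the
complement direction of each edge cut is generated by rerooting the pruned
piece and regrafting it at its original position, which completes the
unrooted SPR neighborhood.  `tbr` combines piece rerooting with every
regraft position; `nni` restricts regrafts to edges adjacent to the original
attachment.  Equally parsimonious trees encountered during sweeps are held
(up to `trees_held_per_replicate`); replicates pool into a globally shortest,
topology-deduplicated set truncated at `max_saved_trees` with a logged
warning.

A backbone constraint is a tree on a subset of taxa; a candidate satisfies
it iff the candidate restricted to the constraint's taxa contains every
nontrivial constraint split (polytomies may be resolved freely; unlisted
taxa — always including fossils and HPAs — attach anywhere).  Enforcement is
by candidate rejection, checked with integer-bitmask split sets.

Defaults (10 addition sequences, hold 5, cap 1,000, SPR) are a desk-scale
profile: on every oracle-checked problem size they reach the exhaustive
optimum, and single climbs that stall one step short (a real phenomenon we
observed on ~2% of random 7-taxon matrices at 6 starts) are covered by
multi-starts.  Protocol-faithful settings for large empirical matrices
(10,000 sequences, hold 10, cap 100,000, TBR) are plain `SearchConfig`
values.  Search results are bit-reproducible given (seed, config); all
per-run seeds in a study derive from the single study seed.

## Ancestral states and HPAs

`fitch_mpr_sets` computes, per internal node and character, the set of
states attainable in at least one most-parsimonious reconstruction
(Swofford–Maddison MPR sets), from unit-cost down- and up-pass DP tables on
the rooted binary species tree.  The classical Fitch final sets, which can
be smaller on ties, are available via `method="fitch_final"`.  Reported sets
are restricted to each character's observed alphabet; under symmetric unit
costs an unobserved state is never uniquely optimal, and this guarantees
HPA rows only ever assert observed states.  Internal nodes are numbered in
preorder from `n_tips + 1` (the root), and HPA pseudo-taxa are labeled
`HPA_<node>`.

`mask_ambiguous` replaces every multi-state cell with `?`.
`repair_inapplicable` then enforces a user-supplied dependency map
(controller character, trigger states, dependent character): a dependent
cell becomes `?` when its controller is in a trigger state *or* is itself
`?` — an unknown controller cannot certify applicability — iterated to a
fixed point so chained dependencies propagate.  Cyclic maps are rejected.
Repaired cells are written `?` rather than `-` so downstream parsimony is
unaffected; counts of masked and repaired cells are retained.  An empty
dependency map is legal (the package ships only the mechanism plus
demonstration maps; real dependency lists are data, not code).

HPAs are always reconstructed on the MSST with the focal order pruned — in
every treatment, including fossil-bearing ones — because a genuinely extinct
clade could never inform its own predicted ancestors, and fossils without
molecular data cannot sit on the scaffold tree that anchors the
reconstruction.

## Treatments and scoring

Seven treatments cross scaffold (S), fossils (F), and HPAs (H).  The
analysis matrix always contains every extant taxon; the focal order's
non-osteological characters are recoded to `?` (its osteology is untouched);
fossil rows enter iff F; HPA rows iff H.  The constraint (iff S) is the
scaffold minus the focal order.  Analyses with fossils are rooted at the
fossil outgroup (a stem taxon near the root); all others at the extant
outgroup (the monotreme analogue).  Baseline runs with no pseudoextinct
order are included for all seven treatments.

After a search, fossils and HPAs are pruned, duplicate topologies are
discarded (first occurrence kept), and each unique tree is compared to the
MSST by the Robinson-Foulds distance — the raw count of nontrivial splits
present in exactly one tree, not halved and not normalized, so two binary
46-tip trees are bounded by 2 × 43 = 86.  Trees with polytomies are compared
by their (smaller) split sets with no penalty term; most-parsimonious trees
are compared exactly as produced, without collapsing zero-length branches.

Misplacement categories, judged on the tree rooted at the extant outgroup:

1. **Wrong sister group** — some scaffold split is incompatible with the
   inferred tree but becomes compatible once the focal order is removed from
   both sides of the comparison.  This "attributable violation" rule means
   scaffold polytomies never flag a legitimate resolution, and splits lying
   entirely inside the focal order are excluded (they belong to category 5).
2. **Focal superorder not monophyletic.**
3. **Focal superorder monophyletic but another superorder broken.**
4. **Focal order polyphyletic or paraphyletic** (orders with >= 2 taxa).
5. **Focal order monophyletic, attached congruently (no category 1), but its
   internal topology differs from the MSST's** (orders with >= 3 taxa).

By this operational rule, category 5 structurally excludes categories 1 and
4 in classifier output.  Published author-assigned tables can pair 5 with 1
(an order both misplaced *and* internally rearranged); the record type
therefore accepts any category set, and the shipped reference tables load
verbatim.  Our classifier is deliberately the narrower, mechanical rule.

RF summary tables aggregate a cell with several equally parsimonious trees
by the cell mean; row and column means are means of cell values, rounded
half-up to two decimals; medians are exact.  This cell-mean-first rule is
the only aggregation consistent with every printed marginal of the reference
RF table, and the test suite verifies all 19 row and 7 column statistics.

## Synthetic data

Characters evolve independently under the symmetric k-state Markov (Mk)
process — the simplest model consistent with unordered, equally weighted
characters — with uniform root states, branch lengths in expected
substitutions, and optional gamma(shape, mean 1) rate multipliers per
character (shape 2.0 in the shipped profiles; `rate_scale` multiplies all
branch lengths and is the homoplasy dial).  Characters are flagged soft with
probability `soft_fraction` (0.2, close to the 881/4,541 soft share of the
large phenomic matrix this emulates).  Fossil tips evolve from a chosen
attachment node along a stem, lose all soft characters, and lose a further
random fraction of osteological ones (0.3 by default; 0.1 for the root-ward
fossil used as the fossil outgroup).

Fixture profiles: `tiny` (12 extant taxa — 10 placentals in 8 orders and 4
pseudo-superorders, 1 marsupial, 1 monotreme — 4 fossils, 200 variable
characters), `default` (24 extant, 8 orders of 3+2 taxa, 8 fossils, 1,000
characters), `paper_scale` (46 extant — 42 placentals in 19 orders with 9
orders of >= 2 and 5 of >= 3 taxa, 2 marsupials, 2 monotremes — 40 fossils,
4,134 characters of which the first 3,371 are osteological, scaffold with
six polytomies).  Branch lengths are set so the expected number of changes
per character is ~1.2 — low homoplasy, a regime where the scaffold-only
treatment should and does place nearly every pseudoextinct order cleanly.
The `paper_scale` topology imitates the clade structure of the real
46-taxon scaffold (including its six polytomies) but is not a reconstruction
of any particular published tree, and the simulator's independent characters
lack the correlated homoplasy (convergent insectivore/myrmecophage anatomy)
that drives the hardest real misplacements — passing synthetic tests
demonstrates algorithmic correctness, not that real morphology is reliable.

## What the tests establish

* Fitch lengths, MPR sets, and RF distances agree with brute-force
  enumeration (and with dendropy, for RF) over thousands of random cases.
* The heuristic search attains exhaustive-search optima on 7-taxon problems,
  constrained and unconstrained (400/400 searches).
* Aggregating the shipped published tables reproduces every printed
  marginal statistic and headline congruence count.
* On default-profile synthetic data the scaffold-only treatment recovers
  >= 90% (observed: 100%) of pseudoextinct orders with empty category sets
  over 20 replicates, and HPA-bearing treatments never yield fewer
  monophyletic focal orders than their HPA-free counterparts on matched
  seeds; mean RF rises monotonically with the homoplasy dial between its
  endpoints.

## Known limitations

* The search is desk-scale software: correct and exhaustively validated on
  small problems, but not engineered for 10,000-replicate TBR runs on
  4,000-character, 130-tip matrices.
* No likelihood or Bayesian inference anywhere (reconstruction and search
  are parsimony-only, by design), no ordered/Dollo/Sankoff-weighted
  characters, no implied weighting, no branch-length semantics in
  comparisons.
* Tie-breaking differs from TNT's undocumented rules; length-optimality and
  topology-set behavior are promised, bit-identical TNT tree files are not.
* The misplacement classifier is mechanical; author-style judgment calls
  (category 5 alongside 1) are intentionally out of scope, and a
  user-supplied expected table can be compared against its output.
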