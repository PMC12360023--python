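# Methods

This note documents the models, defaults, numerical choices and known
limitations of `ccinfer`.  Notation: a chemical graph is `C = (H, α, β)`
with explicit hydrogens, element labels α and bond multiplicities
β ∈ {1,2,3}; `⟨C⟩` is its hydrogen-suppressed graph.

## Chemical-graph model

Graphs are simple (no loops or parallel bonds) and connected.  Element
codes carry an optional valence suffix (`S(2)`, `S(6)`, `N(2)`, …) so
that elements with several valence states act as distinct codes in every
descriptor; the default table covers H, C, N, O, F, Si, P, S, Cl and the
suffixed variants that occur in the standard benchmark alphabets.

Masses are **nominal integer atomic masses** (H=1, C=12, N=14, O=16,
F=19, Si=28, P=31, S=32, Cl=35).  The cycle-configuration machinery only
uses masses through their *ranks*, and the nominal table reproduces
every worked arithmetic value (13 for CH, 29 for C–OH, 14 for both N and
CH₂, 28 for CO) exactly.  The table is an ordinary mapping and can be
replaced by monoisotopic masses; rank-based descriptors change only if a
replacement breaks or creates mass ties.

Inputs must be kekulized.  Aromatic-bond perception is never guessed at
the descriptor level; the SDF/SMILES readers kekulize via RDKit on load
and *skip* records that cannot be kekulized, because every configuration
descriptor depends on concrete β values.

Validation flags: disconnected graphs, valence mismatches, non-terminal
or multiply-bonded hydrogens, fewer than four carbons, and an empty
interior.  The last case deserves a note: iterated leaf deletion can
exhaust an acyclic graph entirely (n-butane's four carbons all get
height < 2), leaving no interior vertex for fringe trees to attach to.
Such molecules are treated as infeasible for the two-layered model and
excluded, exactly as data-set filtering excludes them upstream.

## Two-layered decomposition

Branch parameter ρ (default 2).  Heights come from iterated leaf
deletion on `⟨C⟩`; a vertex with height < ρ is exterior, everything else
(including the 2-core, which never acquires a height) is interior.
Exterior edges form vertex-disjoint trees, each rooted at one interior
vertex; restoring the original hydrogens to such a tree gives the fringe
tree `C[u]`.

Rooted chemical trees are canonicalised by a label-aware recursive code:
each vertex serialises as its element code followed by the sorted list
of `(bond character, child code)` pairs, e.g. `C[-O[-H]]` for the
phenolic fringe.  Equality of codes is equivalent to rooted isomorphism
(checked against exhaustive bijection search in the test suite); the
string doubles as a parseable storage format for vocabularies and
specifications.

Configuration tuples are stored in a canonical orientation: endpoints
ordered by (element rank in the table, degree).  Degrees in edge-
configurations are degrees in `⟨C⟩`.  Leaf-adjacency-configurations are
adjacency-configurations on the heavy leaf edges of fringe trees
(hydrogen leaves excluded), oriented the same way.

The static descriptor catalogue (all individually selectable) contains:
heavy-atom count, interior-vertex count, average mass per heavy atom
(total mass including hydrogens divided by heavy-atom count), counts of
interior vertices of degree 1–4, counts of interior edges of
multiplicity 2 and 3, and per-element heavy-atom counts split
interior/exterior.  The default list is instantiated per data set from
the elements actually present.

## Cycle-configurations

For a chordless cycle `C = (u₁ … u_ℓ)` with all vertices interior, let
`μᵢ = mass*(C[uᵢ])` and let ranks be 1-based positions among the
*distinct* masses on that cycle (ties share a rank).  The CC is the
lexicographic minimum of the rank sequence over all `2ℓ` rotations and
reflected rotations, computed by explicit scan of the candidates —
cycles here have at most `c_max = 6` vertices, so clarity beats a
least-rotation algorithm.  Only cycles with `ℓ ∈ [c_min, c_max]`
(defaults 4 and 6) contribute descriptors; most organic ring systems
fall in this window.

Chordless cycles are enumerated by a bounded-depth DFS over induced
paths from each start vertex (smallest vertex first, reflection fixed by
ordering the neighbours of the start), which yields each induced cycle
exactly once in deterministic order.  The test suite cross-checks the
enumerator against a subset brute force on hundreds of random graphs.

Ring systems that ring-node expansion cannot produce are detected and
reported separately: a spiro pair (two chordless cycles sharing exactly
one vertex) and three-or-more cycles through a common vertex or edge.

## Vocabularies and feature matrices

A vocabulary is extracted from the full data set (fringe codes sorted
lexicographically, AC/EC by element rank/degree/multiplicity, CCs by
(length, sequence)), is shuffle-invariant, and fixes the feature-vector
coordinates; `f = (f_2L, f_CC)` concatenates the 2L block and the CC
block.  Vocabularies are built once per data set, not per CV fold, so
the reported K values have data-set semantics.  At prediction time,
patterns outside the vocabulary score zero with a logged warning — a
necessity for cross-validation folds and for decoded MILP solutions.

## Learning

All four learner families delegate to scikit-learn: lasso (`LassoCV`
with penalty grid 2⁻²⁰…2², chosen by inner 5-fold CV; the near-zero
floor lets noiseless linear data be fit essentially exactly),
depth-unlimited decision trees, 100-tree random forests, and a single
64-unit hidden layer MLP with early stopping.  Evaluation is 10
repetitions of 5-fold CV with fold sizes differing by at most one,
summarised by the order-statistic median of the 50 fold values; folds
are reproducible from the protocol seed, and folds on which a metric's
precondition fails (constant test targets, single-class test fold)
contribute NaN and are reported.

For LLR classification the threshold is
`θ = argmax_r ½(TP̃(r)/C₁ + TÑ(r)/C₀)` over the training scores, where
TP̃ counts positives with score ≥ r and TÑ counts negatives with score
≤ r — a point exactly at r counts as correct for both classes.  Ties
break to the smallest maximising r, and θ is refit on each training
fold.  Prediction is positive iff θ ≤ score.

A caution on weight recovery: full 2L+CC matrices contain exactly
collinear columns (the heavy-atom count is the sum of the per-element
counts), so lasso weights are not individually identifiable even on
noiseless data; predictions are.  Tests therefore assert prediction-
level recovery on the full design and coefficient-level recovery only on
a reduced, identifiable design.

## The inversion MILP

Feasibility program over: one CC selector per ring node (from Ξᵘ), one
fringe-tree selector per interior vertex (from F of the owning node),
one multiplicity selector per interior edge, plus attachment-position
selectors for seed edges incident to ring nodes.  Cycle lengths may be
mixed within Ξᵘ; position-activity and cycle-closing indicators follow
the selected CC's length.  Hydrogens are implicit in the fringe
selection: each fringe tree fixes its root element, its internal bonds
and hydrogens, leaving a residual valence budget for interior edges.

*CC consistency* is linearised by enumeration: for each (ring node, ξ)
pair, all mass sequences over the masses present in the relevant fringe
sets whose canonical rank sequence equals ξ are precomputed (the 2ℓ
orientations of ξ composed with every order-preserving injection of
ranks into mass values); one binary selector per admissible sequence
forces the fringe mass at every cycle position.  Rank classes are mass
classes — fringe trees of equal mass are interchangeable within a rank.
An instance whose enumeration would exceed 20 000 selectors is rejected
with advice to shrink the availability sets.

*Descriptor linking*: fringe, leaf-AC, element and mass counts are
linear in the fringe selectors; interior AC/EC counts use exact 0/1
product indicators over per-vertex (element, degree) state variables and
per-edge multiplicity indicators; CC counts are sums of CC selectors.
The average-mass descriptor is a ratio and has no linear encoding;
building an instance whose model puts nonzero weight on it is an error
(refit without that column).  All specification bounds (atom counts
total/interior/exterior per element, fringe/AC/EC counts, heavy-atom
total) become range constraints; a lower bound exceeding its upper bound
is rejected at build time, before any solver runs.

*Structural conventions.*  Ring edges: the shared edge of a fused pair
occupies cycle positions (0, 1) of both cycles.  Because CC consistency
already enumerates every orientation of every cycle, this placement is
without loss of generality for a ring node with at most one ring edge;
ring edges are therefore required to form a matching (seed trees needing
more are rejected — such fused strips border on the unsupported
shared-structure cases anyway).  Shared vertices are owned by the first
ring node in node order, whose fringe set applies.  For every degree-1
node of the expanded interior, only fringe trees of height exactly ρ
keep that node interior after decoding, so fringe sets of leaf non-ring
nodes are filtered to height-2 trees at build time.

*Backend and verification.*  The builder emits plain variable/constraint
arrays solved by HiGHS through `scipy.optimize.milp` (an LP-format dump
is available for other solvers).  Every feasible solution is decoded
into a chemical graph, re-featurized with the ordinary descriptor code,
and compared coordinate-by-coordinate against the MILP's internal
feature values; any mismatch is a hard error, never a silent repair.
The decoded graph is additionally validated as a chemical graph, so the
solver can never return a valence-violating molecule.

## Synthetic data

The fixtures module provides the reference structures used throughout
(benzene; catechol/resorcinol/hydroquinone with the fixed Kekulé
pattern — double bonds at ring positions 1–2, 3–4, 5–6, hydroxyls at
(1,2)/(1,3)/(1,4); spiro, fused and triple-shared-edge ring systems) and
a seeded random generator of valence-feasible molecules: a random
labelled tree grown under valence budgets over a heavy-element pool
(default {C, O, N}, 8–16 heavy atoms), up to two ring-closing bonds
between vertices at distance 3–5, occasional double-bond upgrades, then
hydrogen completion, rejection-sampled until validation passes.

What the generator emulates: size, element and ring-count ranges typical
of small drug-like molecules, with enough ring variety to exercise the
CC machinery.  What it does not emulate: the empirical distribution of
functional groups, aromaticity patterns, or property–structure
correlations of curated benchmark collections.  Passing tests therefore
demonstrate correctness of the descriptor/learning/inversion machinery
under controlled conditions, not predictive performance on real assay
data — the pipeline accepts such data (SDF/SMILES + property CSV), but
no external data ships with the package.

Test and acceptance problem sizes are deliberately modest (random graphs
of ≤ 16 heavy atoms, oracle graphs of ≤ 10 vertices, 30-molecule
learning runs, seed trees of up to three ring nodes ≈ 20–24 heavy
atoms): each check is either exact or oracle-backed at these sizes, and
the algorithms scale polynomially except for the MILP, whose solve time
is solver-dependent.

## Known limitations

- No charges, stereochemistry, isotopes, resonance handling or 3D.
- Seed trees: ring edges must form a matching (one fused neighbour per
  ring); spiro and ≥3-shared ring systems are representable only through
  non-ring parts, and then only partially.
- The MILP supports models over the implemented descriptor catalogue
  minus average mass; nonlinear learners (DT/RF/ANN) are not invertible
  here and are provided for prediction benchmarking only.
- Cycle-configuration descriptors ignore chordless cycles through
  exterior vertices; under ρ = 2 a cycle vertex is always in the 2-core
  and hence interior, so the case is treated as an error, not skipped.
- Vocabulary columns are data-set-dependent; models are only invertible
  over the vocabulary they were trained on.
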