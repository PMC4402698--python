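# Methods

## Pedigree model

A pedigree is a directed graph of individuals with a sex function, edges
running parent → child, satisfying: acyclicity; in-degree 0 or 2 for every
individual; opposite-sex parents for every child; no isolated individuals
(isolated rows in input files are dropped with a warning rather than
rejected). Validation reports *all* violated axioms as data — a report
object, not an exception — so malformed files can be triaged.

A pedigree is *generational* when a level function g exists with g = 1 on
every founder and g(child) = g(parent) + 1 along every edge. The map, when
it exists, is unique and is computed by constraint propagation in
topological order; a conflict between the two parents' levels (e.g. a
generation-1 × generation-2 mating) makes the pedigree non-generational,
which is reported as a sentinel rather than an error. All comparison
operations require max g = 2.

Identifiers are opaque strings and pedigrees are compared as unlabeled
structures: no operation matches individuals across pedigrees by id. All
serialization sorts individuals lexicographically, so outputs are
byte-stable.

## Family decomposition and the exact monogamous test

A couple is an unordered opposite-sex pair sharing at least one child; its
⟨i, j⟩-family counts i daughters and j sons. Every generation-2 individual
has exactly one parent couple, so the decomposition into families is unique
and conserves children; couples (not components) are the unit, so a
polygamous parent appears in several families. A monogamous 2-generation
pedigree is a disjoint union of families, hence isomorphism testing reduces
to multiset equality of (i, j) pairs. The canonical order is the two-pass
sort (by first component, then by second within runs); the implementation
keeps the two passes explicit because this sort *is* the algorithm, not
just presentation. The convention throughout is first coordinate =
daughters.

The GI-hardness encoding maps a bipartite graph (U, V, E) with no isolated
nodes to a pedigree: U male founders, V female founders, one generation-2
daughter per edge. Every family in the image is ⟨1, 0⟩ and two bipartite
graphs are isomorphic iff their images are; the test suite checks both
directions against the exhaustive isomorphism oracle on small graphs.

## Common integer pair partitions

Sides S and T are multisets of non-negative integer pairs (pedigree family
multisets in the similarity pipeline); ⟨0,0⟩ is never admitted and a
feasible instance has equal first-projection sums and equal
second-projection sums — pedigrees violating this (different daughter or
son totals) are reported as incomparable rather than scored. For plain MCIP
the elements are strictly positive.

Two elementary moves, both conserving the projection sums:

* **dominating split** — for s, t with one ≥ the other component-wise, emit
  min(s, t) and keep the nonzero residual on the dominating side (equal
  tuples consume both);
* **coordinate-exchange (non-dominating) split** — for incomparable s, t
  with s₁ > t₁, s₂ < t₂, emit ⟨t₁, s₂⟩ and leave the axis residuals
  ⟨s₁−t₁, 0⟩ and ⟨0, t₂−s₂⟩.

A degenerate case absent from the textbook description: opposite-axis
tuples such as (x, 0) vs (0, y) are incomparable, yet their exchange piece
would be the forbidden ⟨0,0⟩ and the split would be a no-op. Such pairs are
rejected by the step operation and skipped by every search; on a feasible
dominance-free state with both sides ≥ 2 a splittable pair always exists
(an all-degenerate state would force one side's projection sum to zero and
the other's positive).

### Heuristic

While dominating cross pairs exist, split the lexicographically smallest
(s, t) (a `random` tie-break with an explicit seed is available; correctness
never depends on the choice, only the realized size may). On a
dominance-free state with both sides ≥ 2, brute-force the exchange starts:
for each, a memoized depth-first search over dominating-split sequences
decides whether the start can be finished without another exchange; the
first completable start is committed together with its completing sequence.
If no start is completable (the existence argument from the size-imbalance
property is not a guarantee for every state), the lexicographically first
start is taken and the procedure recurses. Terminal states with one side
down to a single tuple append the other side verbatim. Every returned
partition is re-validated; the size is sandwiched in
[max(|S|,|T|), |S|+|T|] — a factor-2 approximation — when the heuristic
chooses its own starts. A *forced* bad start (supported for analysis) can
exceed the upper bound by one piece per extra exchange round; the worked
3×3 instance realizes exactly this: 4 of its 9 starts finish at size 6, the
other 5 at best 7.

The module also exposes the exhaustive step-choice analyses used in that
example: `completable_by_dominating` (existence search over dominating
sequences) and `best_heuristic_size` (minimum size over all step choices
respecting the heuristic's policy), both memoized on canonical states.

### Exact search

`exact_mcipp_fpt` decides "common partition of size ≤ k" by bounded-depth
branching with memoized failures (monotone in the budget) and the
lower-bound cutoff budget < max(|S|,|T|). Tuples present on both sides are
committed eagerly — two pieces shared by one (s, t) source pair could be
merged into one, so some optimum keeps shared tuples whole and assigns at
most one piece per source pair; the same normal form is asserted on
returned optima.

The branch set deserves a note. A tempting rule — commit a whole live tuple
attaining the minimum first component a or the minimum second component d,
or the piece ⟨a, d⟩ — is *incomplete*: on the worked 3×3 instance above
(a = d = 1) no optimal solution contains ⟨1,11⟩, ⟨12,1⟩ or ⟨1,1⟩, which is
checkable by enumerating all optimal assignment tables. The implemented
rule is therefore pivot-based and complete by construction: fix a pivot
tuple attaining the minimum first component; every common partition assigns
at least one piece to the pivot, so branching over all nonzero pieces
dominated by the pivot, paired with every opposite-side host dominating the
piece, loses no solution. The minimum-component pieces above are still
tried first as a fast path, and pieces are otherwise tried largest-first.
The branching factor is bounded by the pivot's component values rather than
by k alone; for the family-count magnitudes this package targets that
trade-off favors correctness and is certified against the independent
oracle on an exhaustive grid of small instances. Optimization wraps the
decision procedure in iterative deepening from max(|S|,|T|) to |S|+|T|.

For MCIP, the minimum element a of A ∪ B need never be partitioned (a
rerouting argument on an optimal solution shows some optimum contains a
whole), so `exact_mcip_fpt` branches only on which opposite-side element a
is subtracted from — at most max(|A|,|B|) branches per level, depth k. The
property suite verifies the witness claim directly on random instances.

### Oracles

The brute-force references share no search code with the fast paths. For
partitions they enumerate assignment tables — cell (i, j) holds the piece
carved from source i of one side and source j of the other, rows and
columns summing to the sides — minimizing nonzero cells, with
branch-and-bound pruning; the one-piece-per-cell normal form is justified
by the merge argument. The pedigree oracle enumerates sex-preserving
bijections pruned by (sex, in-degree, out-degree) classes. Default caps
(pedigrees ≤ 12 individuals, MCIP totals ≤ 40, MCIPP sides ≤ 4-ish tuples
with projection sums ≤ 25) keep exhaustive sweeps under test-suite budgets.

## Synthetic data

Planted MCIPP instances draw nonzero random pieces (components uniform on
[0, max_value], default 8) and group them surjectively into each side, so
the pieces are a certified common partition and feasibility holds by
construction. Random pedigrees create couples with truncated-geometric
child counts (mean 2, minimum 1 — small families keep oracle
cross-checks cheap), uniform child sexes, and optional polygamy: with the
given probability a new couple reuses an existing generation-1 individual
of the matching sex. Bipartite pairs are random side-labeled graphs,
resampled until isolated-free; the partner is a relabeled copy
(isomorphic) or an independently drawn graph verified non-isomorphic, the
verification being capped at 10 nodes. All generators are deterministic in
the seed.

The generators emulate structure only: no demography, genotypes, component
size distributions from real cohorts, or missingness. Passing tests
certify algorithmic correctness on valid 2-generation structures, not
robustness to noisy real-world pedigree reconstruction.

## Numerical and scale choices

Everything is exact integer combinatorics; there are no tolerances. The
test suite's exhaustive sweeps use 500 seeded planted instances with sides
≤ 4 tuples and projection sums ≤ 25 for the oracle-equivalence and
factor-2 checks, monogamous pedigree pairs ≤ 12 individuals for the
isomorphism cross-check, and 3+3-node bipartite graphs for the encoding
check — sizes chosen so the independent oracles stay exhaustive. The
acceptance script's quantities are exact and seed-independent.

## Known limitations

* Exact isomorphism of polygamous pedigrees is only available through the
  capped brute-force oracle; that hardness is intrinsic, not an
  implementation gap.
* The similarity score compares family multisets; it is blind to which
  parents the sub-families share, so two polygamous pedigrees wired
  differently over identical family multisets score as identical.
* The exact solver's branching is value-bounded; family counts in the
  hundreds with large offspring counts will favor the heuristic.
* Pedigrees of three or more generations are modeled and validated but
  rejected by all comparison operations.
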