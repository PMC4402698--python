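# pedcmp — isomorphism and similarity for 2-generation pedigrees

`pedcmp` compares *unlabeled* two-generation pedigrees: directed acyclic
graphs of sexed individuals in which every non-founder has exactly two
opposite-sex parents and every individual sits at generation 1 (founders) or
generation 2 (children). It is aimed at researchers working with
family-structure data — e.g. reconstructed sibling/parentage groups in
population genetics — who need to ask "are these two pedigrees the same
structure?" and, when they are not, "how similar are they?".

## The model

A couple with *i* daughters and *j* sons forms an **⟨i, j⟩-family**. A
*monogamous* 2-generation pedigree (every generation-1 individual has one
partner) is a disjoint union of such families, so isomorphism testing
reduces to multiset equality of the (i, j) pairs and runs in O(n log n) by a
two-pass sort. Without monogamy, exact isomorphism testing is as hard as
Graph Isomorphism — `pedcmp` includes the encoding that maps any bipartite
graph to a 2-generation pedigree (one ⟨1, 0⟩-family per edge) witnessing
this — so similarity is scored instead by decomposition:

Write each pedigree as its multiset of families, S and T. A **common pair
partition** H of S and T is a multiset of pairs that can be grouped
component-wise to reconstruct S and, independently, to reconstruct T; it
describes a division of both pedigrees into the same collection of matching
sub-families. The **Minimum Common Integer Pair Partition** (MCIPP) asks for
the smallest such H; the smaller |H|, the more similar the pedigrees. MCIPP
generalizes the NP-complete Minimum Common Integer Partition (MCIP) on plain
integers. `pedcmp` ships three solvers behind one interface:

* **heuristic** — repeatedly splits *dominating* pairs (one tuple ≥ the
  other component-wise) by subtraction; when only incomparable tuples
  remain it brute-forces a coordinate-exchange split that dominating splits
  can finish. Output size is sandwiched in [max(|S|,|T|), |S|+|T|], a
  factor-2 approximation.
* **fpt** — an exact bounded-depth branching search, run under iterative
  deepening from the lower bound; practical when the optimal size k is
  small.
* **brute** — an independent exhaustive oracle (assignment-table
  enumeration) used to certify the other two on small instances.

## Worked example

The instance S = {⟨9,4⟩, ⟨1,11⟩, ⟨6,3⟩}, T = {⟨2,8⟩, ⟨12,1⟩, ⟨2,9⟩} has no
dominating cross pair — all 9 pairs are incomparable — so the heuristic must
open with a coordinate-exchange split. Forcing the split on (⟨6,3⟩, ⟨2,9⟩):

```
$ printf '9\t4\n1\t11\n6\t3\n' > S.tsv
$ printf '2\t8\n12\t1\n2\t9\n' > T.tsv
$ pedcmp mcipp solve S.tsv T.tsv --method heuristic --start 6,3:2,9
2	3
0	6
1	5
4	0
1	3
8	1
size	6
```

The six lines are the common partition: e.g. ⟨2,3⟩ + ⟨4,0⟩ = ⟨6,3⟩ rebuilds
one S-tuple while ⟨2,3⟩ + ⟨0,6⟩ = ⟨2,9⟩ rebuilds a T-tuple. Exactly 4 of
the 9 possible opening splits can be finished by dominating splits alone
(each reaching size 6); from the other 5 the best achievable size is 7. The
exact solver confirms 6 is optimal here:

```
$ pedcmp mcipp solve S.tsv T.tsv --method fpt --json
{"size": 6, "method": "fpt", "lower_bound": 3, "upper_bound": 6, ...}
```

Pedigree-level usage: `pedcmp decompose A.ped` emits the family multiset of
a PED file (4 tab-separated columns: id, father, mother, sex; `0` = missing
parent), `pedcmp iso-mono A.ped B.ped` runs the exact monogamous test, and
`pedcmp similarity A.ped B.ped --method fpt` scores two general pedigrees.
`pedcmp simulate …` generates seeded synthetic pedigrees, bipartite pairs
and planted MCIPP instances.

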