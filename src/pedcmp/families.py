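"""Family decomposition and comparison of 2-generation pedigrees.

A monogamous 2-generation pedigree is a disjoint union of <i, j>-families —
one couple with i daughters and j sons — so two such pedigrees are isomorphic
exactly when their multisets of (i, j) pairs coincide, testable by sorting.
For general (polygamous) 2-generation pedigrees exact isomorphism testing is
GI-hard; the similarity pipeline instead decomposes both pedigrees into their
family multisets and scores them by the size of a minimum common integer
pair partition (the fewer matching sub-families needed, the more similar the
pedigrees).

The convention throughout is first coordinate = daughters, second = sons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from . import mcipp
from .mcipp import InfeasibleInstanceError, Pair, SolveResult
from .pedigree import (
    InvalidPedigreeError,
    Pedigree,
    Sex,
    assign_generations,
)

__all__ = [
    "Family",
    "NotTwoGenerationError",
    "NotMonogamousError",
    "IncomparableError",
    "decompose",
    "families_of",
    "is_monogamous",
    "monogamous_isomorphic",
    "canonical_family_order",
    "pedigree_from_bipartite",
    "similarity_mcipp",
]

FamilyMultiset = tuple[Pair, ...]


class NotTwoGenerationError(InvalidPedigreeError):
    """Raised when an operation requires a 2-generation pedigree."""


class NotMonogamousError(InvalidPedigreeError):
    """Raised by the exact test on polygamous input, where it does not apply."""


class IncomparableError(InfeasibleInstanceError):
    """Raised when two pedigrees have different sex-wise child totals and so
    admit no common sub-family decomposition."""


@dataclass(frozen=True)
class Family:
    """One mating couple with its children: an <i, j>-family."""

    father: str
    mother: str
    children: frozenset[str]
    i: int  # daughters
    j: int  # sons

    @property
    def pair(self) -> Pair:
        return (self.i, self.j)


def _require_two_generation(p: Pedigree) -> dict[str, int]:
    gen = assign_generations(p)
    if gen is None:
        raise NotTwoGenerationError("pedigree is not generational")
    if max(gen.values()) != 2:
        raise NotTwoGenerationError(
            f"pedigree has {max(gen.values())} generations, expected 2"
        )
    return gen


def decompose(p: Pedigree) -> list[Family]:
    """Split a 2-generation pedigree into its <i, j>-families.

    One family per couple (unordered parent pair sharing at least one child);
    families may share a parent when the pedigree is polygamous, but every
    generation-2 individual belongs to exactly one family.
    """
    _require_two_generation(p)
    sex_of = p.sex_of
    by_couple: dict[tuple[str, str], set[str]] = {}
    for child in p.individuals:
        parents = p.parents_of(child)
        if not parents:
            continue
        a, b = parents
        father, mother = (a, b) if sex_of[a] is Sex.MALE else (b, a)
        by_couple.setdefault((father, mother), set()).add(child)
    out = []
    for (father, mother), children in sorted(by_couple.items()):
        i = sum(1 for c in children if sex_of[c] is Sex.FEMALE)
        j = len(children) - i
        out.append(Family(father, mother, frozenset(children), i, j))
    return out


def families_of(p: Pedigree) -> FamilyMultiset:
    """The multiset of (daughters, sons) counts, one pair per couple,
    in canonical sorted order."""
    return canonical_family_order(f.pair for f in decompose(p))


def canonical_family_order(pairs: Iterable[Pair]) -> FamilyMultiset:
    """Two-pass radix-style sort: by first component, then, within runs of
    equal first components, by second.  Equivalent to lexicographic order but
    kept explicit because multiset equality of the sorted sequences *is* the
    monogamous isomorphism test."""
    by_first = sorted(pairs, key=lambda p: p[0])
    out: list[Pair] = []
    run: list[Pair] = []
    for p in by_first:
        if run and p[0] != run[0][0]:
            out.extend(sorted(run, key=lambda q: q[1]))
            run = []
        run.append(p)
    out.extend(sorted(run, key=lambda q: q[1]))
    return tuple(out)


def is_monogamous(p: Pedigree) -> bool:
    """True iff every generation-1 individual appears in exactly one couple."""
    _require_two_generation(p)
    seen: dict[str, set[tuple[str, str]]] = {}
    for fam in decompose(p):
        for parent in (fam.father, fam.mother):
            seen.setdefault(parent, set()).add((fam.father, fam.mother))
    return all(len(couples) == 1 for couples in seen.values())


def monogamous_isomorphic(p: Pedigree, q: Pedigree) -> bool:
    """Exact isomorphism test for monogamous 2-generation pedigrees.

    Each pedigree is a disjoint union of <i, j>-families, so isomorphism
    reduces to multiset equality of the (i, j) pairs, decided by the two-pass
    sort in O(n log n).
    """
    for ped in (p, q):
        if not is_monogamous(ped):
            raise NotMonogamousError(
                "pedigree is not monogamous; exact isomorphism testing is "
                "GI-hard here — use similarity_mcipp instead"
            )
    return families_of(p) == families_of(q)


def pedigree_from_bipartite(
    U: Iterable[str], V: Iterable[str], E: Iterable[tuple[str, str]]
) -> Pedigree:
    """Encode a bipartite graph as a 2-generation pedigree.

    Nodes of U become generation-1 males, nodes of V generation-1 females,
    and each edge (u, v) a generation-2 daughter of the couple (u, v): every
    family in the image is a <1, 0>-family, and two bipartite graphs are
    isomorphic exactly when their image pedigrees are.  (This encoding is why
    exact 2-generation isomorphism testing inherits Graph Isomorphism
    hardness.)
    """
    U, V = set(map(str, U)), set(map(str, V))
    if U & V:
        raise ValueError(f"sides overlap: {sorted(U & V)}")
    edges = [(str(u), str(v)) for u, v in E]
    for u, v in edges:
        if u not in U or v not in V:
            raise ValueError(f"edge ({u}, {v}) does not join U to V")
    touched = {x for e in edges for x in e}
    isolated = sorted((U | V) - touched)
    if isolated:
        raise ValueError(f"bipartite input has isolated nodes: {isolated}")

    sex_of: dict[str, Sex] = {}
    for u in U:
        sex_of[f"u:{u}"] = Sex.MALE
    for v in V:
        sex_of[f"v:{v}"] = Sex.FEMALE
    ped_edges: list[tuple[str, str]] = []
    for u, v in sorted(set(edges)):
        child = f"c:{u}|{v}"
        sex_of[child] = Sex.FEMALE
        ped_edges.append((f"u:{u}", child))
        ped_edges.append((f"v:{v}", child))
    return Pedigree(sex_of, ped_edges)


def similarity_mcipp(
    p: Pedigree, q: Pedigree, method: str = "fpt", **kwargs
) -> SolveResult:
    """Similarity score for two 2-generation pedigrees.

    Decomposes each pedigree into its family multiset and finds a common
    pair partition — a decomposition of both pedigrees into the same multiset
    of matching sub-families (a couple may be reused across sub-families).
    The smaller the partition, the more alike the family structures; size
    equal to the shared family-multiset size means isomorphic family
    structure.

    Requires equal daughter totals and equal son totals across the two
    pedigrees; otherwise no common decomposition exists and
    :class:`IncomparableError` is raised.
    """
    S = families_of(p)
    T = families_of(q)
    if mcipp.projection_sums(S) != mcipp.projection_sums(T):
        raise IncomparableError(
            "pedigrees are incomparable: generation-2 sex totals differ "
            f"({mcipp.projection_sums(S)} vs {mcipp.projection_sums(T)})"
        )
    if method == "heuristic":
        return mcipp.heuristic_mcipp(S, T, **kwargs)
    return mcipp.mcipp_optimize(S, T, method=method, **kwargs)
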