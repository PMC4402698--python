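"""Seeded generators for pedigrees, bipartite graphs and partition instances.

Every solver in the package is testable without external data: the
generators emit valid pedigrees with known family multisets, bipartite graph
pairs of known isomorphism status, and pair-partition instances with a
*planted* common partition that certifies feasibility and upper-bounds the
optimum.  All outputs are deterministic functions of the seed.

What these fixtures emulate — and what they do not: the pedigree generator
produces structurally valid 2-generation pedigrees with geometric family
sizes and optional polygamy, which exercises every code path of the
comparison pipeline, but it models no demography, no genotypes and no
missing-parent ambiguity beyond structure.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Optional

import networkx as nx

from .mcipp import Pair, PairPartition, as_pair_multiset
from .pedigree import Pedigree, Sex

__all__ = [
    "PlantedInstance",
    "gen_planted_mcipp",
    "gen_random_pedigree",
    "gen_bipartite_pair",
    "bipartite_parts",
    "truncated_geometric",
]

BIPARTITE_CHECK_CAP = 10  # total nodes for the exhaustive non-isomorphism check


@dataclass(frozen=True)
class PlantedInstance:
    """An MCIPP instance together with the common partition it was built
    from; the optimum is therefore at most ``len(planted.pieces)``."""

    S: tuple[Pair, ...]
    T: tuple[Pair, ...]
    planted: PairPartition
    seed: int


def gen_planted_mcipp(
    n_pieces: int,
    max_value: int,
    sides: tuple[int, int],
    seed: int,
) -> PlantedInstance:
    """Draw random pair pieces and group them into the two sides.

    ``n_pieces`` nonzero pairs with components in [0, max_value] are grouped
    into ``sides[0]`` nonempty groups summed component-wise to form S and,
    independently, into ``sides[1]`` groups to form T, so the pieces are a
    common partition by construction and the projection sums match.
    """
    k1, k2 = sides
    if n_pieces < max(k1, k2) or min(k1, k2) < 1:
        raise ValueError(
            f"cannot group {n_pieces} pieces into sides {sides} (each group nonempty)"
        )
    rng = random.Random(seed)
    pieces = []
    for _ in range(n_pieces):
        p = (0, 0)
        while p == (0, 0):
            p = (rng.randint(0, max_value), rng.randint(0, max_value))
        pieces.append(p)

    def group(k: int) -> list[int]:
        # surjective assignment piece -> group index
        labels = list(range(k)) + [rng.randrange(k) for _ in range(n_pieces - k)]
        rng.shuffle(labels)
        return labels

    s_labels = group(k1)
    t_labels = group(k2)
    S = [(0, 0)] * k1
    T = [(0, 0)] * k2
    for p, si, ti in zip(pieces, s_labels, t_labels):
        S[si] = (S[si][0] + p[0], S[si][1] + p[1])
        T[ti] = (T[ti][0] + p[0], T[ti][1] + p[1])

    # Canonical sorted sides; remap the planted assignment accordingly.
    S_sorted = as_pair_multiset(S)
    T_sorted = as_pair_multiset(T)
    s_order = _stable_order(S, S_sorted)
    t_order = _stable_order(T, T_sorted)
    planted = PairPartition(
        tuple(pieces),
        tuple(s_order[si] for si in s_labels),
        tuple(t_order[ti] for ti in t_labels),
    )
    if not planted.is_valid_for(S_sorted, T_sorted):  # pragma: no cover
        raise AssertionError("planted partition failed validation")
    return PlantedInstance(S_sorted, T_sorted, planted, seed)


def _stable_order(original: list[Pair], sorted_side: tuple[Pair, ...]) -> list[int]:
    """Map original positions to positions in the sorted side, multiplicity-
    aware."""
    slots: dict[Pair, list[int]] = {}
    for idx, p in enumerate(sorted_side):
        slots.setdefault(p, []).append(idx)
    return [slots[p].pop(0) for p in original]


def truncated_geometric(rng: random.Random, mean: float = 2.0) -> int:
    """Child count per couple: geometric with the given mean, minimum 1."""
    p = 1.0 / mean
    n = 1
    while rng.random() > p:
        n += 1
    return n


def gen_random_pedigree(
    n_families: int,
    polygamy_rate: float = 0.0,
    child_dist: Optional[Callable[[random.Random], int]] = None,
    seed: int = 0,
) -> tuple[Pedigree, tuple[Pair, ...]]:
    """Generate a valid 2-generation pedigree and its true family multiset.

    ``n_families`` couples are created; with probability ``polygamy_rate`` a
    couple reuses one generation-1 individual of the matching sex from an
    earlier couple instead of creating a fresh one, which makes the pedigree
    polygamous.  Each couple gets >= 1 children with sexes drawn uniformly.
    ``polygamy_rate=0`` guarantees a monogamous pedigree.
    """
    if not 0.0 <= polygamy_rate <= 1.0:
        raise ValueError("polygamy_rate must be in [0, 1]")
    if n_families < 1:
        raise ValueError("need at least one family")
    rng = random.Random(seed)
    draw_children = child_dist or truncated_geometric

    sex_of: dict[str, Sex] = {}
    edges: list[tuple[str, str]] = []
    males: list[str] = []
    females: list[str] = []
    couples: set[tuple[str, str]] = set()
    multiset: list[Pair] = []
    child_no = 0

    for f in range(n_families):
        father = mother = None
        if rng.random() < polygamy_rate and (males or females):
            # reuse an existing generation-1 individual of a random sex
            if males and (not females or rng.random() < 0.5):
                father = rng.choice(males)
            else:
                mother = rng.choice(females)
        if father is None:
            father = f"m{f}"
            sex_of[father] = Sex.MALE
            males.append(father)
        if mother is None:
            mother = f"f{f}"
            sex_of[mother] = Sex.FEMALE
            females.append(mother)
        if (father, mother) in couples:
            # extremely unlikely duplicate couple via reuse; merge would break
            # the one-family-per-couple bookkeeping, so draw a fresh partner
            mother = f"f{f}"
            sex_of[mother] = Sex.FEMALE
            females.append(mother)
        couples.add((father, mother))

        n_children = draw_children(rng)
        i = j = 0
        for _ in range(n_children):
            child = f"c{child_no}"
            child_no += 1
            if rng.random() < 0.5:
                sex_of[child] = Sex.FEMALE
                i += 1
            else:
                sex_of[child] = Sex.MALE
                j += 1
            edges.append((father, child))
            edges.append((mother, child))
        multiset.append((i, j))

    return Pedigree(sex_of, edges), as_pair_multiset(multiset)


def bipartite_parts(
    g: nx.Graph,
) -> tuple[list[str], list[str], list[tuple[str, str]]]:
    """Split a generated bipartite graph into (U, V, E) with edges oriented
    U -> V, as expected by the pedigree encoding."""
    U = sorted(n for n, d in g.nodes(data=True) if not d["side"])
    V = sorted(n for n, d in g.nodes(data=True) if d["side"])
    E = sorted((a, b) if not g.nodes[a]["side"] else (b, a) for a, b in g.edges())
    return U, V, E


def gen_bipartite_pair(
    n_u: int,
    n_v: int,
    p_edge: float,
    isomorphic: bool,
    seed: int,
) -> tuple[nx.Graph, nx.Graph]:
    """A pair of bipartite graphs of known isomorphism status.

    Both graphs carry a boolean node attribute ``side`` (False for the U
    part).  The first is a random bipartite graph without isolated nodes;
    the second is a relabeled copy when ``isomorphic`` is true, otherwise an
    edge-perturbed copy verified non-isomorphic by exhaustive check (only
    available for small graphs).
    """
    if not isomorphic and n_u + n_v > BIPARTITE_CHECK_CAP:
        raise ValueError(
            f"non-isomorphism verification capped at {BIPARTITE_CHECK_CAP} nodes"
        )
    rng = random.Random(seed)

    def sample() -> nx.Graph:
        for _ in range(1000):
            g = nx.Graph()
            g.add_nodes_from((f"u{i}" for i in range(n_u)), side=False)
            g.add_nodes_from((f"v{i}" for i in range(n_v)), side=True)
            for i in range(n_u):
                for j in range(n_v):
                    if rng.random() < p_edge:
                        g.add_edge(f"u{i}", f"v{j}")
            if all(d > 0 for _, d in g.degree()):
                return g
        raise RuntimeError("could not sample a bipartite graph without isolated nodes")

    def side_isomorphic(a: nx.Graph, b: nx.Graph) -> bool:
        return nx.is_isomorphic(
            a, b, node_match=lambda x, y: x["side"] == y["side"]
        )

    g1 = sample()
    if isomorphic:
        perm_u = rng.sample(range(n_u), n_u)
        perm_v = rng.sample(range(n_v), n_v)
        mapping = {f"u{i}": f"u{perm_u[i]}" for i in range(n_u)}
        mapping.update({f"v{j}": f"v{perm_v[j]}" for j in range(n_v)})
        return g1, nx.relabel_nodes(g1, mapping)
    for _ in range(1000):
        g2 = sample()
        if (
            all(d > 0 for _, d in g2.degree())
            and not side_isomorphic(g1, g2)
        ):
            return g1, g2
    raise RuntimeError("could not sample a non-isomorphic partner graph")
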