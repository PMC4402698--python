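"""Independent brute-force references for certifying the fast paths.

These deliberately share no search code with the heuristic or the branching
solvers: the integer-partition oracles enumerate assignment tables of pieces
to source pairs, and the pedigree oracle enumerates sex-preserving
bijections.  They exist as ground truth for small inputs, not for speed.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional, Sequence

from .mcipp import (
    InfeasibleInstanceError,
    McipPartition,
    Pair,
    PairPartition,
    as_int_multiset,
    as_pair_multiset,
    projection_sums,
)
from .pedigree import Pedigree

__all__ = [
    "OracleCapError",
    "brute_force_mcip",
    "brute_force_mcipp",
    "pedigree_isomorphic_bruteforce",
]

MCIP_SUM_CAP = 40
MCIPP_PROJECTION_SUM_CAP = 25
MCIPP_SIDE_CAP = 4
PEDIGREE_SIZE_CAP = 12


class OracleCapError(ValueError):
    """Raised when an input exceeds the configured exhaustive-search cap."""


def brute_force_mcip(
    A: Iterable[int], B: Iterable[int], cap: int = MCIP_SUM_CAP
) -> tuple[int, McipPartition]:
    """Exhaustive minimum common integer partition.

    Enumerates every assignment table x[i][j] >= 0 with row sums A and column
    sums B (in some optimal solution each (a, b) source pair contributes at
    most one piece, since two pieces shared by the same pair could be merged),
    minimizing the number of nonzero cells.
    """
    A0, B0 = as_int_multiset(A), as_int_multiset(B)
    if sum(A0) != sum(B0):
        raise InfeasibleInstanceError(f"sums differ: {sum(A0)} vs {sum(B0)}")
    if sum(A0) > cap:
        raise OracleCapError(f"total {sum(A0)} exceeds the oracle cap {cap}")
    if not A0:
        return 0, McipPartition((), (), ())

    n, m = len(A0), len(B0)
    best_size = len(A0) + len(B0)  # never optimal, safe sentinel
    best_cells: Optional[list[tuple[int, int, int]]] = None
    lower = max(n, m)

    def rec(i: int, col_rem: list[int], cells: list[tuple[int, int, int]]) -> None:
        nonlocal best_size, best_cells
        if len(cells) >= best_size:
            return
        if i == n:
            if all(r == 0 for r in col_rem):
                best_size = len(cells)
                best_cells = list(cells)
            return
        # rows still to fill each need at least one piece
        if len(cells) + (n - i) >= best_size:
            return

        def fill(j: int, row_rem: int) -> None:
            if len(cells) >= best_size:
                return
            if j == m - 1:
                if row_rem <= col_rem[j]:
                    if row_rem > 0:
                        cells.append((i, j, row_rem))
                        col_rem[j] -= row_rem
                        rec(i + 1, col_rem, cells)
                        col_rem[j] += row_rem
                        cells.pop()
                    else:
                        rec(i + 1, col_rem, cells)
                return
            for x in range(min(row_rem, col_rem[j]) + 1):
                if x > 0:
                    cells.append((i, j, x))
                    col_rem[j] -= x
                fill(j + 1, row_rem - x)
                if x > 0:
                    col_rem[j] += x
                    cells.pop()

        fill(0, A0[i])

    rec(0, list(B0), [])
    assert best_cells is not None
    pieces = tuple(x for _, _, x in best_cells)
    partition = McipPartition(
        pieces, tuple(i for i, _, _ in best_cells), tuple(j for _, j, _ in best_cells)
    )
    assert partition.is_valid_for(A0, B0)
    assert best_size >= lower
    return best_size, partition


def brute_force_mcipp(
    S: Iterable[Sequence[int]],
    T: Iterable[Sequence[int]],
    projection_cap: int = MCIPP_PROJECTION_SUM_CAP,
    side_cap: int = MCIPP_SIDE_CAP,
) -> tuple[int, PairPartition]:
    """Exhaustive minimum common integer pair partition.

    Enumerates assignment tables whose cell (i, j) holds a component-wise
    non-negative pair piece, with row sums S and column sums T, minimizing
    the number of nonzero cells (one piece per source pair suffices in some
    optimum, by the merge argument).
    """
    S0, T0 = as_pair_multiset(S), as_pair_multiset(T)
    if projection_sums(S0) != projection_sums(T0):
        raise InfeasibleInstanceError(
            f"projection sums differ: {projection_sums(S0)} vs {projection_sums(T0)}"
        )
    if S0 and max(projection_sums(S0)) > projection_cap:
        raise OracleCapError(
            f"projection sums {projection_sums(S0)} exceed the oracle cap {projection_cap}"
        )
    if max(len(S0), len(T0)) > side_cap + 1:
        # one extra tuple of slack keeps the printed worked instances in range
        raise OracleCapError(
            f"sides ({len(S0)}, {len(T0)}) exceed the oracle cap {side_cap + 1}"
        )
    if not S0:
        return 0, PairPartition((), (), ())

    n, m = len(S0), len(T0)
    best_size = n + m + 1
    best_cells: Optional[list[tuple[int, int, Pair]]] = None

    def rec(i: int, col_rem: list[Pair], cells: list[tuple[int, int, Pair]]) -> None:
        nonlocal best_size, best_cells
        if i == n:
            if all(r == (0, 0) for r in col_rem):
                if len(cells) < best_size:
                    best_size = len(cells)
                    best_cells = list(cells)
            return
        if len(cells) + (n - i) >= best_size:
            return

        row = S0[i]

        def fill(j: int, rem: Pair) -> None:
            if len(cells) >= best_size:
                return
            if j == m - 1:
                if rem[0] <= col_rem[j][0] and rem[1] <= col_rem[j][1]:
                    if rem != (0, 0):
                        cells.append((i, j, rem))
                        col_rem[j] = (col_rem[j][0] - rem[0], col_rem[j][1] - rem[1])
                        rec(i + 1, col_rem, cells)
                        col_rem[j] = (col_rem[j][0] + rem[0], col_rem[j][1] + rem[1])
                        cells.pop()
                    else:
                        rec(i + 1, col_rem, cells)
                return
            for x in range(min(rem[0], col_rem[j][0]) + 1):
                for y in range(min(rem[1], col_rem[j][1]) + 1):
                    if (x, y) != (0, 0):
                        cells.append((i, j, (x, y)))
                        col_rem[j] = (col_rem[j][0] - x, col_rem[j][1] - y)
                    fill(j + 1, (rem[0] - x, rem[1] - y))
                    if (x, y) != (0, 0):
                        col_rem[j] = (col_rem[j][0] + x, col_rem[j][1] + y)
                        cells.pop()

        fill(0, row)

    rec(0, list(T0), [])
    assert best_cells is not None
    partition = PairPartition(
        tuple(p for _, _, p in best_cells),
        tuple(i for i, _, _ in best_cells),
        tuple(j for _, j, _ in best_cells),
    )
    assert partition.is_valid_for(S0, T0)
    return best_size, partition


def pedigree_isomorphic_bruteforce(
    p: Pedigree, q: Pedigree, cap: int = PEDIGREE_SIZE_CAP
) -> Optional[dict[str, str]]:
    """Exhaustive pedigree isomorphism on small inputs.

    Searches all sex-preserving bijections, pruned by (sex, in-degree,
    out-degree) classes, for one that maps the edge set of ``p`` exactly onto
    the edge set of ``q``.  Returns the witness bijection or ``None``.
    """
    if len(p.individuals) > cap or len(q.individuals) > cap:
        raise OracleCapError(
            f"pedigrees exceed the exhaustive cap of {cap} individuals; "
            "use the monogamous test or the similarity pipeline instead"
        )
    if len(p.individuals) != len(q.individuals) or len(p.edges) != len(q.edges):
        return None

    def classes(ped: Pedigree) -> dict[tuple, list[str]]:
        indeg = {v: 0 for v in ped.individuals}
        outdeg = {v: 0 for v in ped.individuals}
        for a, b in ped.edges:
            outdeg[a] += 1
            indeg[b] += 1
        out: dict[tuple, list[str]] = {}
        for v in sorted(ped.individuals):
            out.setdefault((ped.sex_of[v], indeg[v], outdeg[v]), []).append(v)
        return out

    cp, cq = classes(p), classes(q)
    if set(cp) != set(cq) or any(len(cp[k]) != len(cq[k]) for k in cp):
        return None

    keys = sorted(cp, key=repr)
    p_edges = set(p.edges)
    q_edges = set(q.edges)
    for perms in itertools.product(*(itertools.permutations(cq[k]) for k in keys)):
        phi: dict[str, str] = {}
        for k, perm in zip(keys, perms):
            phi.update(zip(cp[k], perm))
        if {(phi[a], phi[b]) for a, b in p_edges} == q_edges:
            return phi
    return None
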