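"""Pedigree data model, axiom validation, generation assignment and PED I/O.

A pedigree here is a directed acyclic graph of sexed individuals in which
edges run parent -> child, every individual has in-degree 0 (founder) or 2,
the two parents of any child have opposite sexes, and no individual is
isolated.  A pedigree is *generational* when a function g exists with
g = 1 on founders and g(child) = g(parent) + 1 along every edge; the package
compares 2-generation pedigrees (max g = 2), the simplest non-trivial case.

Individual identifiers are opaque strings.  Pedigrees are compared as
*unlabeled* structures: no operation in this package matches individuals
across pedigrees by identifier.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

__all__ = [
    "Sex",
    "Pedigree",
    "Violation",
    "ValidationReport",
    "InvalidPedigreeError",
    "PedFormatError",
    "validate_pedigree",
    "assign_generations",
    "read_ped",
    "write_ped",
    "read_edge_list",
]


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def from_ped_code(cls, code: str) -> "Sex":
        if code == "1":
            return cls.MALE
        if code == "2":
            return cls.FEMALE
        raise PedFormatError(f"invalid sex code {code!r} (expected 1 or 2)")

    @property
    def ped_code(self) -> str:
        return "1" if self is Sex.MALE else "2"


class InvalidPedigreeError(ValueError):
    """Raised when an operation requires a pedigree that passes validation."""


class PedFormatError(ValueError):
    """Raised for malformed PED / edge-list input."""


class Pedigree:
    """Immutable container: individuals with sexes plus parent->child edges.

    Construction checks only referential integrity (edges must join known
    individuals); the structural axioms are checked by
    :func:`validate_pedigree` so that malformed data can be reported rather
    than rejected wholesale.
    """

    __slots__ = ("_sex_of", "_edges")

    def __init__(
        self, sex_of: Mapping[str, Sex], edges: Iterable[tuple[str, str]]
    ) -> None:
        self._sex_of = {str(k): v for k, v in sex_of.items()}
        edge_set = set()
        for parent, child in edges:
            parent, child = str(parent), str(child)
            if parent not in self._sex_of or child not in self._sex_of:
                raise ValueError(f"edge ({parent}, {child}) references unknown individual")
            edge_set.add((parent, child))
        self._edges = frozenset(edge_set)

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(self._sex_of)

    @property
    def sex_of(self) -> dict[str, Sex]:
        return dict(self._sex_of)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v, s in self._sex_of.items():
            g.add_node(v, sex=s)
        g.add_edges_from(self._edges)
        return g

    def parents_of(self, child: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self._edges if b == child))

    def __eq__(self, other: object) -> bool:
        """Labeled equality (same ids, sexes and edges) — an I/O round-trip
        check, *not* isomorphism."""
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._sex_of == other._sex_of and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((frozenset(self._sex_of.items()), self._edges))

    def __len__(self) -> int:
        return len(self._sex_of)

    def __repr__(self) -> str:
        return f"Pedigree({len(self._sex_of)} individuals, {len(self._edges)} edges)"


@dataclass(frozen=True)
class Violation:
    code: str  # "cycle" | "in-degree" | "same-sex-parents" | "isolated"
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "ok"
        return "; ".join(f"{v.code}: {v.detail}" for v in self.violations)


def validate_pedigree(p: Pedigree) -> ValidationReport:
    """Check the pedigree axioms and report every violation found.

    Violations are data, not exceptions: the report lists each failed axiom
    (cycle, in-degree not in {0, 2}, same-sex parents, isolated individual).
    """
    g = p.to_digraph()
    violations: list[Violation] = []
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        violations.append(Violation("cycle", f"cycle through {cyc[0][0]}"))
    for v in sorted(g.nodes):
        indeg = g.in_degree(v)
        if indeg not in (0, 2):
            violations.append(Violation("in-degree", f"{v} has in-degree {indeg}"))
        elif indeg == 2:
            a, b = sorted(g.predecessors(v))
            if p.sex_of[a] == p.sex_of[b]:
                violations.append(
                    Violation("same-sex-parents", f"parents {a}, {b} of {v} share a sex")
                )
        if indeg == 0 and g.out_degree(v) == 0:
            violations.append(Violation("isolated", f"{v} is isolated"))
    return ValidationReport(tuple(violations))


def assign_generations(p: Pedigree) -> Optional[dict[str, int]]:
    """Return the unique generation map, or None if the pedigree is not
    generational.

    The map satisfies g = 1 on every founder and g(child) = g(parent) + 1 on
    every edge; a conflict between the two parents' levels (e.g. a mating
    across generations) makes the pedigree non-generational.
    """
    report = validate_pedigree(p)
    if not report.ok:
        raise InvalidPedigreeError(str(report))
    g = p.to_digraph()
    gen: dict[str, int] = {}
    for v in nx.topological_sort(g):
        preds = list(g.predecessors(v))
        if not preds:
            gen[v] = 1
            continue
        levels = {gen[u] + 1 for u in preds}
        if len(levels) != 1:
            return None
        gen[v] = levels.pop()
    return gen


# ---------------------------------------------------------------------------
# PED I/O — 4 mandatory tab-separated columns:
#   individual_id  father_id  mother_id  sex(1=male, 2=female)
# "0" marks a missing parent; both parents must be present or both absent.
# Lines starting with '#' are comments.
# ---------------------------------------------------------------------------


def _parse_rows(rows: list[tuple[str, str, str, str]], source: str) -> Pedigree:
    sex_of: dict[str, Sex] = {}
    parent_refs: dict[str, tuple[str, str]] = {}
    for iid, father, mother, sex_code in rows:
        if iid in sex_of:
            raise PedFormatError(f"{source}: duplicate individual id {iid!r}")
        if iid == "0":
            raise PedFormatError(f"{source}: individual id '0' is reserved")
        sex_of[iid] = Sex.from_ped_code(sex_code)
        if (father == "0") != (mother == "0"):
            raise PedFormatError(
                f"{source}: individual {iid!r} has exactly one parent (in-degree 1)"
            )
        if father != "0":
            parent_refs[iid] = (father, mother)

    edges: list[tuple[str, str]] = []
    for child, (father, mother) in parent_refs.items():
        for parent, expected in ((father, Sex.MALE), (mother, Sex.FEMALE)):
            if parent not in sex_of:
                raise PedFormatError(f"{source}: unknown parent id {parent!r} for {child!r}")
            if sex_of[parent] is not expected:
                raise PedFormatError(
                    f"{source}: parent {parent!r} of {child!r} listed as "
                    f"{'father' if expected is Sex.MALE else 'mother'} but has sex "
                    f"{sex_of[parent].value}"
                )
            edges.append((parent, child))

    connected = {v for e in edges for v in e}
    isolated = sorted(set(sex_of) - connected)
    if isolated:
        warnings.warn(
            f"{source}: removing {len(isolated)} isolated individual(s): "
            + ", ".join(isolated),
            stacklevel=3,
        )
        for v in isolated:
            del sex_of[v]
    return Pedigree(sex_of, edges)


def read_ped(path: str | Path) -> Pedigree:
    """Read a pedigree from a 4-column PED-style TSV file.

    Isolated individuals are dropped with a warning; structural errors that
    the format can express (single parent, sex conflicts, unknown or
    duplicate ids) raise :class:`PedFormatError`.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise PedFormatError(
                f"{path.name}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
            )
        rows.append(tuple(parts))  # type: ignore[arg-type]
    return _parse_rows(rows, path.name)


def write_ped(p: Pedigree, path: str | Path) -> None:
    """Write a pedigree as PED-style TSV, rows sorted by individual id."""
    path = Path(path)
    lines = []
    for v in sorted(p.individuals):
        parents = p.parents_of(v)
        father = mother = "0"
        if parents:
            for u in parents:
                if p.sex_of[u] is Sex.MALE:
                    father = u
                else:
                    mother = u
        lines.append(f"{v}\t{father}\t{mother}\t{p.sex_of[v].ped_code}")
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(edges_path: str | Path, sex_path: str | Path) -> Pedigree:
    """Read a pedigree from "parent<TAB>child" lines plus a sex map file
    with "individual<TAB>sex_code" lines (1=male, 2=female)."""
    sex_of: dict[str, Sex] = {}
    sex_path = Path(sex_path)
    for lineno, line in enumerate(sex_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PedFormatError(f"{sex_path.name}:{lineno}: expected 2 columns")
        iid, code = parts
        if iid in sex_of:
            raise PedFormatError(f"{sex_path.name}:{lineno}: duplicate id {iid!r}")
        sex_of[iid] = Sex.from_ped_code(code)

    edges: list[tuple[str, str]] = []
    edges_path = Path(edges_path)
    for lineno, line in enumerate(edges_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PedFormatError(f"{edges_path.name}:{lineno}: expected 2 columns")
        parent, child = parts
        for v in (parent, child):
            if v not in sex_of:
                raise PedFormatError(f"{edges_path.name}:{lineno}: unknown id {v!r}")
        edges.append((parent, child))
    return Pedigree(sex_of, edges)
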