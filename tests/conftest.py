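"""Shared fixtures: printed worked instances and small pedigree builders."""

from __future__ import annotations

import random

import pytest

from pedcmp import Pedigree, Sex
from pedcmp.mcipp import as_pair_multiset

# The 3-vs-3 pair-partition instance whose heuristic behaviour is analysed
# exhaustively in the tests (all 9 cross pairs are non-dominating).
WORKED_S = as_pair_multiset([(9, 4), (1, 11), (6, 3)])
WORKED_T = as_pair_multiset([(2, 8), (12, 1), (2, 9)])


@pytest.fixture
def worked_instance():
    return WORKED_S, WORKED_T


@pytest.fixture
def trio():
    """Smallest legal pedigree: a couple with one daughter."""
    return Pedigree(
        {"dad": Sex.MALE, "mom": Sex.FEMALE, "kid": Sex.FEMALE},
        [("dad", "kid"), ("mom", "kid")],
    )


@pytest.fixture
def two_component_pedigree():
    """Polygamous left component (mother shared by two couples, families
    <2,0> and <0,1>) plus a monogamous right component (<1,1>-family)."""
    sex = {
        "m1": Sex.MALE, "w": Sex.FEMALE, "m2": Sex.MALE,
        "g1": Sex.FEMALE, "g2": Sex.FEMALE, "b1": Sex.MALE,
        "rm": Sex.MALE, "rw": Sex.FEMALE, "rg": Sex.FEMALE, "rb": Sex.MALE,
    }
    edges = [
        ("m1", "g1"), ("w", "g1"),
        ("m1", "g2"), ("w", "g2"),
        ("m2", "b1"), ("w", "b1"),
        ("rm", "rg"), ("rw", "rg"),
        ("rm", "rb"), ("rw", "rb"),
    ]
    return Pedigree(sex, edges)


@pytest.fixture
def cross_generation_pedigree():
    """Valid pedigree that is not generational: a generation-1 male mates
    with a generation-2 female."""
    sex = {
        "a": Sex.MALE, "b": Sex.FEMALE, "c": Sex.FEMALE,
        "m": Sex.MALE, "e": Sex.FEMALE,
    }
    edges = [("a", "c"), ("b", "c"), ("m", "e"), ("c", "e")]
    return Pedigree(sex, edges)


def relabel(p: Pedigree, seed: int) -> Pedigree:
    """Shuffled-id copy of a pedigree (isomorphic by construction)."""
    rng = random.Random(seed)
    ids = sorted(p.individuals)
    new = [f"x{i}" for i in range(len(ids))]
    rng.shuffle(new)
    phi = dict(zip(ids, new))
    return Pedigree(
        {phi[v]: s for v, s in p.sex_of.items()},
        [(phi[a], phi[b]) for a, b in p.edges],
    )


def family_pedigree(pairs, seed: int = 0) -> Pedigree:
    """Monogamous pedigree with one <i, j>-family per (i, j) pair."""
    sex: dict[str, Sex] = {}
    edges = []
    n = 0
    for fam, (i, j) in enumerate(pairs):
        f, m = f"f{fam}", f"m{fam}"
        sex[f], sex[m] = Sex.MALE, Sex.FEMALE
        for _ in range(i):
            sex[f"c{n}"] = Sex.FEMALE
            edges += [(f, f"c{n}"), (m, f"c{n}")]
            n += 1
        for _ in range(j):
            sex[f"c{n}"] = Sex.MALE
            edges += [(f, f"c{n}"), (m, f"c{n}")]
            n += 1
    return relabel(Pedigree(sex, edges), seed)
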