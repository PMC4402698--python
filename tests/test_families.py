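"""Family decomposition, monogamy, exact isomorphism, bipartite encoding."""

import itertools

import pytest

from pedcmp import (
    IncomparableError,
    NotMonogamousError,
    Sex,
    assign_generations,
    families_of,
    is_monogamous,
    monogamous_isomorphic,
    pedigree_from_bipartite,
    similarity_mcipp,
    validate_pedigree,
)
from pedcmp.families import canonical_family_order, decompose
from pedcmp.oracles import pedigree_isomorphic_bruteforce
from pedcmp.synthetic import gen_random_pedigree

from conftest import family_pedigree, relabel


class TestDecomposition:
    def test_trio_is_single_one_zero_family(self, trio):
        assert families_of(trio) == ((1, 0),)

    def test_shared_parent_component_decomposes_into_two_families(
        self, two_component_pedigree
    ):
        assert families_of(two_component_pedigree) == ((0, 1), (1, 1), (2, 0))

    def test_three_daughters_only(self):
        p = family_pedigree([(3, 0)])
        assert families_of(p) == ((3, 0),)

    def test_children_conserved_across_families(self):
        p, _ = gen_random_pedigree(8, polygamy_rate=0.4, seed=2)
        gen = assign_generations(p)
        n_children = sum(1 for v in p.individuals if gen[v] == 2)
        assert sum(i + j for i, j in families_of(p)) == n_children

    def test_every_child_in_exactly_one_family(self):
        p, _ = gen_random_pedigree(7, polygamy_rate=0.5, seed=13)
        fams = decompose(p)
        seen = list(itertools.chain.from_iterable(f.children for f in fams))
        assert len(seen) == len(set(seen))

    def test_non_two_generation_rejected(self, cross_generation_pedigree):
        with pytest.raises(Exception, match="not generational"):
            families_of(cross_generation_pedigree)


class TestMonogamy:
    def test_disjoint_families_are_monogamous(self):
        assert is_monogamous(family_pedigree([(1, 1), (2, 0), (0, 3)]))

    def test_shared_parent_is_polygamous(self, two_component_pedigree):
        assert not is_monogamous(two_component_pedigree)

    def test_single_family_is_monogamous(self, trio):
        assert is_monogamous(trio)


class TestMonogamousIsomorphism:
    def test_pedigree_isomorphic_to_itself(self):
        p = family_pedigree([(2, 1), (0, 3)])
        assert monogamous_isomorphic(p, p)

    def test_family_order_is_irrelevant(self):
        p = family_pedigree([(2, 1), (0, 3)], seed=1)
        q = family_pedigree([(0, 3), (2, 1)], seed=2)
        assert monogamous_isomorphic(p, q)

    def test_sexes_are_not_interchangeable(self):
        p = family_pedigree([(2, 1)])
        q = family_pedigree([(1, 2)])
        assert not monogamous_isomorphic(p, q)
        assert pedigree_isomorphic_bruteforce(p, q) is None

    def test_polygamous_input_redirected_to_similarity(self, two_component_pedigree):
        with pytest.raises(NotMonogamousError, match="similarity"):
            monogamous_isomorphic(two_component_pedigree, two_component_pedigree)

    def test_two_pass_sort_matches_lexicographic(self):
        pairs = [(3, 1), (0, 2), (3, 0), (1, 5), (0, 1), (3, 1)]
        assert canonical_family_order(pairs) == tuple(sorted(pairs))


class TestBipartiteEncoding:
    def test_single_edge_gives_trio(self):
        p = pedigree_from_bipartite(["u"], ["v"], [("u", "v")])
        assert len(p) == 3
        assert families_of(p) == ((1, 0),)

    def test_star_shares_male_parent(self):
        p = pedigree_from_bipartite(["u"], ["v1", "v2"], [("u", "v1"), ("u", "v2")])
        assert families_of(p) == ((1, 0), (1, 0))
        assert not is_monogamous(p)

    def test_output_is_valid_two_generation_all_daughters(self):
        E = [("u1", "v1"), ("u1", "v2"), ("u2", "v2"), ("u2", "v3")]
        p = pedigree_from_bipartite(["u1", "u2"], ["v1", "v2", "v3"], E)
        assert validate_pedigree(p).ok
        gen = assign_generations(p)
        assert max(gen.values()) == 2
        assert all(pair == (1, 0) for pair in families_of(p))

    def test_isolated_node_rejected(self):
        with pytest.raises(ValueError, match="isolated"):
            pedigree_from_bipartite(["u"], ["v", "w"], [("u", "v")])


class TestSimilarity:
    def test_identical_pedigrees_partition_into_their_families(self):
        p = family_pedigree([(2, 1), (1, 1), (0, 2)], seed=3)
        q = relabel(p, seed=4)
        res = similarity_mcipp(p, q, method="fpt")
        assert res.size == 3
        assert sorted(res.partition.pieces) == [(0, 2), (1, 1), (2, 1)]

    def test_unequal_sex_totals_incomparable(self):
        p = family_pedigree([(2, 4)])
        q = family_pedigree([(4, 5)])
        with pytest.raises(IncomparableError):
            similarity_mcipp(p, q)

    def test_split_families_score_between_bounds(self):
        # q splits p's <2,2>-family across two couples
        p = family_pedigree([(2, 2), (1, 0)], seed=5)
        q = family_pedigree([(2, 1), (1, 1)], seed=6)
        res = similarity_mcipp(p, q, method="fpt")
        assert 2 <= res.size <= 4
        heur = similarity_mcipp(p, q, method="heuristic")
        brute = similarity_mcipp(p, q, method="brute")
        assert brute.size == res.size <= heur.size
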