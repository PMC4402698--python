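"""Pedigree model: axiom validation, generation assignment, PED I/O."""

import pytest

from pedcmp import (
    InvalidPedigreeError,
    PedFormatError,
    Pedigree,
    Sex,
    assign_generations,
    read_ped,
    validate_pedigree,
    write_ped,
)
from pedcmp.pedigree import read_edge_list
from pedcmp.synthetic import gen_random_pedigree

from conftest import family_pedigree


class TestValidation:
    def test_smallest_legal_pedigree_is_ok(self, trio):
        assert validate_pedigree(trio).ok

    def test_single_parent_reports_in_degree(self):
        p = Pedigree({"a": Sex.MALE, "c": Sex.FEMALE}, [("a", "c")])
        report = validate_pedigree(p)
        assert not report.ok
        assert {v.code for v in report.violations} == {"in-degree"}

    def test_same_sex_parents_reported(self):
        p = Pedigree(
            {"a": Sex.MALE, "b": Sex.MALE, "c": Sex.FEMALE},
            [("a", "c"), ("b", "c")],
        )
        assert {v.code for v in validate_pedigree(p).violations} == {"same-sex-parents"}

    def test_cycle_and_isolated_reported(self):
        p = Pedigree(
            {"a": Sex.MALE, "b": Sex.FEMALE, "c": Sex.FEMALE, "z": Sex.MALE},
            [("a", "b"), ("c", "b"), ("b", "a"), ("c", "a")],
        )
        codes = {v.code for v in validate_pedigree(p).violations}
        assert "cycle" in codes
        assert "isolated" in codes

    def test_cross_generation_mating_is_valid_but_not_generational(
        self, cross_generation_pedigree
    ):
        assert validate_pedigree(cross_generation_pedigree).ok
        assert assign_generations(cross_generation_pedigree) is None


class TestGenerations:
    def test_single_family_levels(self, trio):
        assert assign_generations(trio) == {"dad": 1, "mom": 1, "kid": 2}

    def test_two_disjoint_families_all_two_generation(self):
        p = family_pedigree([(1, 1), (2, 0)])
        gen = assign_generations(p)
        assert gen is not None and set(gen.values()) == {1, 2}

    def test_generation_map_satisfies_both_defining_conditions(self):
        p, _ = gen_random_pedigree(6, polygamy_rate=0.3, seed=9)
        gen = assign_generations(p)
        indeg = {v: 0 for v in p.individuals}
        for _, child in p.edges:
            indeg[child] += 1
        assert all(gen[v] == 1 for v in p.individuals if indeg[v] == 0)
        assert all(gen[b] == gen[a] + 1 for a, b in p.edges)

    def test_invalid_pedigree_rejected(self):
        p = Pedigree({"a": Sex.MALE, "c": Sex.FEMALE}, [("a", "c")])
        with pytest.raises(InvalidPedigreeError):
            assign_generations(p)


class TestPedIO:
    def test_four_row_file(self, tmp_path):
        f = tmp_path / "fam.ped"
        f.write_text(
            "# a comment\n"
            "dad\t0\t0\t1\n"
            "mom\t0\t0\t2\n"
            "son\tdad\tmom\t1\n"
            "dau\tdad\tmom\t2\n"
        )
        p = read_ped(f)
        assert len(p) == 4 and len(p.edges) == 4

    def test_round_trip_is_identity(self, tmp_path):
        p, _ = gen_random_pedigree(12, polygamy_rate=0.2, seed=4)
        f = tmp_path / "roundtrip.ped"
        write_ped(p, f)
        assert read_ped(f) == p

    @pytest.mark.parametrize(
        "rows, match",
        [
            ("kid\tdad\t0\t2\ndad\t0\t0\t1\n", "one parent"),
            ("kid\tdad\tmom\t2\ndad\t0\t0\t1\n", "unknown parent"),
            ("dad\t0\t0\t1\ndad\t0\t0\t1\n", "duplicate"),
            ("kid\tdad\tmom\t2\ndad\t0\t0\t1\nmom\t0\t0\t1\n", "listed as mother"),
            ("kid\tdad\tmom\t3\n", "sex code"),
        ],
    )
    def test_malformed_files_rejected(self, tmp_path, rows, match):
        f = tmp_path / "bad.ped"
        f.write_text(rows)
        with pytest.raises(PedFormatError, match=match):
            read_ped(f)

    def test_isolated_rows_removed_with_warning(self, tmp_path):
        f = tmp_path / "iso.ped"
        f.write_text(
            "dad\t0\t0\t1\nmom\t0\t0\t2\nkid\tdad\tmom\t2\nghost\t0\t0\t1\n"
        )
        with pytest.warns(UserWarning, match="isolated"):
            p = read_ped(f)
        assert "ghost" not in p.individuals and len(p) == 3

    def test_edge_list_reader_matches_ped(self, tmp_path, trio):
        (tmp_path / "e.tsv").write_text("dad\tkid\nmom\tkid\n")
        (tmp_path / "s.tsv").write_text("dad\t1\nmom\t2\nkid\t2\n")
        assert read_edge_list(tmp_path / "e.tsv", tmp_path / "s.tsv") == trio
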