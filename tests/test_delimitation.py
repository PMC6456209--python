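import itertools

import numpy as np
import pytest

from its2morph.alignment import EncodedSequence, encode
from its2morph.cbc import CBCMatrix
from its2morph.delimitation import (
    DelimitationError,
    absolute_identity,
    assign_species,
    minimal_species_count,
)
from oracles import brute_force_min_blocks


def matrix_from_edges(ids, edges):
    n = len(ids)
    cbc = np.zeros((n, n), dtype=int)
    for a, b in edges:
        i, j = ids.index(a), ids.index(b)
        cbc[i, j] = cbc[j, i] = 1
    return CBCMatrix(list(ids), cbc, np.zeros((n, n), dtype=int))


class TestMinimalSpeciesCount:
    def test_all_zero_one_block(self):
        mat = matrix_from_edges(list("abcde"), [])
        count, part = minimal_species_count(mat)
        assert count == 1
        assert part.blocks == [set("abcde")]

    def test_path_graph_two_blocks(self):
        mat = matrix_from_edges(list("abc"), [("a", "b"), ("b", "c")])
        count, part = minimal_species_count(mat)
        assert count == 2
        assert {frozenset(b) for b in part.blocks} == {frozenset("ac"), frozenset("b")}

    def test_triangle_three_blocks(self):
        mat = matrix_from_edges(list("abc"), [("a", "b"), ("b", "c"), ("a", "c")])
        assert minimal_species_count(mat)[0] == 3

    def test_within_block_pairs_have_no_cbc(self):
        ids = list("abcdef")
        edges = [("a", "b"), ("c", "d"), ("e", "f"), ("a", "c")]
        mat = matrix_from_edges(ids, edges)
        _, part = minimal_species_count(mat)
        for blk in part.blocks:
            for x, y in itertools.combinations(sorted(blk), 2):
                assert mat.get(x, y)[0] == 0

    def test_matches_partition_enumeration(self, rng):
        """Exact solver equals brute-force set-partition search (<= 8 records)."""
        for _ in range(25):
            n = int(rng.integers(2, 9))
            ids = [f"r{k}" for k in range(n)]
            edges = [
                (ids[a], ids[b])
                for a in range(n)
                for b in range(a + 1, n)
                if rng.random() < 0.3
            ]
            mat = matrix_from_edges(ids, edges)
            count, _ = minimal_species_count(mat)
            eset = {frozenset(e) for e in edges}
            want = brute_force_min_blocks(ids, lambda a, b: frozenset((a, b)) in eset)
            assert count == want

    def test_monotone_under_added_record(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            ids = [f"r{k}" for k in range(n)]
            edges = [
                (ids[a], ids[b])
                for a in range(n)
                for b in range(a + 1, n)
                if rng.random() < 0.4
            ]
            small = matrix_from_edges(ids[:-1], [e for e in edges if ids[-1] not in e])
            full = matrix_from_edges(ids, edges)
            assert minimal_species_count(full)[0] >= minimal_species_count(small)[0]

    def test_greedy_fallback_flagged(self):
        ids = [f"r{k}" for k in range(20)]
        mat = matrix_from_edges(ids, [(ids[0], ids[1])])
        count, part = minimal_species_count(mat)
        assert not part.exact
        assert count >= 2


class TestAbsoluteIdentity:
    def test_identical_true(self):
        e = encode("GGAAACC", "((...))", "x")
        assert absolute_identity(e, EncodedSequence("y", e.letters))

    def test_unpaired_substitution_strict_false(self):
        x = encode("GGAAACC", "((...))", "x")
        y = encode("GGAGACC", "((...))", "y")
        assert not absolute_identity(x, y, mode="strict")

    def test_unpaired_substitution_structure_only_true(self):
        x = encode("GGAAACC", "((...))", "x")
        y = encode("GGAGACC", "((...))", "y")
        assert absolute_identity(x, y, mode="structure-only")

    def test_unknown_mode_rejected(self):
        e = encode("GGAAACC", "((...))", "x")
        with pytest.raises(ValueError):
            absolute_identity(e, e, mode="fuzzy")


class TestAssignSpecies:
    def _setup(self):
        ids = ["q1", "q2", "q3", "ref1"]
        edges = []
        mat = matrix_from_edges(ids, edges)
        genus = {"q1": "Diaporthe", "q2": "Diaporthe", "q3": "Diaporthe"}
        return mat, genus

    def test_identity_with_reference_names_query(self):
        mat, genus = self._setup()
        part = assign_species(
            ["q1", "q2", "q3"],
            [("ref1", "Diaporthe mayteni")],
            mat,
            {("q1", "ref1"): True},
            genus,
        )
        assert part.labels["q1"] == "Diaporthe mayteni"

    def test_non_identical_zero_cbc_queries_share_type_block(self):
        mat, genus = self._setup()
        part = assign_species(["q1", "q2", "q3"], [("ref1", "D. sp")], mat, {}, genus)
        assert part.labels["q1"] == part.labels["q2"] == "Diaporthe sp. type-01"

    def test_cbc_against_all_flags_putative_new_species(self):
        ids = ["q1", "q2", "ref1"]
        mat = matrix_from_edges(ids, [("q1", "q2"), ("q1", "ref1")])
        genus = {"q1": "Harknessia", "q2": "Harknessia"}
        part = assign_species(["q1", "q2"], [("ref1", "H. eucalypti")], mat, {}, genus)
        assert "putative new species" in part.flags["q1"]
        assert part.flags["q2"] == []
        assert part.labels["q1"] != part.labels["q2"]

    def test_identity_with_cbc_is_inconsistency_error(self):
        ids = ["q1", "ref1"]
        mat = matrix_from_edges(ids, [("q1", "ref1")])
        with pytest.raises(DelimitationError, match="inconsistency"):
            assign_species(
                ["q1"], [("ref1", "X y")], mat, {("q1", "ref1"): True}, {"q1": "X"}
            )

    def test_conflicting_reference_names_error(self):
        ids = ["q1", "ref1", "ref2"]
        mat = matrix_from_edges(ids, [])
        with pytest.raises(DelimitationError, match="conflicting"):
            assign_species(
                ["q1"],
                [("ref1", "A b"), ("ref2", "C d")],
                mat,
                {("q1", "ref1"): True, ("q1", "ref2"): True},
                {"q1": "A"},
            )

    def test_missing_genus_rejected(self):
        mat, _ = self._setup()
        with pytest.raises(DelimitationError, match="genus"):
            assign_species(["q1"], [], mat, {}, {})

    def test_type_numbers_consecutive_per_genus(self):
        ids = ["q1", "q2", "q3", "q4"]
        mat = matrix_from_edges(ids, [("q1", "q2"), ("q3", "q4")])
        genus = {"q1": "Xylaria", "q2": "Xylaria", "q3": "Alternaria", "q4": "Alternaria"}
        part = assign_species(ids, [], mat, {}, genus)
        assert part.labels["q1"] == "Xylaria sp. type-01"
        assert part.labels["q2"] == "Xylaria sp. type-02"
        assert part.labels["q3"] == "Alternaria sp. type-01"
        assert part.labels["q4"] == "Alternaria sp. type-02"


class TestEndToEndRecovery:
    def test_planted_partition_recovered(self, three_species_set, truth_encoded):
        from its2morph.alignment import align_progressive
        from its2morph.cbc import cbc_matrix

        seqs, truth = three_species_set
        mat = cbc_matrix(align_progressive(truth_encoded))
        _, part = minimal_species_count(mat)
        assert sorted(map(sorted, part.blocks)) == sorted(map(sorted, truth.partition()))
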