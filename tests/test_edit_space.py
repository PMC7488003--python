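"""Edit-distance, operation application and first-step operation sets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (
    all_one_base_ops,
    brute_first_steps,
    count_minimal_scripts,
    slow_levenshtein,
)
from lineagemst.edit_space import (
    AlphabetError,
    EditOperation,
    EnumerationLimitError,
    InvalidOperationError,
    apply_operation,
    canonical_edit_path,
    distance_record,
    edit_distance,
    enumerate_minimal_scripts,
    first_step_operations,
    pairwise_distances,
)

dna = st.text(alphabet="ACGT", max_size=8)


class TestEditDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ATCCCC", "GCCCC", 2),
            ("", "ACG", 3),
            ("ACG", "", 3),
            ("", "", 0),
            ("ACGT", "ACGT", 0),
            ("AA", "A", 1),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert edit_distance(a, b) == expected

    def test_rejects_off_alphabet_characters(self):
        with pytest.raises(AlphabetError, match="'X'"):
            edit_distance("AXC", "AAC")

    @given(a=dna, b=dna)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_reference_dp_and_is_symmetric(self, a, b):
        d = edit_distance(a, b)
        assert d == slow_levenshtein(a, b)
        assert d == edit_distance(b, a)
        assert (d == 0) == (a == b)

    @given(a=dna, b=dna, c=dna)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


class TestApplyOperation:
    @pytest.mark.parametrize(
        "seq, op, expected",
        [
            ("ATCCCC", EditOperation("del", 1), "TCCCC"),
            ("ATCCCC", EditOperation("sub", 1, "G"), "GTCCCC"),
            ("ACG", EditOperation("ins", 4, "T"), "ACGT"),
            ("ACG", EditOperation("ins", 1, "T"), "TACG"),
        ],
    )
    def test_examples(self, seq, op, expected):
        assert apply_operation(seq, op) == expected
        assert edit_distance(seq, expected) == 1

    @pytest.mark.parametrize(
        "seq, op",
        [
            ("ACG", EditOperation("del", 4)),
            ("ACG", EditOperation("ins", 5, "T")),
            ("ACG", EditOperation("sub", 1, "A")),  # no-op substitution
        ],
    )
    def test_invalid_operations_rejected(self, seq, op):
        with pytest.raises(InvalidOperationError):
            apply_operation(seq, op)

    def test_operation_value_semantics(self):
        assert EditOperation("sub", 3, "G") == EditOperation("sub", 3, "G")
        assert len({EditOperation("del", 1), EditOperation("del", 1)}) == 1
        assert EditOperation.parse("sub:3:G") == EditOperation("sub", 3, "G")
        assert EditOperation.parse(str(EditOperation("del", 2))) == EditOperation("del", 2)


class TestFirstStepOperations:
    def test_worked_example_four_unique_operations(self):
        ops = first_step_operations("ATCCCC", "GCCCC")
        assert ops == {
            EditOperation("del", 1),
            EditOperation("del", 2),
            EditOperation("sub", 1, "G"),
            EditOperation("sub", 2, "G"),
        }

    def test_identical_sequences_have_empty_set(self):
        assert first_step_operations("ACGT", "ACGT") == frozenset()

    def test_two_deletions_toward_shorter_repeat(self):
        assert first_step_operations("AA", "A") == {
            EditOperation("del", 1),
            EditOperation("del", 2),
        }

    @given(a=dna, b=dna)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_exactly_the_distance_reducing_operations(self, a, b):
        """The returned set equals the brute-force set over every valid
        one-base operation, for sequences up to length 8."""
        assert first_step_operations(a, b) == brute_first_steps(a, b)

    @given(a=dna, b=dna)
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_every_step_reduces_distance_by_one(self, a, b):
        d = edit_distance(a, b)
        for op in first_step_operations(a, b):
            assert edit_distance(apply_operation(a, op), b) == d - 1

    def test_distance_record_bundles_both(self):
        rec = distance_record("ATCCCC", "GCCCC")
        assert rec.distance == 2
        assert len(rec.first_step_ops) == 4


class TestMinimalScripts:
    def test_worked_example_four_paths_of_length_two(self):
        scripts = enumerate_minimal_scripts("ATCCCC", "GCCCC")
        assert len(scripts) == 4
        assert all(len(s) == 2 for s in scripts)
        assert len(set(scripts)) == 4
        for script in scripts:
            cur = "ATCCCC"
            for op in script:
                cur = apply_operation(cur, op)
            assert cur == "GCCCC"

    def test_identity_yields_one_empty_script(self):
        assert enumerate_minimal_scripts("ACG", "ACG") == [()]

    def test_two_single_deletion_scripts(self):
        scripts = enumerate_minimal_scripts("AA", "A")
        assert sorted(s[0].position for s in scripts) == [1, 2]

    def test_cap_refuses_large_distances(self):
        with pytest.raises(EnumerationLimitError):
            enumerate_minimal_scripts("A" * 10, "C" * 10, cap=3)

    @pytest.mark.parametrize(
        "a, b",
        [("ATC", "GC"), ("AAC", "CAA"), ("ACG", "GCA"), ("AG", "GGA")],
    )
    def test_script_count_matches_exhaustive_search(self, a, b):
        assert len(enumerate_minimal_scripts(a, b)) == count_minimal_scripts(a, b)


class TestCanonicalPath:
    @given(a=dna, b=dna)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_path_is_minimal_and_lands_on_target(self, a, b):
        path = canonical_edit_path(a, b)
        assert len(path) == edit_distance(a, b)
        cur = a
        for op, seq in path:
            cur = apply_operation(cur, op)
            assert cur == seq
        assert cur == b


class TestPairwiseDistances:
    def test_single_sequence(self):
        assert pairwise_distances(["A"]).tolist() == [[0]]

    def test_worked_pair(self):
        mat = pairwise_distances(["ATCCCC", "GCCCC"])
        assert mat.tolist() == [[0, 2], [2, 0]]

    def test_matches_elementwise_calls(self):
        rng = np.random.default_rng(7)
        seqs = ["".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(3, 9))) for _ in range(4)]
        mat = pairwise_distances(seqs)
        assert (mat == mat.T).all()
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                assert mat[i, j] == edit_distance(a, b)
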