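"""Sankoff reconstruction, unambiguous changes, and step-matrices."""

import random

import numpy as np
import pytest

from rna_accretion import (
    Character,
    CharacterMatrix,
    StepMatrix,
    build_step_matrix,
    export_bubble,
    mpr_reconstruct,
    parse_tree,
    sankoff_cost,
    unambiguous_changes,
)

from conftest import brute_force_parsimony, oracle_unambiguous, random_newick


class TestSankoffCost:
    @pytest.mark.parametrize(
        "newick,states,expected",
        [
            ("((A,B),(C,D));", {"A": 0, "B": 0, "C": 2, "D": 2}, 2),
            ("((A,B),C);", {"A": 0, "B": 1, "C": 3}, 3),
            ("((A,B),(C,D));", {"A": 5, "B": 5, "C": 5, "D": 5}, 0),
        ],
    )
    def test_known_costs(self, newick, states, expected):
        assert sankoff_cost(parse_tree(newick), states) == expected

    def test_polytomy_handled_natively(self):
        assert sankoff_cost(parse_tree("(A,B,C,D);"), {"A": 0, "B": 0, "C": 0, "D": 3}) == 3

    def test_missing_leaf_treated_as_absent_or_rejected(self):
        t = parse_tree("((A,B),C);")
        assert sankoff_cost(t, {"A": 2, "B": 2}) == 2  # C -> state 0
        with pytest.raises(ValueError, match="no observed state"):
            sankoff_cost(t, {"A": 2, "B": 2}, missing="error")

    def test_matches_brute_force_on_random_suite(self, rng):
        for _ in range(100):
            n = rng.randint(3, 6)
            t = parse_tree(random_newick(rng, n))
            states = {chr(ord("A") + i): rng.randint(0, 5) for i in range(n)}
            expected, _ = brute_force_parsimony(t, states)
            assert sankoff_cost(t, states) == expected


class TestUnambiguousChanges:
    def test_ambiguous_branch_not_reported(self):
        # the single 0->1 change sits on different branches in different MPRs
        t = parse_tree("((A,B),(C,D));")
        assert unambiguous_changes(t, {"A": 0, "B": 0, "C": 1, "D": 1}) == []

    def test_terminal_change_reported(self):
        t = parse_tree("((A,B),(C,D));")
        changes = unambiguous_changes(t, {"A": 0, "B": 0, "C": 0, "D": 1})
        assert [(c.branch, c.from_state, c.to_state) for c in changes] == [("D", 0, 1)]

    def test_constant_character_no_changes(self):
        t = parse_tree("((A,B),(C,D));")
        assert unambiguous_changes(t, {k: 4 for k in "ABCD"}) == []

    def test_matches_enumeration_oracle_on_random_suite(self, rng):
        for _ in range(100):
            n = rng.randint(3, 6)
            t = parse_tree(random_newick(rng, n))
            states = {chr(ord("A") + i): rng.randint(0, 5) for i in range(n)}
            _, optimal = brute_force_parsimony(t, states)
            expected = oracle_unambiguous(t, optimal)
            got = {
                (c.branch, c.from_state, c.to_state)
                for c in unambiguous_changes(t, states)
            }
            assert got == expected

    def test_mpr_enumeration_complete_and_minimal(self, rng):
        for _ in range(30):
            n = rng.randint(3, 5)
            t = parse_tree(random_newick(rng, n))
            states = {chr(ord("A") + i): rng.randint(0, 4) for i in range(n)}
            cost, optimal = brute_force_parsimony(t, states, max_state=4)
            res = mpr_reconstruct(t, states)
            assert res.min_cost == cost
            assert res.n_mpr == len(optimal)
            assert res.mprs is not None
            got = {tuple(sorted(m.items())) for m in res.mprs}
            want = {tuple(sorted(m.items())) for m in optimal}
            assert got == want
            # each leaf's final set is the singleton of its observed state
            for leaf, s in states.items():
                assert res.final_sets[leaf] == {s}

    def test_fallback_warns_when_limit_exceeded(self):
        t = parse_tree("((A,B),(C,D));")
        states = {"A": 0, "B": 4, "C": 0, "D": 4}
        with pytest.warns(UserWarning, match="approximate"):
            approx = unambiguous_changes(t, states, mpr_limit=1)
        exact = unambiguous_changes(t, states)
        # the fallback is a lower bound on the exact unambiguous set
        assert set(approx) <= set(exact)


def _matrix(characters, rows, taxa=("A", "B", "C", "D")):
    return CharacterMatrix(
        taxa=list(taxa),
        characters=characters,
        states=[list(r) for r in rows],
    )


class TestStepMatrix:
    def test_single_terminal_change(self):
        t = parse_tree("((A,B),(C,D));")
        m = _matrix([Character("s1", "helical")], ["0", "0", "0", "1"])
        sm = build_step_matrix(t, m, "helical")
        assert sm.counts[0, 1] == 1
        assert sm.counts.sum() == 1

    def test_additivity_over_characters(self):
        t = parse_tree("((A,B),(C,D));")
        m2 = _matrix(
            [Character("s1", "helical"), Character("s2", "helical")],
            ["00", "00", "00", "11"],
        )
        sm = build_step_matrix(t, m2, "helical")
        assert sm.counts[0, 1] == 2
        single = build_step_matrix(
            t, _matrix([Character("s1", "helical")], ["0", "0", "0", "1"]), "helical"
        )
        assert (sm.counts == 2 * single.counts).all()

    def test_constant_matrix_is_zero(self):
        t = parse_tree("((A,B),(C,D));")
        m = _matrix([Character("s1", "helical")], ["7", "7", "7", "7"])
        assert build_step_matrix(t, m, "helical").counts.sum() == 0

    def test_class_filter_selects_characters(self):
        t = parse_tree("((A,B),(C,D));")
        m = _matrix(
            [Character("s1", "helical"), Character("l1", "unpaired")],
            ["00", "00", "00", "12"],
        )
        helical = build_step_matrix(t, m, "helical")
        unpaired = build_step_matrix(t, m, "unpaired")
        assert helical.counts[0, 1] == 1 and helical.counts[0, 2] == 0
        assert unpaired.counts[0, 2] == 1 and unpaired.counts[0, 1] == 0

    def test_taxon_mismatch_names_offenders(self):
        t = parse_tree("((A,B),C);")
        m = _matrix([Character("s1", "helical")], ["0", "0", "0", "1"])
        with pytest.raises(ValueError, match="D"):
            build_step_matrix(t, m, "helical")

    def test_multistep_change_recorded_as_single_cell(self):
        # a 3->0 loss lands in counts[3,0], not decomposed into unit steps
        t = parse_tree("((A,B),(C,D));")
        m = _matrix([Character("v", "helical")], ["3", "3", "3", "0"])
        sm = build_step_matrix(t, m, "helical")
        assert sm.counts[3, 0] == 1 and sm.counts.sum() == 1


class TestExportBubble:
    def test_counts_and_frequency_columns(self):
        counts = np.zeros((36, 36), int)
        counts[0, 1] = 2
        out = export_bubble(StepMatrix(counts, "helical", 2))
        assert out.splitlines()[1].split("\t") == ["0", "1", "2", "1"]

    def test_zero_matrix_header_only(self):
        out = export_bubble(StepMatrix(np.zeros((36, 36), int), "helical", 3))
        assert out.strip() == "from\tto\tcount\tfrequency"

    def test_symbol_labels_above_nine(self):
        counts = np.zeros((36, 36), int)
        counts[10, 11] = 1
        out = export_bubble(StepMatrix(counts, "helical", 1))
        assert out.splitlines()[1].startswith("A\tB\t1")
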