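"""Structure parsing, decomposition, and character coding."""

import random
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rna_accretion import (
    CharacterMatrix,
    SecondaryStructure,
    build_character_matrix,
    decode_state,
    decompose,
    encode_state,
    parse_structure,
    positional_homology,
    read_nexus_matrix,
    write_nexus_matrix,
    write_structure,
)
from rna_accretion.structure import HomologyConflictError, StructureFormatError

from conftest import match_brackets, oracle_decompose, random_dot_bracket


class TestParsing:
    def test_bracket_matching_matches_stack_oracle(self):
        db = "(((...)))"
        s = parse_structure(db)
        assert s.pairs == {(0, 8), (1, 7), (2, 6)}
        m = match_brackets(db)
        assert s.pairs == {(i, j) for i, j in m.items() if i < j}
        assert sum(1 for i in range(9) if i not in m) == 3

    def test_fully_unpaired(self):
        s = parse_structure("....")
        assert s.pairs == set() and s.length == 4

    @pytest.mark.parametrize("bad", ["((..)", "..)..", "(((", "..x.."])
    def test_malformed_dot_bracket_raises(self, bad):
        with pytest.raises(StructureFormatError):
            parse_structure(bad)

    def test_pseudoknot_brackets_preserved(self):
        s = parse_structure("((..[[..))..]]")
        assert (0, 9) in s.pairs and (4, 13) in s.pairs
        assert len(s.pairs) == 4  # crossing pairs kept

    @pytest.mark.parametrize("fmt", ["dot-bracket", "ct"])
    def test_parse_write_parse_identity(self, rng, fmt):
        for _ in range(20):
            db = random_dot_bracket(rng)
            s = parse_structure(f">x\n{'A' * len(db)}\n{db}")
            s2 = parse_structure(write_structure(s, fmt), fmt)
            assert s2.pairs == s.pairs and s2.length == s.length

    def test_bpseq_roundtrip_and_duplicate_partner(self):
        s = parse_structure(">m\nGGGAAACCC\n(((...)))")
        s2 = parse_structure(write_structure(s, "bpseq"), "bpseq")
        assert s2.pairs == s.pairs
        bad = "1 G 5\n2 G 5\n3 A 0\n4 A 0\n5 C 1\n"
        with pytest.raises(StructureFormatError, match="duplicate"):
            parse_structure(bad, "bpseq")

    def test_ct_out_of_range_partner(self):
        bad = "3 m\n1 G 0 2 9 1\n2 A 1 3 0 2\n3 C 2 0 0 3\n"
        with pytest.raises(StructureFormatError, match="range"):
            parse_structure(bad, "ct")


class TestDecompose:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("(((...)))", [("stem", 3), ("hairpin_loop", 3)]),
            ("..(((...)))", [("free_end_5p", 2), ("stem", 3), ("hairpin_loop", 3)]),
            ("....", [("free_end_5p", 4)]),
            # 1-nt bulge splits the helix into two stems
            (
                "((.((...))))",
                [("stem", 2), ("bulge", 1), ("stem", 2), ("hairpin_loop", 3)],
            ),
            # internal loop: unpaired on both sides
            (
                "((.((...)).))",
                [
                    ("stem", 2),
                    ("internal_loop", 1),
                    ("stem", 2),
                    ("hairpin_loop", 3),
                    ("internal_loop", 1),
                ],
            ),
            # three-way junction: multiloop segments between the arms
            (
                "((.((..)).((..)).))",
                [
                    ("stem", 2),
                    ("multiloop_segment", 1),
                    ("stem", 2),
                    ("hairpin_loop", 2),
                    ("multiloop_segment", 1),
                    ("stem", 2),
                    ("hairpin_loop", 2),
                    ("multiloop_segment", 1),
                ],
            ),
            # exterior joint between two hairpin arms
            (
                "((..))..((..))",
                [
                    ("stem", 2),
                    ("hairpin_loop", 2),
                    ("joint", 2),
                    ("stem", 2),
                    ("hairpin_loop", 2),
                ],
            ),
        ],
    )
    def test_known_decompositions(self, db, expected):
        subs = decompose(parse_structure(db))
        assert [(x.kind, x.length) for x in subs] == expected

    def test_agrees_with_recursive_oracle_on_random_structures(self, rng):
        for _ in range(200):
            db = random_dot_bracket(rng, max_len=60)
            subs = decompose(parse_structure(db))
            assert [(x.kind, x.length) for x in subs] == oracle_decompose(db)

    def test_partition_covers_every_residue_exactly_once(self, rng):
        for _ in range(50):
            db = random_dot_bracket(rng)
            s = parse_structure(db)
            positions = [p for sub in decompose(s) for p in sub.positions]
            assert sorted(positions) == list(range(s.length))

    def test_pseudoknot_crossing_stems_both_recovered(self):
        s = parse_structure("((..[[..))..]]")
        stems = [x for x in decompose(s) if x.kind == "stem"]
        assert len(stems) == 2
        assert {x.length for x in stems} == {2}

    def test_empty_structure(self):
        assert decompose(SecondaryStructure("e", "", set(), length=0)) == []

    def test_gu_separate_counts_wobble_pairs(self):
        s = parse_structure(">m\nGGGAAACUC\n(((...)))")
        subs = decompose(s, gu_separate=True)
        gu = [x for x in subs if x.kind == "gu_pairs"]
        assert len(gu) == 1 and gu[0].length == 1  # G2:U6 wobble
        # gu record overlays its stem: partition over the others still holds
        rest = [p for x in subs if x.kind != "gu_pairs" for p in x.positions]
        assert sorted(rest) == list(range(9))


class TestEncoding:
    def test_alphanumeric_symbol_scheme(self):
        assert encode_state(10) == "A"
        assert encode_state(0) == "0"
        assert encode_state(25) == "P"

    def test_clipping_above_z_warns(self):
        with pytest.warns(UserWarning, match="clip"):
            assert encode_state(36) == "Z"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            encode_state(-1)

    @given(st.integers(min_value=0, max_value=200))
    @settings(deadline=None, max_examples=60)
    def test_encode_decode_roundtrip_clips_at_35(self, k):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert decode_state(encode_state(k)) == min(k, 35)


class TestCharacterMatrix:
    def _two_molecules(self):
        a = parse_structure(">a\n\n(((((((...)))))))")
        b = parse_structure(">b\n\n(((((((...)))))))")
        return [(a, decompose(a)), (b, decompose(b))]

    def test_shared_stem_coded_identically(self):
        pairs = self._two_molecules()
        hom = positional_homology({s.id: d for s, d in pairs})
        m = build_character_matrix(pairs, hom)
        col = m.column("stem_1")
        assert col == {"a": 7, "b": 7}
        assert m.classes()["stem_1"] == "helical"

    def test_missing_label_coded_zero(self):
        a = parse_structure(">a\n\n((..))..((..))")
        b = parse_structure(">b\n\n((..))")
        pairs = [(a, decompose(a)), (b, decompose(b))]
        hom = positional_homology({s.id: d for s, d in pairs})
        m = build_character_matrix(pairs, hom)
        assert m.value("b", "stem_2") == 0

    def test_state_twelve_is_c(self):
        a = parse_structure(">a\n\n" + "(" * 12 + "..." + ")" * 12)
        m = build_character_matrix(
            [(a, decompose(a))], positional_homology({"a": decompose(a)})
        )
        t = m.taxa.index("a")
        c = [ch.label for ch in m.characters].index("stem_1")
        assert m.states[t][c] == "C"

    def test_homology_conflict_raises(self):
        a = parse_structure(">a\n\n((..))..((..))")
        subs = decompose(a)
        hom = {("a", 0): "X", ("a", 3): "X"}  # two stems, same label
        with pytest.raises(HomologyConflictError):
            build_character_matrix([(a, subs)], hom)

    def test_nexus_roundtrip(self):
        pairs = self._two_molecules()
        hom = positional_homology({s.id: d for s, d in pairs})
        m = build_character_matrix(pairs, hom)
        m2 = read_nexus_matrix(write_nexus_matrix(m))
        assert m2.taxa == m.taxa
        assert m2.states == m.states
        assert [c.cls for c in m2.characters] == [c.cls for c in m.characters]

    def test_bad_symbol_rejected(self):
        from rna_accretion import Character

        with pytest.raises(ValueError, match="bad state symbol"):
            CharacterMatrix(
                taxa=["a"],
                characters=[Character("x", "helical")],
                states=[["%"]],
            )
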