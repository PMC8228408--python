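"""RNA secondary structures, their decomposition into substructures, and
ordered multistate character coding.

A molecule's secondary structure is held as a set of base pairs over 0-based
residue indices. :func:`decompose` partitions the residues into the classical
substructure inventory (stems, hairpin loops, bulges, internal loops,
multiloop segments, joints, free ends), and substructure lengths are coded as
single alphanumeric symbols ``0-9A-Z`` (values 0..35) suitable for ordered
(Wagner) multistate parsimony. State ``'0'`` is reserved for an absent
substructure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SYMBOLS",
    "SecondaryStructure",
    "Substructure",
    "Character",
    "CharacterMatrix",
    "StructureFormatError",
    "HomologyConflictError",
    "encode_state",
    "decode_state",
    "decompose",
    "build_character_matrix",
    "positional_homology",
]

#: Alphanumeric state alphabet: '0'..'9' code 0..9, 'A'..'Z' code 10..35.
SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_SYMBOL_VALUE = {s: i for i, s in enumerate(SYMBOLS)}

#: Substructure kinds whose length is counted in base pairs.
_PAIRED_KINDS = frozenset({"stem", "gu_pairs"})

KINDS = (
    "stem",
    "hairpin_loop",
    "bulge",
    "internal_loop",
    "multiloop_segment",
    "joint",
    "free_end_5p",
    "free_end_3p",
    "gu_pairs",
)


class StructureFormatError(ValueError):
    """Malformed structure record (unbalanced brackets, bad indices, ...)."""


class HomologyConflictError(ValueError):
    """Two substructures of one molecule mapped to the same homology label."""


def encode_state(length: int) -> str:
    """Code a substructure length as one alphanumeric state symbol.

    Lengths 0..9 map to ``'0'``..``'9'`` and 10..35 to ``'A'``..``'Z'``.
    Lengths above 35 exceed the 36-symbol alphabet and are clipped to
    ``'Z'`` with a warning.
    """
    if length < 0:
        raise ValueError(f"length must be non-negative, got {length}")
    if length > 35:
        warnings.warn(
            f"length {length} exceeds state 'Z' (35); clipping", stacklevel=2
        )
        return "Z"
    return SYMBOLS[length]


def decode_state(symbol: str) -> int:
    """Inverse of :func:`encode_state`: symbol -> integer state value."""
    try:
        return _SYMBOL_VALUE[symbol]
    except KeyError:
        raise ValueError(f"unknown state symbol {symbol!r}") from None


@dataclass
class SecondaryStructure:
    """One RNA molecule: a label, an optional sequence, and its base pairs.

    Pairs are 0-based ``(i, j)`` with ``i < j``. Crossing (pseudoknotted)
    pairs are permitted and preserved.
    """

    id: str
    sequence: str
    pairs: set[tuple[int, int]]
    length: int | None = None

    def __post_init__(self) -> None:
        if self.length is None:
            if self.sequence:
                self.length = len(self.sequence)
            elif self.pairs:
                self.length = max(j for _, j in self.pairs) + 1
            else:
                self.length = 0
        n = self.length
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(
                    f"{self.id}: pair ({i},{j}) out of range for length {n}"
                )
            if i in seen or j in seen:
                raise ValueError(
                    f"{self.id}: residue in more than one pair at ({i},{j})"
                )
            seen.add(i)
            seen.add(j)
        if self.sequence and len(self.sequence) != n:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != {n}"
            )

    @property
    def partner(self) -> dict[int, int]:
        """Symmetric residue -> pairing-partner map."""
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


@dataclass
class Substructure:
    """A homologous piece of a secondary structure.

    ``length`` counts base pairs for stems (and gu_pairs records), and
    unpaired nucleotides for everything else.
    """

    label: str
    kind: str
    length: int
    positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown substructure kind {self.kind!r}")
        if self.length < 0:
            raise ValueError("substructure length must be non-negative")

    @property
    def cls(self) -> str:
        """Character class: stems are helical, everything else unpaired.

        gu_pairs characters default to helical (they live inside stems); the
        caller may override when building a matrix.
        """
        return "helical" if self.kind in ("stem", "gu_pairs") else "unpaired"


def _stems(pairs: set[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Maximal runs of consecutively stacked pairs (i,j),(i+1,j-1),...

    Computed on the full pair set, so the two helices of a pseudoknot are
    both recovered even though they cross. Any interruption of stacking
    terminates a stem.
    """
    pmap = dict(pairs)
    stems = []
    for i in sorted(pmap):
        j = pmap[i]
        if pmap.get(i - 1) == j + 1:
            continue  # continuation of the stem starting further out
        run = []
        a, b = i, j
        while pmap.get(a) == b and a < b:
            run.append((a, b))
            a, b = a + 1, b - 1
        stems.append(run)
    return stems


def _enclosing_pair(
    pairs: Sequence[tuple[int, int]], l: int, r: int
) -> tuple[int, int] | None:
    """Innermost pair (p,q) with p < l and r < q, or None (exterior run)."""
    best = None
    for p, q in pairs:
        if p < l and r < q:
            if best is None or p > best[0] or (p == best[0] and q < best[1]):
                best = (p, q)
    return best


def _direct_branches(
    pairs: Sequence[tuple[int, int]], p: int, q: int
) -> list[tuple[int, int]]:
    """Outermost pairs strictly inside (p,q): the helices meeting its loop."""
    inside = [(a, b) for a, b in pairs if p < a and b < q]
    out = []
    for a, b in inside:
        if not any(x < a and b < y for x, y in inside if (x, y) != (a, b)):
            out.append((a, b))
    return sorted(out)


def decompose(
    s: SecondaryStructure, gu_separate: bool = False
) -> list[Substructure]:
    """Partition a structure into its substructures, 5'->3'.

    Stems are maximal stacking runs; any interruption (bulge, internal loop,
    junction) terminates a stem, so a 1-nt bulge splits a helix into two stem
    substructures. Unpaired runs are classified by flanking context:
    hairpin loop when closed by a single stem end, bulge/internal loop
    between the two ends of adjacent stems, multiloop segment inside a
    junction of >= 3 stems, joint between stems on the exterior, and free
    ends at the molecule termini. A fully unpaired molecule is a single
    5' free end.

    With ``gu_separate`` (requires a sequence), each stem containing G:U
    wobble pairs also emits a ``gu_pairs`` record whose length is the wobble
    count; these overlay their stem and are excluded from the residue
    partition.

    Labels are positional (``S1``, ``L1``, ...) and are placeholders until a
    homology map assigns shared labels across molecules.
    """
    n = s.length or 0
    if n == 0:
        return []
    if not s.pairs:
        return [
            Substructure("L1", "free_end_5p", n, list(range(n)))
        ]

    paired = set()
    for i, j in s.pairs:
        paired.add(i)
        paired.add(j)
    pairs_sorted = sorted(s.pairs)

    subs: list[Substructure] = []
    # helical substructures
    for run in _stems(s.pairs):
        pos = sorted([i for ij in run for i in ij])
        subs.append(Substructure("", "stem", len(run), pos))
        if gu_separate and s.sequence:
            gu = [
                (i, j)
                for i, j in run
                if {s.sequence[i].upper(), s.sequence[j].upper()} == {"G", "U"}
            ]
            if gu:
                subs.append(
                    Substructure(
                        "",
                        "gu_pairs",
                        len(gu),
                        sorted([i for ij in gu for i in ij]),
                    )
                )

    # unpaired runs
    i = 0
    while i < n:
        if i in paired:
            i += 1
            continue
        l = i
        while i < n and i not in paired:
            i += 1
        r = i - 1
        kind = _classify_unpaired_run(pairs_sorted, l, r, n)
        subs.append(
            Substructure("", kind, r - l + 1, list(range(l, r + 1)))
        )

    subs.sort(key=lambda x: (x.positions[0], x.kind == "gu_pairs"))
    counters: dict[str, int] = {}
    for sub in subs:
        prefix = {
            "stem": "S",
            "gu_pairs": "G",
        }.get(sub.kind, "L")
        counters[prefix] = counters.get(prefix, 0) + 1
        sub.label = f"{prefix}{counters[prefix]}"
    return subs


def _classify_unpaired_run(
    pairs: Sequence[tuple[int, int]], l: int, r: int, n: int
) -> str:
    enc = _enclosing_pair(pairs, l, r)
    if enc is None:
        if l == 0:
            return "free_end_5p"
        if r == n - 1:
            return "free_end_3p"
        return "joint"
    p, q = enc
    branches = _direct_branches(pairs, p, q)
    if not branches:
        return "hairpin_loop"
    if len(branches) == 1:
        a, b = branches[0]
        # two potential unpaired sides of the loop closed by (p,q)
        other_empty = (a == p + 1) or (b == q - 1)
        return "bulge" if other_empty else "internal_loop"
    return "multiloop_segment"


@dataclass(frozen=True)
class Character:
    """One column of a character matrix: a homology label plus its class."""

    label: str
    cls: str  # "helical" | "unpaired"

    def __post_init__(self) -> None:
        if self.cls not in ("helical", "unpaired"):
            raise ValueError(f"character class must be helical/unpaired, got {self.cls!r}")


@dataclass
class CharacterMatrix:
    """Taxa x ordered multistate characters, alphanumeric states 0-9/A-Z.

    ``states[t][c]`` is the symbol for taxon ``t``, character ``c``. State
    ``'0'`` means the substructure is absent in that taxon. All characters
    are ordered (Wagner): a change from state i to j costs |i - j|.
    """

    taxa: list[str]
    characters: list[Character]
    states: list[list[str]]
    ordered: bool = True

    def __post_init__(self) -> None:
        if len(self.states) != len(self.taxa):
            raise ValueError("one state row per taxon required")
        for t, row in zip(self.taxa, self.states):
            if len(row) != len(self.characters):
                raise ValueError(f"taxon {t}: row length != character count")
            for sym in row:
                if sym not in _SYMBOL_VALUE:
                    raise ValueError(f"taxon {t}: bad state symbol {sym!r}")

    def value(self, taxon: str, label: str) -> int:
        """Decoded integer state for one cell."""
        t = self.taxa.index(taxon)
        c = [ch.label for ch in self.characters].index(label)
        return decode_state(self.states[t][c])

    def column(self, label: str) -> dict[str, int]:
        """Decoded states of one character, keyed by taxon."""
        c = [ch.label for ch in self.characters].index(label)
        return {t: decode_state(self.states[i][c]) for i, t in enumerate(self.taxa)}

    def classes(self) -> dict[str, str]:
        """Label -> class map over all characters."""
        return {ch.label: ch.cls for ch in self.characters}

    def subset(self, cls: str) -> "CharacterMatrix":
        """Matrix restricted to one character class."""
        idx = [i for i, ch in enumerate(self.characters) if ch.cls == cls]
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=[self.characters[i] for i in idx],
            states=[[row[i] for i in idx] for row in self.states],
        )


def positional_homology(
    decompositions: Mapping[str, Sequence[Substructure]],
) -> dict[tuple[str, int], str]:
    """Label substructures by kind and 5'->3' occurrence order.

    Maps ``(taxon, index-in-decomposition)`` to a shared label like
    ``stem_1`` or ``hairpin_loop_2``. Adequate when all molecules share a
    common template topology; real analyses supply curated label maps.
    """
    out: dict[tuple[str, int], str] = {}
    for taxon, subs in decompositions.items():
        counters: dict[str, int] = {}
        for idx, sub in enumerate(subs):
            counters[sub.kind] = counters.get(sub.kind, 0) + 1
            out[(taxon, idx)] = f"{sub.kind}_{counters[sub.kind]}"
    return out


def build_character_matrix(
    structures: Iterable[tuple[SecondaryStructure, Sequence[Substructure]]],
    homology: Mapping[tuple[str, int], str],
    gu_class: str = "helical",
) -> CharacterMatrix:
    """Assemble a character matrix from decomposed molecules.

    ``homology`` maps ``(molecule id, substructure index)`` to a shared
    homology label; at most one substructure per molecule may carry a label.
    Taxa lacking a label are coded ``'0'`` (absent). Character class is
    taken from the substructure kind (stem -> helical, others -> unpaired);
    ``gu_class`` sets the class of gu_pairs characters.
    """
    taxa: list[str] = []
    cells: dict[str, dict[str, int]] = {}
    classes: dict[str, str] = {}
    order: list[str] = []
    for s, subs in structures:
        taxa.append(s.id)
        for idx, sub in enumerate(subs):
            label = homology.get((s.id, idx))
            if label is None:
                continue
            col = cells.setdefault(label, {})
            if s.id in col:
                raise HomologyConflictError(
                    f"molecule {s.id}: two substructures labeled {label!r}"
                )
            col[s.id] = sub.length
            cls = gu_class if sub.kind == "gu_pairs" else sub.cls
            if classes.setdefault(label, cls) != cls:
                raise HomologyConflictError(
                    f"label {label!r}: conflicting classes across taxa"
                )
            if label not in order:
                order.append(label)
    characters = [Character(lab, classes[lab]) for lab in order]
    states = [
        [encode_state(cells[lab].get(t, 0)) for lab in order] for t in taxa
    ]
    return CharacterMatrix(taxa=taxa, characters=characters, states=states)
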