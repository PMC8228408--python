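"""Readers and writers for secondary-structure records and character matrices.

Supported structure formats: Vienna dot-bracket (one record: ``>id`` line,
sequence line, structure line), CT (Zuker 6-column, 1-based) and bpseq
(3-column, 1-based). Character matrices round-trip through a NEXUS
CHARACTERS block with ``SYMBOLS="0..9A..Z"`` and one CHARSET per character
class.

Internal coordinates are 0-based; CT/bpseq I/O uses those formats' 1-based
conventions.
"""

from __future__ import annotations

import re

from .structure import (
    SYMBOLS,
    Character,
    CharacterMatrix,
    SecondaryStructure,
    StructureFormatError,
)

__all__ = [
    "parse_structure",
    "write_structure",
    "read_nexus_matrix",
    "write_nexus_matrix",
]

# bracket alphabets for dot-bracket strings; letters Aa etc. mark pseudoknots
_OPEN = "([{<ABCDE"
_CLOSE = ")]}>abcde"


def _parse_dot_bracket(text: str) -> SecondaryStructure:
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError("empty dot-bracket record")
    sid = "unnamed"
    if lines[0].startswith(">"):
        sid = lines[0][1:].strip() or "unnamed"
        lines = lines[1:]
    if not lines:
        raise StructureFormatError("dot-bracket record has no structure line")
    if len(lines) == 1:
        seq, struct = "", lines[0]
    else:
        seq, struct = lines[0], lines[1]
        if seq and len(seq) != len(struct):
            raise StructureFormatError(
                f"sequence length {len(seq)} != structure length {len(struct)}"
            )
    pairs: set[tuple[int, int]] = set()
    stacks: dict[int, list[int]] = {k: [] for k in range(len(_OPEN))}
    for col, ch in enumerate(struct):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(col)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE.index(ch)]
            if not stack:
                raise StructureFormatError(
                    f"unbalanced brackets: unmatched {ch!r} at column {col + 1}"
                )
            pairs.add((stack.pop(), col))
        else:
            raise StructureFormatError(
                f"bad character {ch!r} at column {col + 1}"
            )
    for k, stack in stacks.items():
        if stack:
            raise StructureFormatError(
                f"unbalanced brackets: unmatched {_OPEN[k]!r} at column {stack[-1] + 1}"
            )
    return SecondaryStructure(sid, seq, pairs, length=len(struct))


def _parse_ct(text: str) -> SecondaryStructure:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError("empty CT record")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError):
        raise StructureFormatError("CT header must start with residue count") from None
    sid = " ".join(head[1:]) or "unnamed"
    if len(lines) - 1 < n:
        raise StructureFormatError(f"CT record: expected {n} rows, got {len(lines) - 1}")
    seq = []
    pairs: set[tuple[int, int]] = set()
    partner: dict[int, int] = {}
    for lineno, ln in enumerate(lines[1 : n + 1], start=2):
        f = ln.split()
        if len(f) < 6:
            raise StructureFormatError(f"CT line {lineno}: expected 6 columns")
        idx, base, pair_to = int(f[0]), f[1], int(f[4])
        if idx < 1 or idx > n:
            raise StructureFormatError(f"CT line {lineno}: index {idx} out of range")
        seq.append(base)
        if pair_to:
            if pair_to < 1 or pair_to > n:
                raise StructureFormatError(
                    f"CT line {lineno}: partner {pair_to} out of range"
                )
            i, j = idx - 1, pair_to - 1
            for k in (i, j):
                if k in partner and partner[k] != (j if k == i else i):
                    raise StructureFormatError(
                        f"CT line {lineno}: duplicate pairing partner for residue {k + 1}"
                    )
            partner[i], partner[j] = j, i
            if i < j:
                pairs.add((i, j))
    return SecondaryStructure(sid, "".join(seq), pairs, length=n)


def _parse_bpseq(text: str) -> SecondaryStructure:
    seq = []
    pairs: set[tuple[int, int]] = set()
    partner: dict[int, int] = {}
    rows = 0
    for lineno, ln in enumerate(text.strip().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        f = ln.split()
        if len(f) != 3:
            raise StructureFormatError(f"bpseq line {lineno}: expected 3 columns")
        idx, base, pair_to = int(f[0]), f[1], int(f[2])
        rows += 1
        if idx != rows:
            raise StructureFormatError(
                f"bpseq line {lineno}: index {idx} out of order (expected {rows})"
            )
        seq.append(base)
        if pair_to:
            i, j = idx - 1, pair_to - 1
            if i == j:
                raise StructureFormatError(f"bpseq line {lineno}: self-pairing")
            for k in (i, j):
                if k in partner and partner[k] != (j if k == i else i):
                    raise StructureFormatError(
                        f"bpseq line {lineno}: duplicate pairing partner for residue {k + 1}"
                    )
            partner[i], partner[j] = j, i
            if i < j:
                pairs.add((i, j))
    if not rows:
        raise StructureFormatError("empty bpseq record")
    for i, j in pairs:
        if j >= rows:
            raise StructureFormatError(f"bpseq: partner {j + 1} out of range")
    return SecondaryStructure("unnamed", "".join(seq), pairs, length=rows)


_PARSERS = {
    "dot-bracket": _parse_dot_bracket,
    "ct": _parse_ct,
    "bpseq": _parse_bpseq,
}


def parse_structure(text: str, format: str = "dot-bracket") -> SecondaryStructure:
    """Parse one structure record; see module docstring for formats."""
    try:
        parser = _PARSERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(_PARSERS)}"
        ) from None
    return parser(text)


def _dot_bracket_string(s: SecondaryStructure) -> str:
    """Render pairs as brackets, promoting crossing pairs to extra alphabets."""
    n = s.length or 0
    out = ["."] * n
    layers: list[list[tuple[int, int]]] = []
    for i, j in sorted(s.pairs):
        for k, layer in enumerate(layers):
            if not any(a < i < b < j or i < a < j < b for a, b in layer):
                layer.append((i, j))
                break
        else:
            k = len(layers)
            layers.append([(i, j)])
        if k >= len(_OPEN):
            raise ValueError("pseudoknot nesting too deep for dot-bracket output")
        out[i], out[j] = _OPEN[k], _CLOSE[k]
    return "".join(out)


def write_structure(s: SecondaryStructure, format: str = "dot-bracket") -> str:
    """Serialize a structure in the named format (inverse of parse)."""
    n = s.length or 0
    partner = s.partner
    seq = s.sequence or "N" * n
    if format == "dot-bracket":
        return f">{s.id}\n{seq}\n{_dot_bracket_string(s)}\n"
    if format == "ct":
        lines = [f"{n} {s.id}"]
        for i in range(n):
            p = partner.get(i, -1) + 1
            lines.append(f"{i + 1} {seq[i]} {i} {i + 2 if i + 1 < n else 0} {p} {i + 1}")
        return "\n".join(lines) + "\n"
    if format == "bpseq":
        lines = [
            f"{i + 1} {seq[i]} {partner.get(i, -1) + 1}" for i in range(n)
        ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def write_nexus_matrix(m: CharacterMatrix) -> str:
    """NEXUS CHARACTERS block with the 36-symbol alphabet.

    Emits a CHARLABELS line with the homology labels and one CHARSET per
    character class (helical/unpaired) in a SETS block.
    """
    lines = [
        "#NEXUS",
        "BEGIN CHARACTERS;",
        f"  DIMENSIONS NTAX={len(m.taxa)} NCHAR={len(m.characters)};",
        f'  FORMAT DATATYPE=STANDARD SYMBOLS="{SYMBOLS}" MISSING=? GAP=-;',
        "  CHARLABELS",
        "    " + " ".join(ch.label for ch in m.characters) + ";",
        "  MATRIX",
    ]
    width = max((len(t) for t in m.taxa), default=1)
    for t, row in zip(m.taxa, m.states):
        lines.append(f"    {t:<{width}}  {''.join(row)}")
    lines.append("  ;")
    lines.append("END;")
    lines.append("BEGIN SETS;")
    for cls in ("helical", "unpaired"):
        idx = [
            str(i + 1) for i, ch in enumerate(m.characters) if ch.cls == cls
        ]
        if idx:
            lines.append(f"  CHARSET {cls} = {' '.join(idx)};")
    lines.append("END;")
    return "\n".join(lines) + "\n"


def read_nexus_matrix(text: str) -> CharacterMatrix:
    """Read a CHARACTERS block written by :func:`write_nexus_matrix`.

    Character classes are recovered from the SETS block; characters in no
    CHARSET default to unpaired.
    """
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise ValueError("not a NEXUS file")
    mdim = re.search(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+)\s*;", text, re.I)
    if not mdim:
        raise ValueError("NEXUS: missing DIMENSIONS")
    ntax, nchar = int(mdim.group(1)), int(mdim.group(2))
    mlab = re.search(r"CHARLABELS\s+(.*?);", text, re.I | re.S)
    labels = (
        mlab.group(1).split()
        if mlab
        else [f"c{i + 1}" for i in range(nchar)]
    )
    if len(labels) != nchar:
        raise ValueError("NEXUS: CHARLABELS count != NCHAR")
    mmat = re.search(r"MATRIX\s+(.*?);", text, re.I | re.S)
    if not mmat:
        raise ValueError("NEXUS: missing MATRIX")
    taxa: list[str] = []
    states: list[list[str]] = []
    for ln in mmat.group(1).splitlines():
        ln = ln.strip()
        if not ln:
            continue
        name, row = ln.split(None, 1)
        row = row.replace(" ", "")
        if len(row) != nchar:
            raise ValueError(f"NEXUS: taxon {name}: row length != NCHAR")
        taxa.append(name)
        states.append(list(row))
    if len(taxa) != ntax:
        raise ValueError("NEXUS: taxon count != NTAX")
    classes = {lab: "unpaired" for lab in labels}
    for mcs in re.finditer(r"CHARSET\s+(\w+)\s*=\s*([\d\s]+);", text, re.I):
        cls, idx = mcs.group(1).lower(), mcs.group(2).split()
        if cls in ("helical", "unpaired"):
            for i in idx:
                classes[labels[int(i) - 1]] = cls
    characters = [Character(lab, classes[lab]) for lab in labels]
    return CharacterMatrix(taxa=taxa, characters=characters, states=states)
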