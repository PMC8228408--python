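"""Shared fixtures: random structure/tree generators and brute-force oracles.

The oracles here deliberately take different algorithmic routes from the
package (recursive-descent loop parsing, exhaustive assignment enumeration)
so agreement is informative.
"""

from __future__ import annotations

import itertools
import random

import pytest


# ---------------------------------------------------------------- structures

def match_brackets(db: str) -> dict[int, int]:
    """Symmetric bracket-match map via a plain stack (independent oracle)."""
    stack, match = [], {}
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            match[i], match[j] = j, i
    assert not stack
    return match


def oracle_decompose(db: str) -> list[tuple[str, int]]:
    """Recursive-descent decomposition of a nested dot-bracket string.

    Returns (kind, length) in 5'->3' order of first residue; stems count
    base pairs, everything else unpaired nucleotides. Independent of the
    package's flat run-classification algorithm.
    """
    match = match_brackets(db)
    out: list[tuple[int, str, int]] = []  # (first position, kind, length)

    def scan(l: int, r: int, enclosed: bool) -> None:
        """One loop region: classify its unpaired runs, recurse into helices."""
        runs: list[tuple[int, int]] = []
        helices = 0
        i = l
        while i <= r:
            if db[i] == ".":
                start = i
                while i <= r and db[i] == ".":
                    i += 1
                runs.append((start, i - start))
            else:
                helices += 1
                j = match[i]
                # follow the maximal stacking run inward
                k = 1
                while db[i + k] == "(" and match[i + k] == j - k:
                    k += 1
                out.append((i, "stem", k))
                scan(i + k, j - k, True)
                i = j + 1
        for start, length in runs:
            if not enclosed:
                if start == 0:
                    kind = "free_end_5p"
                elif start + length == len(db):
                    kind = "free_end_3p"
                else:
                    kind = "joint"
            elif helices == 0:
                kind = "hairpin_loop"
            elif helices == 1:
                kind = "bulge" if len(runs) == 1 else "internal_loop"
            else:
                kind = "multiloop_segment"
            out.append((start, kind, length))

    scan(0, len(db) - 1, False)
    return [(kind, length) for _, kind, length in sorted(out)]


def random_dot_bracket(rng: random.Random, max_len: int = 60) -> str:
    """Random nested structure with stems >= 1 bp and hairpins >= 1 nt."""

    def gen(budget: int, depth: int) -> str:
        if budget < 5 or (depth > 0 and rng.random() < 0.3):
            return "." * rng.randint(1, max(1, min(6, budget)))
        pieces = []
        remaining = budget
        while remaining >= 5 and rng.random() < 0.7:
            k = rng.randint(1, min(4, (remaining - 1) // 2))
            inner = gen(remaining - 2 * k, depth + 1)
            pieces.append("(" * k + inner + ")" * k)
            remaining -= 2 * k + len(inner)
        if not pieces:
            return "." * rng.randint(1, max(1, min(6, budget)))
        if rng.random() < 0.5:
            pieces.insert(0, "." * rng.randint(1, 3))
        if rng.random() < 0.5:
            pieces.append("." * rng.randint(1, 3))
        return "".join(pieces)

    return gen(rng.randint(8, max_len), 0)


# --------------------------------------------------------------- trees

def random_newick(rng: random.Random, n_leaves: int) -> str:
    """Random rooted binary topology over leaves A, B, C, ..."""
    nodes = [chr(ord("A") + i) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


# --------------------------------------------------------- parsimony oracle

def brute_force_parsimony(
    tree, leaf_states: dict[str, int], max_state: int = 5
) -> tuple[int, list[dict[str, int]]]:
    """Exhaustive Sankoff oracle: min cost and all optimal assignments.

    Enumerates every assignment of states 0..max_state to internal nodes
    and scores sum(|parent - child|) over all branches. Internal nodes are
    keyed node{preorder index}, leaves by label, matching the package.
    """
    nodes = list(tree.preorder_node_iter())
    keys = {}
    internal = []
    for i, n in enumerate(nodes):
        if n.is_leaf():
            keys[id(n)] = n.taxon.label
        else:
            keys[id(n)] = f"node{i}"
            internal.append(n)
    best_cost = None
    best: list[dict[str, int]] = []
    for combo in itertools.product(range(max_state + 1), repeat=len(internal)):
        assign = {keys[id(n)]: s for n, s in zip(internal, combo)}
        assign.update(leaf_states)
        cost = 0
        for n in nodes:
            for c in n.child_nodes():
                cost += abs(assign[keys[id(n)]] - assign[keys[id(c)]])
        if best_cost is None or cost < best_cost:
            best_cost, best = cost, [assign]
        elif cost == best_cost:
            best.append(assign)
    return best_cost, best


def oracle_unambiguous(tree, optimal: list[dict[str, int]]) -> set[tuple[str, int, int]]:
    """Branch changes shared by every optimal assignment."""
    nodes = list(tree.preorder_node_iter())
    keys = {
        id(n): (n.taxon.label if n.is_leaf() else f"node{i}")
        for i, n in enumerate(nodes)
    }
    out = set()
    for n in nodes:
        for c in n.child_nodes():
            pairs = {(a[keys[id(n)]], a[keys[id(c)]]) for a in optimal}
            if len(pairs) == 1:
                i, j = next(iter(pairs))
                if i != j:
                    out.add((keys[id(c)], i, j))
    return out


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20210527)
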