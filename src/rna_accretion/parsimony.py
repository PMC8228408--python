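"""Ancestral state reconstruction for ordered characters and step-matrices.

Characters are ordered (Wagner): a change between states i and j costs
|i - j|, the path length on the linear character-state graph. Ancestral
reconstruction uses the Sankoff dynamic program over rooted trees
(polytomies handled natively). A state change on a branch is *unambiguous*
when every most-parsimonious reconstruction (MPR) assigns the same parent
and child states to that branch; unambiguous changes aggregated over the
characters of one class (helical or unpaired) form the step-matrix behind a
bubble chart.

Exact unambiguity is decided by bounded MPR enumeration. When a character's
MPR count exceeds ``mpr_limit``, the singleton final-set criterion is used
instead (a conservative lower bound on the change set) and a warning is
issued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import dendropy
import numpy as np

from .structure import SYMBOLS, CharacterMatrix

__all__ = [
    "Change",
    "MPRResult",
    "StepMatrix",
    "sankoff_cost",
    "mpr_reconstruct",
    "unambiguous_changes",
    "build_step_matrix",
    "export_bubble",
]

MAX_STATE = 35
CostFn = Callable[[int, int], float]


def _wagner_cost(i: int, j: int) -> int:
    return abs(i - j)


@dataclass(frozen=True)
class Change:
    """One unambiguous ancestral->descendant change on a branch.

    ``branch`` names the branch by its child node: the leaf label for
    terminal branches, else a stable preorder id like ``node3``.
    """

    branch: str
    from_state: int
    to_state: int


@dataclass
class MPRResult:
    """Sankoff reconstruction summary for one character on one tree."""

    min_cost: int
    #: node key -> set of states appearing in >= 1 MPR at that node
    final_sets: dict[str, frozenset[int]]
    #: all MPRs as node-key -> state maps, when enumerated within the limit
    mprs: list[dict[str, int]] | None = None
    #: total number of MPRs (exact even when not enumerated)
    n_mpr: int = 0


def _node_key(node: dendropy.Node, index: int) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return f"node{index}"


def _prepare(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, int],
    missing: str,
) -> tuple[list, dict, dict]:
    """Preorder node list, node->key map, and per-leaf states."""
    nodes = list(tree.preorder_node_iter())
    keys = {id(n): _node_key(n, i) for i, n in enumerate(nodes)}
    states = {}
    for n in nodes:
        if not n.is_leaf():
            continue
        label = n.taxon.label
        if label in leaf_states:
            s = leaf_states[label]
            if not 0 <= s <= MAX_STATE:
                raise ValueError(f"leaf {label!r}: state {s} outside 0..{MAX_STATE}")
            states[id(n)] = s
        elif missing == "absent":
            states[id(n)] = 0
        else:
            raise ValueError(f"leaf {label!r} has no observed state")
    return nodes, keys, states


def _state_range(states: dict, cost: CostFn | None) -> list[int]:
    # Under |i-j| costs every MPR keeps internal states within the observed
    # range (shifting an out-of-range block toward it strictly lowers cost);
    # a custom cost function forfeits that guarantee.
    if cost is None:
        lo, hi = min(states.values()), max(states.values())
        return list(range(lo, hi + 1))
    return list(range(MAX_STATE + 1))


def _down_pass(
    nodes: list, states: dict, S: list[int], cost: CostFn
) -> dict[int, dict[int, float]]:
    """Sankoff cost vectors g[node][s] = min cost of the subtree given s."""
    g: dict[int, dict[int, float]] = {}
    for n in reversed(nodes):  # postorder
        if n.is_leaf():
            s0 = states[id(n)]
            g[id(n)] = {s: (0 if s == s0 else float("inf")) for s in S}
        else:
            vec = {}
            for s in S:
                total = 0.0
                for c in n.child_nodes():
                    total += min(cost(s, t) + g[id(c)][t] for t in S)
                vec[s] = total
            g[id(n)] = vec
    return g


def sankoff_cost(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, int],
    cost: CostFn | None = None,
    missing: str = "absent",
) -> int:
    """Minimum total cost over all ancestral state assignments.

    ``cost`` defaults to the ordered-character metric |i - j|. Leaves absent
    from ``leaf_states`` are treated as state 0 (substructure absent) when
    ``missing='absent'``, or rejected when ``missing='error'``.
    """
    nodes, _, states = _prepare(tree, leaf_states, missing)
    S = _state_range(states, cost)
    g = _down_pass(nodes, states, S, cost or _wagner_cost)
    best = min(g[id(nodes[0])].values())
    return int(best)


def mpr_reconstruct(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, int],
    cost: CostFn | None = None,
    mpr_limit: int = 100_000,
    missing: str = "absent",
) -> MPRResult:
    """Full Sankoff reconstruction: cost, final sets, and (bounded) MPR list.

    Final sets contain every state a node takes in at least one MPR,
    obtained by the standard top-down backtrack. The complete MPR list is
    enumerated only while the MPR count stays within ``mpr_limit``.
    """
    cfun = cost or _wagner_cost
    nodes, keys, states = _prepare(tree, leaf_states, missing)
    S = _state_range(states, cost)
    g = _down_pass(nodes, states, S, cfun)
    root = nodes[0]
    min_cost = min(g[id(root)].values())

    # optimal child states given a parent state, per (node, parent state)
    def child_options(c: dendropy.Node, s: int) -> list[int]:
        vals = {t: cfun(s, t) + g[id(c)][t] for t in S}
        m = min(vals.values())
        return [t for t in S if vals[t] == m]

    # final sets by top-down propagation
    final: dict[int, set[int]] = {
        id(root): {s for s in S if g[id(root)][s] == min_cost}
    }
    for n in nodes:
        for c in n.child_nodes():
            opts: set[int] = set()
            for s in final[id(n)]:
                opts.update(child_options(c, s))
            final[id(c)] = opts

    # exact MPR count: M[v][s] = number of optimal subtree assignments
    M: dict[int, dict[int, int]] = {}
    for n in reversed(nodes):
        if n.is_leaf():
            M[id(n)] = {s: 1 for s in S if s == states[id(n)]}
        else:
            vec = {}
            for s in final[id(n)] | set(S):
                prod = 1
                for c in n.child_nodes():
                    prod *= sum(M[id(c)].get(t, 0) for t in child_options(c, s))
                vec[s] = prod
            M[id(n)] = vec
    n_mpr = sum(M[id(root)].get(s, 0) for s in final[id(root)])

    mprs: list[dict[str, int]] | None = None
    if n_mpr <= mpr_limit:
        mprs = []

        def expand(assignment: dict[str, int], pending: list) -> None:
            if not pending:
                mprs.append(dict(assignment))
                return
            node, s = pending[0]
            rest = pending[1:]
            children = node.child_nodes()

            def assign_children(k: int, extra: list) -> None:
                if k == len(children):
                    expand(assignment, extra + rest)
                    return
                c = children[k]
                for t in child_options(c, s):
                    assignment[keys[id(c)]] = t
                    nxt = [(c, t)] if not c.is_leaf() else []
                    assign_children(k + 1, extra + nxt)

            assign_children(0, [])

        for s in sorted(final[id(root)]):
            if g[id(root)][s] == min_cost:
                expand({keys[id(root)]: s}, [(root, s)])

    final_keyed = {keys[i]: frozenset(v) for i, v in final.items()}
    return MPRResult(
        min_cost=int(min_cost),
        final_sets=final_keyed,
        mprs=mprs,
        n_mpr=n_mpr,
    )


def unambiguous_changes(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, int],
    cost: CostFn | None = None,
    mpr_limit: int = 100_000,
    missing: str = "absent",
) -> list[Change]:
    """Branch changes present in *every* most-parsimonious reconstruction.

    A change i -> j (i != j) is reported on a branch iff all MPRs agree on
    both the parent state i and the child state j. Decided exactly by MPR
    enumeration when the MPR count is within ``mpr_limit``; otherwise the
    singleton final-set criterion is applied (a lower bound on the true
    unambiguous set) with a warning.
    """
    res = mpr_reconstruct(tree, leaf_states, cost, mpr_limit, missing)
    nodes = list(tree.preorder_node_iter())
    keys = {id(n): _node_key(n, i) for i, n in enumerate(nodes)}
    changes: list[Change] = []
    if res.mprs is not None:
        for n in nodes:
            for c in n.child_nodes():
                pk, ck = keys[id(n)], keys[id(c)]
                pairs = {(m[pk], m[ck]) for m in res.mprs}
                if len(pairs) == 1:
                    i, j = next(iter(pairs))
                    if i != j:
                        changes.append(Change(ck, i, j))
    else:
        warnings.warn(
            f"{res.n_mpr} MPRs exceed mpr_limit={mpr_limit}; "
            "using approximate singleton final-set criterion",
            stacklevel=2,
        )
        for n in nodes:
            for c in n.child_nodes():
                fp = res.final_sets[keys[id(n)]]
                fc = res.final_sets[keys[id(c)]]
                if len(fp) == 1 and len(fc) == 1:
                    (i,), (j,) = tuple(fp), tuple(fc)
                    if i != j:
                        changes.append(Change(keys[id(c)], i, j))
    return changes


@dataclass
class StepMatrix:
    """36x36 counts of unambiguous ancestral->descendant state changes.

    ``counts[i, j]`` is the number of i -> j changes summed over the
    characters of one class. The diagonal (stasis) is never counted.
    """

    counts: np.ndarray
    cls: str
    n_characters: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (MAX_STATE + 1, MAX_STATE + 1):
            raise ValueError("step matrix must be 36x36")

    @property
    def frequencies(self) -> np.ndarray:
        """Per-character average frequency of each change."""
        if self.n_characters == 0:
            return self.counts.astype(float)
        return self.counts / self.n_characters

    def single_step_fraction(self) -> float:
        """Fraction of all counted changes lying on the +-1 diagonals."""
        total = self.counts.sum()
        if total == 0:
            return float("nan")
        diag = sum(
            self.counts[i, j]
            for i in range(MAX_STATE + 1)
            for j in range(MAX_STATE + 1)
            if abs(i - j) == 1
        )
        return diag / total


def build_step_matrix(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    class_filter: str = "helical",
    mpr_limit: int = 100_000,
    missing: str = "absent",
) -> StepMatrix:
    """Sum unambiguous changes over all characters of one class.

    Works identically on trees of molecules and trees of substructures; the
    tree's leaf set decides which. Every matrix taxon must be a tree leaf.
    """
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    offenders = [t for t in matrix.taxa if t not in leaf_labels]
    if offenders:
        raise ValueError(f"matrix taxa missing from tree: {offenders}")
    counts = np.zeros((MAX_STATE + 1, MAX_STATE + 1), dtype=int)
    n_char = 0
    for ci, ch in enumerate(matrix.characters):
        if ch.cls != class_filter:
            continue
        n_char += 1
        leaf_states = {
            t: matrix.value(t, ch.label) for t in matrix.taxa
        }
        for change in unambiguous_changes(
            tree, leaf_states, mpr_limit=mpr_limit, missing=missing
        ):
            counts[change.from_state, change.to_state] += 1
    return StepMatrix(counts=counts, cls=class_filter, n_characters=n_char)


def export_bubble(sm: StepMatrix) -> str:
    """Long-format TSV of nonzero step-matrix cells (bubble-chart data).

    Columns: ancestral symbol, descendant symbol, count, and per-character
    average frequency.
    """
    lines = ["from\tto\tcount\tfrequency"]
    freq = sm.frequencies
    for i in range(MAX_STATE + 1):
        for j in range(MAX_STATE + 1):
            if sm.counts[i, j]:
                lines.append(
                    f"{SYMBOLS[i]}\t{SYMBOLS[j]}\t{sm.counts[i, j]}\t{freq[i, j]:.10g}"
                )
    return "\n".join(lines) + "\n"
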