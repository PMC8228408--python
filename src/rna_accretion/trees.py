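"""Rooted trees and node-distance chronologies.

Trees of substructures place each substructure of a molecule at a leaf; the
branching order of the (typically highly pectinate) tree gives the relative
age of each part. The age of a leaf is its *node distance* (nd): the number
of internal nodes between the root and the leaf, rescaled so the shallowest
leaf (the molecule's origin) sits at 0 and the deepest (the present
molecule) at 1. Branch lengths play no role; nd is a node count.

Parsing is delegated to dendropy; trees are consumed as rooted, exactly as
written, with polytomies preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy

__all__ = ["SubstructureAge", "parse_tree", "node_distance_ages", "leaf_depths", "ages_to_tsv"]


@dataclass(frozen=True)
class SubstructureAge:
    """Relative age of one leaf: 0 = origin of the molecule, 1 = present."""

    label: str
    nd: float


def parse_tree(text: str, format: str = "newick") -> dendropy.Tree:
    """Parse a rooted tree from Newick or NEXUS text.

    The tree is used as written: no re-rooting, polytomies preserved.
    Duplicate leaf labels are rejected.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=format,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"tree parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def leaf_depths(tree: dendropy.Tree) -> dict[str, int]:
    """Raw node depths: internal nodes on the root-to-leaf path, root counted.

    A leaf hanging directly off the root has depth 1. Exported for
    debugging; the nd normalization removes the root-counting constant.
    """
    depths: dict[str, int] = {}
    for leaf in tree.leaf_node_iter():
        d = 0
        node = leaf.parent_node
        while node is not None:
            d += 1
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def node_distance_ages(tree: dendropy.Tree) -> list[SubstructureAge]:
    """Relative node-distance ages for every leaf.

    nd(leaf) = (depth - min_depth) / (max_depth - min_depth). On a tree
    where all leaves are equally deep (e.g., fully balanced), all ages are
    0 and a degeneracy warning is issued.
    """
    depths = leaf_depths(tree)
    if len(depths) < 2:
        raise ValueError("node-distance ages need a tree with >= 2 leaves")
    lo, hi = min(depths.values()), max(depths.values())
    if lo == hi:
        warnings.warn(
            "all leaves at equal depth; node-distance ages degenerate to 0",
            stacklevel=2,
        )
        return [SubstructureAge(l, 0.0) for l in depths]
    return [
        SubstructureAge(l, (d - lo) / (hi - lo)) for l, d in depths.items()
    ]


def ages_to_tsv(ages: list[SubstructureAge]) -> str:
    """Two-column TSV ``label<TAB>nd``."""
    lines = ["label\tnd"]
    lines += [f"{a.label}\t{a.nd:.10g}" for a in ages]
    return "\n".join(lines) + "\n"
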