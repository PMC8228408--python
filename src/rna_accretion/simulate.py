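"""Synthetic accretion histories, trees, and evolving ordered characters.

The generators emulate the statistical structure the analysis assumes, so
every stage of the pipeline is testable without external data:

* pectinate trees of substructures whose leaf order encodes relative age;
* mean substructure lengths decaying as y(x) = A exp(-c x) with
  multiplicative lognormal noise;
* ordered multistate characters evolving by +-1 steps along the branches of
  a rooted tree (Poisson number of steps per branch, reflecting at the
  state-alphabet boundaries 0 and 35);
* families of dot-bracket molecules sharing a template topology with
  varying stem/loop lengths, usable as an end-to-end self-checking fixture.

All randomness flows from a single numpy Generator seeded by
``SyntheticConfig.seed``: identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .parsimony import MAX_STATE
from .stats import AccretionSeries, _accretion_ranks
from .structure import SecondaryStructure, Substructure, decompose
from .trees import node_distance_ages, parse_tree

import pandas as pd

__all__ = [
    "SyntheticConfig",
    "FixtureError",
    "gen_accretion_history",
    "simulate_ordered_character",
    "gen_molecule_set",
    "gen_molecule_tree",
    "pectinate_tree",
]


class FixtureError(RuntimeError):
    """A generated fixture failed its own self-check."""


@dataclass
class SyntheticConfig:
    """Generating conditions for synthetic accretion data.

    ``A_true``/``c_true`` default to the strongest observed decay regime for
    a small ancient RNA (an initial part of ~13.6 units shrinking by
    ~ 39% per added substructure); ``noise_sd`` is the sd of additive noise
    on ln y, i.e., multiplicative lognormal noise on lengths.
    """

    n_sub: int = 10
    A_true: float = 13.56
    c_true: float = 0.490
    noise_sd: float = 0.2
    n_taxa: int = 20
    step_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sub < 3:
            raise ValueError("n_sub must be >= 3")
        if self.A_true <= 0:
            raise ValueError("A_true must be positive")
        if self.c_true < 0 or self.noise_sd < 0:
            raise ValueError("c_true and noise_sd must be non-negative")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def pectinate_tree(labels: Sequence[str]) -> dendropy.Tree:
    """Fully pectinate (caterpillar) rooted tree; labels oldest-first.

    ``labels[0]`` branches off at the root, ``labels[-1]`` is the deepest
    leaf, so node-distance ages increase along the label order.
    """
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")
    newick = f"({labels[-2]},{labels[-1]})"
    for lab in reversed(labels[:-2]):
        newick = f"({lab},{newick})"
    return parse_tree(newick + ";", "newick")


def gen_accretion_history(
    cfg: SyntheticConfig,
) -> tuple[dendropy.Tree, AccretionSeries]:
    """A pectinate tree of substructures plus its noisy accretion series.

    Leaf i (labels ``sub1..subN``, oldest first) gets accretion rank x = i
    and mean length A_true * exp(-c_true * i) * exp(eps) with
    eps ~ Normal(0, noise_sd). Multiplicative noise keeps every length
    strictly positive, so no truncation is applied and the log-space model
    holds exactly. Ages are node-distance ages computed from the tree.
    """
    rng = cfg.rng()
    labels = [f"sub{i}" for i in range(1, cfg.n_sub + 1)]
    tree = pectinate_tree(labels)
    age_map = {a.label: a.nd for a in node_distance_ages(tree)}
    x = np.arange(1, cfg.n_sub + 1)
    eps = rng.normal(0.0, cfg.noise_sd, size=cfg.n_sub) if cfg.noise_sd else np.zeros(cfg.n_sub)
    y = cfg.A_true * np.exp(-cfg.c_true * x) * np.exp(eps)
    df = pd.DataFrame(
        {
            "label": labels,
            "cls": "helical",
            "nd": [age_map[l] for l in labels],
            "mean_length": y,
            "x": x,
        }
    )
    return tree, AccretionSeries(df)


def simulate_ordered_character(
    tree: dendropy.Tree,
    root_state: int,
    step_rate: float,
    seed: int,
    full: bool = False,
) -> dict[str, int] | tuple[dict[str, int], dict[str, int]]:
    """Evolve one ordered character down a tree by +-1 stepwise walks.

    Each branch draws Poisson(step_rate) unit steps, each +1 or -1 with
    equal probability, reflecting at the alphabet boundaries 0 and 35.
    Returns observed leaf states; with ``full`` also the true states of
    every node (leaves by label, internal nodes by preorder id), so tests
    can compare inferred change against realized change. Deterministic
    given the seed.
    """
    if not 0 <= root_state <= MAX_STATE:
        raise ValueError(f"root_state {root_state} outside 0..{MAX_STATE}")
    if step_rate < 0:
        raise ValueError("step_rate must be non-negative")
    rng = np.random.default_rng(seed)
    states: dict[int, int] = {}
    out: dict[str, int] = {}
    history: dict[str, int] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            states[id(node)] = root_state
        else:
            s = states[id(node.parent_node)]
            for _ in range(rng.poisson(step_rate)):
                step = 1 if rng.random() < 0.5 else -1
                s += step
                if s < 0:  # reflect at the bounded alphabet edges
                    s = 1
                elif s > MAX_STATE:
                    s = MAX_STATE - 1
            states[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label] = states[id(node)]
            history[node.taxon.label] = states[id(node)]
        else:
            history[f"node{i}"] = states[id(node)]
    if full:
        return out, history
    return out


def gen_molecule_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random rooted binary tree over ``t1..tN`` (uniform coalescent-style
    joins), for simulating character evolution over molecules."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [f"t{i}" for i in range(1, n_taxa + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return parse_tree(nodes[0] + ";", "newick")


@dataclass
class _Token:
    label: str
    kind: str
    length: int


#: template stem lengths (bp) and hairpin loop lengths (nt) for the default
#: four-armed molecule; joints of 2 nt separate the arms.
_TEMPLATE_STEMS = (7, 5, 5, 4)
_TEMPLATE_LOOPS = (4, 7, 7, 4)


def gen_molecule_set(
    cfg: SyntheticConfig,
    p_absent: float = 0.1,
    length_jitter: int = 1,
) -> tuple[list[SecondaryStructure], dict[tuple[str, int], str], pd.DataFrame]:
    """Dot-bracket molecules on a shared template, with the homology map.

    Each molecule strings together hairpin-stem arms from the template,
    separated by 2-nt joints and flanked by free ends, with per-molecule
    ``+-length_jitter`` variation. The last arm (the variable arm of the
    template) is absent with probability ``p_absent`` and coded '0'.
    Returns the structures, the (taxon, substructure-index) -> label
    homology map, and the expected per-taxon length table the decomposition
    must reproduce (the fixture self-checks and raises
    :class:`FixtureError` otherwise).
    """
    rng = cfg.rng()
    structures: list[SecondaryStructure] = []
    homology: dict[tuple[str, int], str] = {}
    rows = []
    n_arms = len(_TEMPLATE_STEMS)
    for t in range(1, cfg.n_taxa + 1):
        taxon = f"t{t}"
        absent_last = rng.random() < p_absent
        plan: list[_Token] = [_Token("fe5", "free_end_5p", int(rng.integers(1, 4)))]
        for a in range(n_arms):
            if a == n_arms - 1 and absent_last:
                continue
            k = max(1, _TEMPLATE_STEMS[a] + int(rng.integers(-length_jitter, length_jitter + 1)))
            h = max(3, _TEMPLATE_LOOPS[a] + int(rng.integers(-length_jitter, length_jitter + 1)))
            plan.append(_Token(f"stem{a + 1}", "stem", k))
            plan.append(_Token(f"loop{a + 1}", "hairpin_loop", h))
            if a < n_arms - 1:
                plan.append(_Token(f"joint{a + 1}", "joint", 2))
        # a dropped last arm leaves joint(n-1) dangling before the 3' end:
        # merge it into the 3' free end
        tail = _Token("fe3", "free_end_3p", int(rng.integers(1, 4)))
        if plan[-1].kind == "joint":
            tail.length += plan.pop().length
        plan.append(tail)

        db = []
        open_stem = 0
        for tok in plan:
            if tok.kind == "stem":
                db.append("(" * tok.length)
                open_stem = tok.length
            elif tok.kind == "hairpin_loop":
                db.append("." * tok.length + ")" * open_stem)
            else:
                db.append("." * tok.length)
        struct_line = "".join(db)
        s = SecondaryStructure(
            taxon, "", _pairs_from_brackets(struct_line), length=len(struct_line)
        )
        structures.append(s)

        subs = decompose(s)
        if len(subs) != len(plan):
            raise FixtureError(
                f"{taxon}: decomposition yields {len(subs)} parts, plan has {len(plan)}"
            )
        for idx, (sub, tok) in enumerate(zip(subs, plan)):
            if sub.kind != tok.kind or sub.length != tok.length:
                raise FixtureError(
                    f"{taxon}: part {idx} is {sub.kind}/{sub.length}, "
                    f"plan says {tok.kind}/{tok.length}"
                )
            homology[(taxon, idx)] = tok.label
            rows.append({"taxon": taxon, "label": tok.label, "length": tok.length})
    return structures, homology, pd.DataFrame(rows)


def _pairs_from_brackets(struct: str) -> set[tuple[int, int]]:
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, ch in enumerate(struct):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.add((stack.pop(), i))
    return pairs
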