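"""Parsimony optimization of continuous characters on a fixed topology.

Network descriptors are mapped onto a rooted phylogeny under linear
(Wagner/Farris) parsimony: ancestral states minimize the total absolute
change summed over branches, and each internal node gets the *interval* of
values attained by some minimal reconstruction.  Branch lengths are ignored
(topology-only optimization); polytomies are handled exactly, since the
minimizing interval at a node with k children is the median interval of the
2k child-interval endpoints.

The down-pass computes per-node state intervals and the minimal total
change; the up-pass refines each interval with the ancestral context so the
reported interval is the full set of most-parsimonious states at that node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd


class TreeError(ValueError):
    """Raised for malformed trees or tree/data mismatches."""


@dataclass
class PhyloNode:
    """One node of a rooted topology; ``children`` empty for leaves."""

    node_id: int
    label: str | None
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted topology with uniquely named leaves; branch lengths ignored."""

    def __init__(self, root: PhyloNode) -> None:
        self.root = root
        self.nodes: list[PhyloNode] = []
        self._collect(root)
        leaves = [n.label for n in self.nodes if n.is_leaf]
        if None in leaves or len(set(leaves)) != len(leaves):
            dupes = sorted({l for l in leaves if l is not None and leaves.count(l) > 1})
            raise TreeError(f"leaf labels must be unique and non-empty; duplicates: {dupes}")

    def _collect(self, node: PhyloNode) -> None:
        self.nodes.append(node)
        for child in node.children:
            self._collect(child)

    @property
    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves]  # type: ignore[misc]

    @property
    def internal_nodes(self) -> list[PhyloNode]:
        return [n for n in self.nodes if not n.is_leaf]


def parse_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick tree (path or string) into a :class:`PhyloTree`.

    Quoted labels and polytomies are preserved; duplicate leaf labels and
    malformed Newick raise :class:`TreeError`.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "(" not in source):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    counter = [0]

    def build(dnode) -> PhyloNode:
        node_id = counter[0]
        counter[0] += 1
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = PhyloNode(node_id=node_id, label=label)
        for child in dnode.child_nodes():
            node.children.append(build(child))
        return node

    root = build(dtree.seed_node)
    return PhyloTree(root)


def write_newick(tree: PhyloTree) -> str:
    def render(node: PhyloNode) -> str:
        if node.is_leaf:
            return _quote(node.label or "")
        inner = ",".join(render(c) for c in node.children)
        return f"({inner})"
    return render(tree.root) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Farris interval optimization

Interval = tuple[float, float]


def _interval_dist(x: Interval, y: Interval) -> float:
    """Gap between two closed intervals (0 when they intersect)."""
    return max(0.0, max(x[0], y[0]) - min(x[1], y[1]))


def _point_dist(x: float, iv: Interval) -> float:
    return max(0.0, iv[0] - x, x - iv[1])


def _median_interval(intervals: list[Interval]) -> Interval:
    """Minimizing interval of sum-of-distances to the given intervals.

    With k intervals the optimum set is [E_k, E_k+1] where E is the sorted
    multiset of all 2k endpoints (for k = 2 this is the intersection when it
    exists, else the gap-closing interval).
    """
    endpoints = sorted([e for iv in intervals for e in iv])
    k = len(intervals)
    return (endpoints[k - 1], endpoints[k])


@dataclass
class PhyloCharacterMap:
    """Ancestral-state intervals and minimal total change for one character."""

    character: str
    tree: PhyloTree
    intervals: dict[int, Interval]     # node_id -> [lo, hi]
    total_change: float

    def as_table(self) -> pd.DataFrame:
        rows = []
        for node in self.tree.nodes:
            lo, hi = self.intervals[node.node_id]
            rows.append({"node_id": node.node_id,
                         "label": node.label or "",
                         "is_leaf": node.is_leaf,
                         "character": self.character,
                         "lo": lo, "hi": hi})
        return pd.DataFrame(rows)


def farris_optimize(tree: PhyloTree, tip_values: dict[str, float],
                    character: str = "trait") -> PhyloCharacterMap:
    """Linear-parsimony ancestral intervals and minimal total change.

    Down-pass: each leaf gets the degenerate interval at its observed value;
    each internal node gets the median interval of its children's intervals,
    and the sum of gaps closed there accrues to the total change.  Up-pass:
    each non-root internal node's final interval is the median interval of
    its children's down-pass intervals together with its ancestral context
    (the median interval of its siblings' down-pass intervals and the
    parent's own context), giving the exact set of most-parsimonious states.
    """
    missing = [l for l in tree.leaf_names if l not in tip_values]
    if missing:
        raise TreeError(f"missing tip values for: {sorted(missing)}")

    down: dict[int, Interval] = {}
    total_change = 0.0

    def down_pass(node: PhyloNode) -> Interval:
        nonlocal total_change
        if node.is_leaf:
            v = float(tip_values[node.label])  # type: ignore[index]
            down[node.node_id] = (v, v)
            return down[node.node_id]
        child_ivs = [down_pass(c) for c in node.children]
        iv = _median_interval(child_ivs)
        # the summed distance is constant over the median interval; evaluate
        # it at the interval's lower end
        total_change += sum(_point_dist(iv[0], civ) for civ in child_ivs)
        down[node.node_id] = iv
        return iv

    down_pass(tree.root)

    final: dict[int, Interval] = {}
    final[tree.root.node_id] = down[tree.root.node_id]

    def up_pass(node: PhyloNode, context: Interval | None) -> None:
        for child in node.children:
            if child.is_leaf:
                final[child.node_id] = down[child.node_id]
                continue
            sibling_ivs = [down[c.node_id] for c in node.children if c is not child]
            surround = sibling_ivs + ([context] if context is not None else [])
            child_context = _median_interval(surround) if surround else None
            below = [down[c.node_id] for c in child.children]
            combined = below + ([child_context] if child_context is not None else [])
            final[child.node_id] = _median_interval(combined)
            up_pass(child, child_context)

    up_pass(tree.root, None)

    lo = min(tip_values[l] for l in tree.leaf_names)
    hi = max(tip_values[l] for l in tree.leaf_names)
    for iv in final.values():
        assert lo - 1e-9 <= iv[0] <= iv[1] <= hi + 1e-9, \
            "ancestral interval escapes the tip-value range"
    return PhyloCharacterMap(character=character, tree=tree, intervals=final,
                             total_change=total_change)


def map_descriptors(tree: PhyloTree, descriptor_table: pd.DataFrame,
                    variables: list[str] = ("D", "L", "C", "H", "P"),
                    ) -> dict[str, PhyloCharacterMap]:
    """Farris-optimize each descriptor column over the tree.

    The table's ``taxon`` column must align one-to-one with the tree leaves.
    """
    taxa = set(descriptor_table["taxon"].astype(str))
    leaves = set(tree.leaf_names)
    if taxa != leaves:
        raise TreeError(
            f"taxon mismatch: only in table {sorted(taxa - leaves)}, "
            f"only in tree {sorted(leaves - taxa)}")
    maps = {}
    for var in variables:
        tips = dict(zip(descriptor_table["taxon"].astype(str),
                        descriptor_table[var].astype(float)))
        maps[var] = farris_optimize(tree, tips, character=var)
    return maps


def maps_as_table(maps: dict[str, PhyloCharacterMap]) -> pd.DataFrame:
    """Long-format node x character interval table."""
    return pd.concat([m.as_table() for m in maps.values()], ignore_index=True)
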