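"""Stem/leaf segmentation of a tree skeleton by root-to-tip path counting.

For a rooted tree skeleton, the path from the root (the minimum-height tip)
to every other tip is unique.  A node belonging to more than two such paths
is labelled stem; the remaining nodes fall apart into connected leaf
segments, each hanging off exactly one stem junction.  Leaves are then ranked
bottom-up by their attachment height on the stem.

On a tree, "node on more than two root-to-tip paths" is equivalent to "the
subtree below the node contains more than two tips", which allows a linear
time implementation by subtree tip counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .skeleton import Node, SkeletonGraph, is_tree

Array = np.ndarray

__all__ = ["Leaf", "SegmentedPlant", "segment", "order_leaves",
           "path_count_stem_nodes", "subtree_tip_stem_nodes"]


@dataclass
class Leaf:
    """One leaf segment: its stem junction and the path out to its tip."""

    junction: Node
    path: list[Node]               # from the node adjacent to the junction to the tip
    attachment_height_mm: float
    azimuth_deg: float             # initial direction around the stem, for tie-breaks
    nodes: set[Node] = field(default_factory=set)
    rank: int | None = None


@dataclass
class SegmentedPlant:
    """Stem path plus leaf segments; stem and leaf nodes partition the skeleton."""

    skel: SkeletonGraph
    stem: list[Node]               # ordered from the root upward
    leaves: list[Leaf]
    used_fallback: bool = False    # True when the <=2-tip relaxation was applied

    @property
    def stem_xyz(self) -> Array:
        return self.skel.nodes_xyz(self.stem)

    def leaf_xyz(self, leaf: Leaf) -> Array:
        return self.skel.nodes_xyz(leaf.path)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.stem:
            x, y, z = self.skel.xyz(v)
            rows.append({"x_mm": x, "y_mm": y, "z_mm": z, "label": "stem"})
        for leaf in self.leaves:
            lab = f"leaf_{leaf.rank}" if leaf.rank is not None else "leaf"
            for v in sorted(leaf.nodes):
                x, y, z = self.skel.xyz(v)
                rows.append({"x_mm": x, "y_mm": y, "z_mm": z, "label": lab})
        return pd.DataFrame(rows)

    def leaf_summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rank": leaf.rank,
            "attach_height_mm": leaf.attachment_height_mm,
            "n_nodes": len(leaf.nodes),
        } for leaf in self.leaves])


def _rooted_tip_counts(g: nx.Graph, root: Node) -> dict[Node, int]:
    """Number of non-root tips in the subtree hanging below each node."""
    parent: dict[Node, Node | None] = {root: None}
    order: list[Node] = [root]
    for u in order:
        for v in sorted(g.neighbors(u)):
            if v not in parent:
                parent[v] = u
                order.append(v)
    counts = {v: 0 for v in order}
    for v in reversed(order):
        if g.degree(v) <= 1 and v != root:
            counts[v] = 1
        p = parent[v]
        if p is not None:
            counts[p] += counts[v]
    return counts


def path_count_stem_nodes(g: nx.Graph, root: Node, threshold: int = 2) -> set[Node]:
    """Stem nodes by the literal rule: count, for every tip, the unique
    root-to-tip path, and keep nodes on more than ``threshold`` paths."""
    counts: dict[Node, int] = {v: 0 for v in g.nodes}
    tips = [v for v in g.nodes if g.degree(v) <= 1 and v != root]
    for tip in tips:
        for v in nx.shortest_path(g, root, tip):
            counts[v] += 1
    return {v for v, c in counts.items() if c > threshold}


def subtree_tip_stem_nodes(g: nx.Graph, root: Node, threshold: int = 2) -> set[Node]:
    """Equivalent linear-time rule: nodes whose subtree holds more than
    ``threshold`` tips (the root lies on every path)."""
    counts = _rooted_tip_counts(g, root)
    return {v for v, c in counts.items() if c > threshold}


def segment(skel: SkeletonGraph, order: bool = True) -> SegmentedPlant:
    """Split a tree skeleton into a stem path and leaf segments.

    Raises on non-tree input.  For plants with two or fewer tips the literal
    more-than-two-paths rule labels nothing as stem; a relaxed at-least-two
    rule is applied instead and the result flagged.
    """
    if not is_tree(skel):
        raise ValueError("segmentation requires a tree skeleton")
    g = skel.graph
    root = skel.root()
    counts = _rooted_tip_counts(g, root)
    total_tips = counts[root]
    used_fallback = total_tips <= 2
    if used_fallback:
        stem_set = {v for v, c in counts.items() if c >= min(2, max(total_tips, 1))}
    else:
        stem_set = {v for v, c in counts.items() if c > 2}
    stem_set.add(root)

    # order stem nodes by tree distance from the root
    stem_sub = g.subgraph(stem_set)
    dist = nx.shortest_path_length(stem_sub, root)
    stem = sorted(stem_set, key=lambda v: (dist.get(v, np.inf),) + v)

    leaves: list[Leaf] = []
    rest = g.subgraph(v for v in g.nodes if v not in stem_set)
    for comp in nx.connected_components(rest):
        comp = set(comp)
        junctions = sorted({s for v in comp for s in g.neighbors(v) if s in stem_set},
                           key=lambda s: (skel.xyz(s)[2],) + s)
        if not junctions:
            continue
        junction = junctions[0]  # ties resolved to the lowest stem node
        starts = sorted(v for v in comp if junction in g.neighbors(v))
        start = starts[0]
        sub = g.subgraph(comp)
        # tip = geodesically farthest node from the attachment
        lengths = nx.single_source_dijkstra_path_length(sub, start, weight="length")
        tip = max(sorted(lengths), key=lambda v: (lengths[v],) + v)
        path = nx.dijkstra_path(sub, start, tip, weight="length")
        jx = skel.xyz(junction)
        head = skel.nodes_xyz(path[:min(3, len(path))]).mean(axis=0)
        azimuth = float(np.degrees(np.arctan2(head[1] - jx[1], head[0] - jx[0])) % 360.0)
        leaves.append(Leaf(junction=junction, path=path,
                           attachment_height_mm=float(jx[2]),
                           azimuth_deg=azimuth, nodes=comp))
    plant = SegmentedPlant(skel=skel, stem=stem, leaves=leaves,
                           used_fallback=used_fallback)
    return order_leaves(plant) if order else plant


def order_leaves(seg: SegmentedPlant) -> SegmentedPlant:
    """Assign ranks 1..k bottom-up by attachment height; ties broken by
    azimuth, then by path length."""
    ordered = sorted(seg.leaves, key=lambda l: (l.attachment_height_mm,
                                                l.azimuth_deg, len(l.path)))
    leaves = []
    for rank, leaf in enumerate(ordered, start=1):
        leaves.append(replace(leaf, rank=rank))
    return SegmentedPlant(skel=seg.skel, stem=seg.stem, leaves=leaves,
                          used_fallback=seg.used_fallback)
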