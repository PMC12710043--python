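"""Skeletonization of the voxel hull into a curve-skeleton graph.

The hull is thinned by 3-D topology-preserving thinning to a one-voxel-wide
skeleton, which is turned into a graph over skeleton voxels with
26-connectivity edges.  Disconnected fragments closer than a bridge length
are joined, terminal branches that do not look like plant organs are pruned,
and the result is expected to be a tree for a valid single-shoot plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_skeletonize

from .carving import VoxelGrid

Array = np.ndarray
Node = tuple[int, int, int]

__all__ = [
    "SkeletonGraph", "BranchFeatures", "BranchClassifier",
    "RuleBasedBranchClassifier", "MarginBranchClassifier",
    "thin", "join_gaps", "prune_spurious", "is_tree",
]

# the 13 lexicographically-positive offsets of the 26-neighbourhood
_OFFSETS = np.array([(a, b, c)
                     for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
                     if (a, b, c) > (0, 0, 0)], dtype=np.int64)


class DegenerateSkeletonError(ValueError):
    """Raised when an operation would destroy the entire skeleton."""


@dataclass
class SkeletonGraph:
    """Graph over skeleton voxels; nodes are integer grid triples.

    Node attributes: ``xyz`` (world mm) and ``radius`` (local hull radius from
    the distance transform, mm).  Edge attributes: ``length`` (mm) and
    ``is_bridge`` for gap-joining edges.
    """

    graph: nx.Graph
    voxel_size: float
    origin: Array

    def copy(self) -> "SkeletonGraph":
        return SkeletonGraph(self.graph.copy(), self.voxel_size, self.origin.copy())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def xyz(self, node: Node) -> Array:
        return self.graph.nodes[node]["xyz"]

    def nodes_xyz(self, nodes=None) -> Array:
        nodes = list(self.graph.nodes) if nodes is None else list(nodes)
        return np.array([self.graph.nodes[v]["xyz"] for v in nodes])

    def tips(self) -> list[Node]:
        return sorted(v for v, d in self.graph.degree if d <= 1)

    def root(self) -> Node:
        """The degree-1 node at minimum height (the pot surface end)."""
        tips = self.tips()
        if not tips:
            raise ValueError("skeleton has no degree-1 node to serve as root")
        return min(tips, key=lambda v: (self.graph.nodes[v]["xyz"][2],) + v)

    def components(self) -> list[set[Node]]:
        return sorted(nx.connected_components(self.graph), key=lambda c: -len(c))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node table and edge list for CSV serialization."""
        nodes = sorted(self.graph.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        ntab = pd.DataFrame({
            "node_id": [index[v] for v in nodes],
            "i": [v[0] for v in nodes],
            "j": [v[1] for v in nodes],
            "k": [v[2] for v in nodes],
            "x_mm": [self.graph.nodes[v]["xyz"][0] for v in nodes],
            "y_mm": [self.graph.nodes[v]["xyz"][1] for v in nodes],
            "z_mm": [self.graph.nodes[v]["xyz"][2] for v in nodes],
            "radius_mm": [self.graph.nodes[v].get("radius", np.nan) for v in nodes],
        })
        edges = [(index[a], index[b], d.get("is_bridge", False))
                 for a, b, d in self.graph.edges(data=True)]
        etab = pd.DataFrame(edges, columns=["node_a", "node_b", "is_bridge"])
        return ntab, etab

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        ntab, etab = self.to_frames()
        ntab.to_csv(prefix.with_suffix(".nodes.csv"), index=False)
        etab.to_csv(prefix.with_suffix(".edges.csv"), index=False)


def largest_component(skel: SkeletonGraph) -> SkeletonGraph:
    """Keep only the largest connected component.

    Fragments that remain disconnected after gap joining are phantom hull
    volume with no support near the plant; they cannot belong to a
    single-shoot skeleton.  Ties are broken toward the component containing
    the lowest node.
    """
    comps = skel.components()
    if len(comps) <= 1:
        return skel
    best_size = len(comps[0])
    tied = [c for c in comps if len(c) == best_size]
    comp = min(tied, key=lambda c: min((skel.graph.nodes[v]["xyz"][2],) + v for v in c))
    out = skel.copy()
    out.graph.remove_nodes_from(set(out.graph.nodes) - set(comp))
    return out


def is_tree(skel: SkeletonGraph) -> bool:
    """True iff the skeleton is connected and acyclic (|E| = |V| - 1)."""
    g = skel.graph
    if g.number_of_nodes() == 0:
        return False
    return nx.is_tree(g)


def thin(grid: VoxelGrid, compute_radius: bool = True) -> SkeletonGraph:
    """Reduce the hull to a one-voxel-wide skeleton graph.

    Uses 3-D topology-preserving thinning (medial-axis style iterative
    boundary removal), so the number of connected components of the hull is
    preserved.  Node radii are sampled from the Euclidean distance transform
    of the hull, giving a local thickness estimate in mm.
    """
    occ = grid.occupancy
    if not occ.any():
        raise ValueError("cannot skeletonize an empty grid")
    sk = _sk_skeletonize(occ).astype(bool)
    if not sk.any():
        # tiny objects can thin to nothing; keep the single most interior voxel
        dt = ndimage.distance_transform_edt(occ)
        sk = np.zeros_like(occ)
        sk[np.unravel_index(np.argmax(dt), occ.shape)] = True
    coords = np.argwhere(sk)
    if compute_radius:
        dt = ndimage.distance_transform_edt(occ)
        radii = dt[tuple(coords.T)] * grid.voxel_size
    else:
        radii = np.full(len(coords), np.nan)

    g = nx.Graph()
    xyz = grid.origin + (coords + 0.5) * grid.voxel_size
    for c, p, r in zip(map(tuple, coords.tolist()), xyz, radii):
        g.add_node(c, xyz=p, radius=float(r))

    flat = np.ravel_multi_index(coords.T, occ.shape)
    order = np.argsort(flat)
    flat_sorted = flat[order]
    coords_sorted = coords[order]
    shape = np.array(occ.shape)
    for off in _OFFSETS:
        nb = coords_sorted + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, occ.shape)
        pos = np.searchsorted(flat_sorted, nb_flat)
        pos = np.clip(pos, 0, len(flat_sorted) - 1)
        hit = flat_sorted[pos] == nb_flat
        a_idx = np.flatnonzero(ok)[hit]
        b_idx = pos[hit]
        step = float(np.linalg.norm(off) * grid.voxel_size)
        for a, b in zip(a_idx, b_idx):
            g.add_edge(tuple(coords_sorted[a].tolist()),
                       tuple(coords_sorted[b].tolist()),
                       length=step, is_bridge=False)
    return SkeletonGraph(graph=g, voxel_size=grid.voxel_size, origin=grid.origin.copy())


def join_gaps(skel: SkeletonGraph, max_bridge: float = 15.0) -> SkeletonGraph:
    """Bridge disconnected skeleton fragments whose closest node pair is
    within ``max_bridge`` mm, iterating until no two components are that
    close.  Bridge edges are flagged.  Already-connected input is returned
    unchanged (same object)."""
    if skel.n_nodes == 0 or nx.is_connected(skel.graph):
        return skel
    out = skel.copy()
    while True:
        comps = [sorted(c) for c in nx.connected_components(out.graph)]
        if len(comps) <= 1:
            break
        trees = []
        for comp in comps:
            pts = out.nodes_xyz(comp)
            trees.append((comp, pts, cKDTree(pts)))
        best = (np.inf, None, None)
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                ci, pi, ti = trees[i]
                cj, pj, tj = trees[j]
                d, idx = tj.query(pi)
                k = int(np.argmin(d))
                if d[k] < best[0]:
                    best = (float(d[k]), ci[k], cj[int(idx[k])])
        dist, a, b = best
        if dist > max_bridge:
            break
        out.graph.add_edge(a, b, length=dist, is_bridge=True)
    return out


@dataclass(frozen=True)
class BranchFeatures:
    """Shape features of one terminal branch (tip-to-junction path)."""

    length_mm: float
    mean_radius_mm: float
    straightness: float       # chord length / arc length, in (0, 1]
    attach_height_frac: float  # junction height / skeleton height range
    tip_height_frac: float

    def as_vector(self) -> Array:
        return np.array([self.length_mm, self.mean_radius_mm, self.straightness,
                         self.attach_height_frac, self.tip_height_frac])


class BranchClassifier(Protocol):
    def is_spurious(self, features: BranchFeatures) -> bool: ...


@dataclass
class RuleBasedBranchClassifier:
    """Deterministic fallback: a branch is spurious when it is shorter than
    ``min_length_mm`` or thinner than ``min_radius_mm``."""

    min_length_mm: float = 30.0
    min_radius_mm: float = 0.0

    def is_spurious(self, features: BranchFeatures) -> bool:
        if features.length_mm < self.min_length_mm:
            return True
        if (np.isfinite(features.mean_radius_mm)
                and features.mean_radius_mm < self.min_radius_mm):
            return True
        return False


class MarginBranchClassifier:
    """Linear margin classifier over branch features.

    Trained on synthetically labelled branches (organs vs. injected noise
    spurs); a functional stand-in for a pre-trained organ/noise classifier
    whose training data is not distributed."""

    def __init__(self) -> None:
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVC

        self._model = make_pipeline(StandardScaler(), LinearSVC())
        self._fitted = False

    def fit(self, features: list[BranchFeatures], spurious: list[bool]) -> "MarginBranchClassifier":
        x = np.array([f.as_vector() for f in features])
        self._model.fit(x, np.asarray(spurious, dtype=int))
        self._fitted = True
        return self

    def is_spurious(self, features: BranchFeatures) -> bool:
        if not self._fitted:
            raise RuntimeError("classifier has not been fitted")
        return bool(self._model.predict(features.as_vector()[None, :])[0])


def default_branch_classifier(skel: SkeletonGraph) -> RuleBasedBranchClassifier:
    """Scale-aware pruning rule for a given skeleton.

    Besides the minimum branch length, branches whose mean local radius is
    below ~1.5 voxels are treated as spurious: phantom visual-hull slivers
    (ghost intersections of view cones) are about one voxel thin, while real
    organs carry the full thickness of the plant part they came from.  The
    radius floor is capped at 80% of the skeleton's median node radius so the
    rule stays neutral on grids too coarse to resolve organ thickness.
    """
    radii = np.array([d.get("radius", np.nan)
                      for _, d in skel.graph.nodes(data=True)], dtype=float)
    med = np.nanmedian(radii) if np.isfinite(radii).any() else np.nan
    floor = 1.5 * skel.voxel_size
    if np.isfinite(med):
        floor = min(floor, 0.8 * med)
    return RuleBasedBranchClassifier(min_length_mm=30.0, min_radius_mm=floor)


def _terminal_branch(g: nx.Graph, tip: Node) -> tuple[list[Node], Node | None]:
    """Path from a tip to the first node of degree >= 3 (exclusive).

    Returns ``(branch_nodes, junction)``; ``junction`` is None when the walk
    exhausts the graph (pure path component)."""
    path = [tip]
    prev = None
    cur = tip
    while True:
        nbrs = [v for v in sorted(g.neighbors(cur)) if v != prev]
        if g.degree(cur) >= 3 and cur != tip:
            return path[:-1], cur
        if not nbrs:
            return path, None
        prev, cur = cur, nbrs[0]
        path.append(cur)


def _branch_features(skel: SkeletonGraph, branch: list[Node],
                     junction: Node | None) -> BranchFeatures:
    pts = skel.nodes_xyz(branch)
    seg = np.diff(pts, axis=0)
    arc = float(np.sum(np.linalg.norm(seg, axis=1))) if len(pts) > 1 else skel.voxel_size
    anchor = skel.xyz(junction) if junction is not None else pts[-1]
    chord = float(np.linalg.norm(pts[0] - anchor))
    radii = [skel.graph.nodes[v].get("radius", np.nan) for v in branch]
    zs = skel.nodes_xyz()[:, 2]
    zmin, zmax = float(zs.min()), float(zs.max())
    zrange = max(zmax - zmin, 1e-9)
    return BranchFeatures(
        length_mm=max(arc, skel.voxel_size),
        mean_radius_mm=float(np.nanmean(radii)) if len(radii) else np.nan,
        straightness=min(chord / max(arc, 1e-9), 1.0) if arc > 0 else 1.0,
        attach_height_frac=(float(anchor[2]) - zmin) / zrange,
        tip_height_frac=(float(pts[0][2]) - zmin) / zrange,
    )


def prune_spurious(skel: SkeletonGraph,
                   classifier: BranchClassifier | None = None) -> SkeletonGraph:
    """Delete terminal branches classified as spurious, cascading until stable.

    The branch containing the root tip (minimum-height end of the stem) is
    never pruned.  One branch (the shortest spurious one) is removed per pass
    so junction degrees update before re-evaluation.
    """
    out = skel.copy()
    if out.n_nodes == 0:
        return out
    if classifier is None:
        classifier = default_branch_classifier(skel)
    while True:
        g = out.graph
        root = out.root()
        candidates: list[tuple[float, list[Node], Node | None]] = []
        for tip in out.tips():
            if tip == root:
                continue
            branch, junction = _terminal_branch(g, tip)
            feats = _branch_features(out, branch, junction)
            spurious = classifier.is_spurious(feats)
            if spurious and junction is None and len(branch) >= g.number_of_nodes():
                # a pure path whose single branch is itself spurious: nothing
                # would remain of the skeleton
                raise DegenerateSkeletonError(
                    "pruning would delete the entire skeleton; input has no "
                    "non-spurious branch")
            if root in branch:
                continue  # never sever the stem from the ground
            if spurious:
                candidates.append((feats.length_mm, branch, junction))
        if not candidates:
            return out
        candidates.sort(key=lambda t: (t[0], t[1][0]))
        _, branch, junction = candidates[0]
        g.remove_nodes_from(branch)
        if g.number_of_nodes() == 0:
            raise DegenerateSkeletonError("pruning deleted every skeleton node")
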