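"""Dihedral-space clustering of conformers.

The pairwise distance between two structures is the mean circular distance
over the selected (alignment position, angle) variables where both have a
defined value at a shared non-gap column, so the distance stays in degrees
and is directly comparable to the cluster radius.  RMS and max aggregation
are available as alternatives.  Complete (maximum) linkage builds the
tree; flat clusters come from refusing every merge whose height reaches
the radius, making the radius literally the minimum distance allowed
between surviving clusters (default 60 degrees).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .circular import circ_dist
from .io import EnsembleError, PositionSelection, StructureListEntry

__all__ = ["DistanceMatrix", "ClusterTree", "ClusterResult",
           "structure_distance", "distance_matrix", "linkage_complete",
           "cut_tree", "emit_cluster_families", "to_newick", "cluster"]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # condensed upper triangle, degrees
    n_variables_used: list[int]  # per condensed pair

    def full(self) -> np.ndarray:
        n = len(self.labels)
        m = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = self.values[k]
                k += 1
        return m


@dataclass
class ClusterTree:
    """Merge list in scipy linkage convention.

    ``merges[k] = (a, b, height)`` joins nodes a and b (leaves are
    0..n-1, internal nodes n+k) at the given complete-linkage height.
    """
    merges: list[tuple[int, int, float]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class ClusterResult:
    labels: dict[str, int]  # structure label -> cluster id, 1-based
    radius: float
    tree: ClusterTree

    @property
    def n_clusters(self) -> int:
        return max(self.labels.values())


def structure_distance(t1: dict[tuple[int, str], float],
                       t2: dict[tuple[int, str], float],
                       selection: PositionSelection,
                       alignment: Alignment,
                       label1: str, label2: str,
                       aggregation: str = "mean") -> tuple[float, int]:
    """Distance between two structures' torsion maps, in degrees.

    ``t1``/``t2`` map (residue index, angle) to a defined torsion value.
    Variables compared are all (selected position, selected angle) pairs
    where both structures are non-gap and defined.
    """
    dists = []
    row1, row2 = alignment.cells[label1], alignment.cells[label2]
    for position in alignment.positions:
        if not selection.contains(position):
            continue
        col = alignment.column_of(position)
        i1, i2 = row1[col], row2[col]
        if i1 is None or i2 is None:
            continue
        for angle in selection.angles:
            v1, v2 = t1.get((i1, angle)), t2.get((i2, angle))
            if v1 is None or v2 is None:
                continue
            dists.append(circ_dist(v1, v2))
    if not dists:
        raise EnsembleError(
            f"no comparable dihedral variables between {label1!r} and {label2!r}")
    d = np.asarray(dists)
    if aggregation == "mean":
        value = float(d.mean())
    elif aggregation == "rms":
        value = float(np.sqrt(np.mean(d ** 2)))
    elif aggregation == "max":
        value = float(d.max())
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return value, len(dists)


def distance_matrix(torsion_maps: dict[str, dict],
                    labels: list[str],
                    selection: PositionSelection,
                    alignment: Alignment,
                    aggregation: str = "mean") -> DistanceMatrix:
    """Condensed pairwise distance matrix over the ensemble."""
    values, n_used = [], []
    for i, li in enumerate(labels):
        for lj in labels[i + 1:]:
            d, n = structure_distance(torsion_maps[li], torsion_maps[lj],
                                      selection, alignment, li, lj,
                                      aggregation=aggregation)
            values.append(d)
            n_used.append(n)
    if n_used and max(n_used) > 0 and min(n_used) < 0.5 * max(n_used):
        log.warning("number of compared dihedrals varies by more than 50%% "
                    "across pairs (%d..%d)", min(n_used), max(n_used))
    return DistanceMatrix(labels=list(labels), values=np.asarray(values),
                          n_variables_used=n_used)


def linkage_complete(d: DistanceMatrix) -> ClusterTree:
    """Agglomerative complete-linkage clustering.

    At every step the two clusters with the smallest maximum pairwise
    member distance are merged; ties are broken by the smallest leaf
    index contained in a cluster, so the tree is deterministic.
    """
    n = len(d.labels)
    if n < 2:
        raise EnsembleError("clustering requires at least 2 structures")
    full = d.full()
    # active cluster id -> (member leaf set, tree node id)
    active: dict[int, tuple[frozenset[int], int]] = {
        i: (frozenset([i]), i) for i in range(n)}
    # complete-linkage distance between active clusters
    dist: dict[tuple[int, int], float] = {
        (i, j): full[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        best = None
        for (i, j), h in dist.items():
            mi = min(active[i][0]); mj = min(active[j][0])
            lo, hi = (mi, mj) if mi < mj else (mj, mi)
            cand = (h, lo, hi, i, j)
            if best is None or cand < best:
                best = cand
        h, _, _, i, j = best
        mem_i, node_i = active[i]
        mem_j, node_j = active[j]
        # report child node ids ordered by smallest contained leaf
        if min(mem_i) > min(mem_j):
            node_i, node_j = node_j, node_i
        merges.append((node_i, node_j, float(h)))
        merged = mem_i | mem_j
        new_id = min(i, j)
        other = max(i, j)
        del active[other]
        active[new_id] = (merged, next_node)
        next_node += 1
        for k in list(active):
            if k == new_id:
                continue
            a, b = (k, new_id) if k < new_id else (new_id, k)
            d1 = dist.get((min(k, i), max(k, i)))
            d2 = dist.get((min(k, j), max(k, j)))
            dist[(a, b)] = max(x for x in (d1, d2) if x is not None)
        dist = {(a, b): v for (a, b), v in dist.items()
                if a in active and b in active and a != b}
    return ClusterTree(merges=merges, labels=list(d.labels))


def cut_tree(tree: ClusterTree, radius: float) -> ClusterResult:
    """Flat clusters from refusing merges at height >= radius.

    Cluster ids are 1-based, ordered by decreasing size (ties by smallest
    member index).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = tree.n_leaves
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    node_of = dict(members)  # tree node id -> member set
    for k, (a, b, h) in enumerate(tree.merges):
        node_of[n + k] = node_of[a] | node_of[b]
        if h < radius:
            ra, rb = find(min(node_of[a])), find(min(node_of[b]))
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    labels = {}
    for cid, group in enumerate(ordered, start=1):
        for i in group:
            labels[tree.labels[i]] = cid
    return ClusterResult(labels=labels, radius=radius, tree=tree)


def emit_cluster_families(result: ClusterResult,
                          entries: list[StructureListEntry]) -> str:
    """Regenerate the Structure list with cluster ids in the family column,
    ready to seed a follow-up run with cluster-defined families."""
    lines = []
    for e in entries:
        cid = result.labels[e.label]
        lines.append(f"{e.basename} {e.chain_spec} {cid}")
    return "\n".join(lines) + "\n"


def to_newick(tree: ClusterTree) -> str:
    """Newick text with branch lengths = parent height - child height."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h) in enumerate(tree.merges):
        height[n + k] = h
        children[n + k] = (a, b)

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{tree.labels[node]}:{bl:.12g}"
        a, b = children[node]
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{bl:.12g}"

    root = n + len(tree.merges) - 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"


def cluster(torsion_maps: dict[str, dict], labels: list[str],
            selection: PositionSelection, alignment: Alignment,
            radius: float = 60.0, aggregation: str = "mean",
            ) -> tuple[DistanceMatrix, ClusterTree, ClusterResult]:
    """Distance matrix -> complete-linkage tree -> radius cut, in one call."""
    dm = distance_matrix(torsion_maps, labels, selection, alignment,
                         aggregation=aggregation)
    tree = linkage_complete(dm)
    return dm, tree, cut_tree(tree, radius)
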