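"""Cluster-merger tree over a descending LD-threshold sweep.

The LD matrix defines a weighted graph on loci.  As the threshold drops
through the distinct observed r^2 values, connected components grow and
fuse; recording each fusion yields a tree equivalent to single-linkage
agglomeration with r^2 as similarity.  Ties (several edges at exactly the
same weight) trigger one simultaneous multi-way merge per resulting
component, so no arbitrary order among tied edges is invented.  Components
still separate when the edges run out are closed under a synthetic root at
threshold 0, keeping the tree total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ldna.core import LDMatrix


@dataclass
class ClusterNode:
    """One cluster in the merger tree.

    Leaves are single loci (``cluster_id`` equal to the locus index,
    ``formation_threshold`` 1.0).  Internal nodes are created by merge
    events; their id numbering starts at the locus count and follows event
    order, which makes ids deterministic given input order (presentation
    only -- semantics flow through member sets).
    """

    cluster_id: int
    members: np.ndarray  # sorted locus indices
    formation_threshold: float
    merge_threshold: float | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MergeEvent:
    threshold: float
    merging_clusters: list[int]
    new_cluster_id: int
    triggering_edges: list[tuple[int, int]]


@dataclass
class MergeTree:
    nodes: dict[int, ClusterNode]
    event_log: list[MergeEvent]
    locus_ids: np.ndarray
    root_id: int
    ld: LDMatrix | None = None

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def members_of(self, cluster_id: int) -> np.ndarray:
        return self.nodes[cluster_id].members

    def descendants(self, cluster_id: int):
        """All cluster ids strictly below ``cluster_id``."""
        stack = list(self.nodes[cluster_id].children)
        while stack:
            c = stack.pop()
            yield c
            stack.extend(self.nodes[c].children)


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_merge_tree(ld: LDMatrix) -> MergeTree:
    """Single-linkage merger tree of the LD graph.

    Processes distinct edge weights in strictly descending order; at each
    weight, every set of clusters connected by edges of that weight fuses
    in one multi-way event.  Runs in O(P log P) for P defined pairs
    (sorted edges plus union-find).
    """
    p = ld.n_loci
    if p < 2:
        raise ValueError("need at least 2 loci to build a merge tree")
    ii, jj, ww = ld.edges()
    order = np.argsort(-ww, kind="stable")
    ii, jj, ww = ii[order], jj[order], ww[order]

    nodes = {i: ClusterNode(i, np.array([i]), 1.0) for i in range(p)}
    dsu = _DisjointSet(p)
    current: dict[int, int] = {i: i for i in range(p)}  # DSU root -> cluster id
    event_log: list[MergeEvent] = []
    next_id = p

    # Group consecutive equal weights (exact float equality).
    start = 0
    while start < len(ww):
        stop = start
        w = ww[start]
        while stop < len(ww) and ww[stop] == w:
            stop += 1
        # Clusters touched by edges of this weight, linked at cluster level.
        group_edges = [(int(ii[k]), int(jj[k])) for k in range(start, stop)]
        cluster_pairs = []
        for a, b in group_edges:
            ca, cb = current[dsu.find(a)], current[dsu.find(b)]
            if ca != cb:
                cluster_pairs.append((ca, cb, (a, b)))
        if cluster_pairs:
            # Components among the touched premerger clusters.
            ids = sorted({c for ca, cb, _ in cluster_pairs for c in (ca, cb)})
            local = {c: k for k, c in enumerate(ids)}
            sub = _DisjointSet(len(ids))
            for ca, cb, _ in cluster_pairs:
                sub.union(local[ca], local[cb])
            comps: dict[int, list[int]] = {}
            for c in ids:
                comps.setdefault(sub.find(local[c]), []).append(c)
            for comp in comps.values():
                if len(comp) < 2:
                    continue
                comp_set = set(comp)
                trig = [
                    e for ca, cb, e in cluster_pairs if ca in comp_set and cb in comp_set
                ]
                members = np.sort(np.concatenate([nodes[c].members for c in comp]))
                new = ClusterNode(next_id, members, float(w), children=list(comp))
                nodes[next_id] = new
                for c in comp:
                    nodes[c].merge_threshold = float(w)
                    nodes[c].parent = next_id
                event_log.append(MergeEvent(float(w), list(comp), next_id, trig))
                anchor = int(members[0])
                for c in comp:
                    dsu.union(anchor, int(nodes[c].members[0]))
                # stale roots are never returned by find again, so leaving
                # their entries in `current` is harmless
                current[dsu.find(anchor)] = next_id
                next_id += 1
        start = stop

    # Close any remaining separate clusters under a synthetic root at 0.
    remaining = sorted({current[dsu.find(i)] for i in range(p)})
    if len(remaining) > 1:
        members = np.arange(p)
        nodes[next_id] = ClusterNode(next_id, members, 0.0, children=list(remaining))
        for c in remaining:
            nodes[c].merge_threshold = 0.0
            nodes[c].parent = next_id
        event_log.append(MergeEvent(0.0, list(remaining), next_id, []))
        root_id = next_id
    else:
        root_id = remaining[0]
    return MergeTree(nodes=nodes, event_log=event_log, locus_ids=ld.locus_ids, root_id=root_id, ld=ld)


def clusters_at_threshold(tree: MergeTree, t: float) -> list[np.ndarray]:
    """Partition of loci into clusters alive at LD threshold ``t``.

    A cluster is alive at ``t`` when it has formed (formation >= t) and has
    not yet merged (merge threshold < t, edges at exactly ``t`` being
    included in the graph).  Singletons are returned as size-1 arrays.
    Equivalent to connected components of the graph restricted to edges
    with r^2 >= t, but read off the tree.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out = []
    for node in tree.nodes.values():
        merged = node.merge_threshold is not None and node.merge_threshold >= t
        if node.formation_threshold >= t and not merged:
            out.append(node.members)
    return out


def cluster_edges(tree: MergeTree, cluster_id: int, t: float, ld: LDMatrix | None = None) -> int:
    """Number of intracluster pairs with r^2 >= t for the given cluster.

    The cluster must exist at ``t`` in the inclusive sense
    merge_threshold <= t <= formation_threshold (at its merge threshold a
    cluster is counted as itself for the last time; this is the convention
    used for the |E|_min outlier filter).
    """
    ld = ld or tree.ld
    if ld is None:
        raise ValueError("no LD matrix attached to the tree or supplied")
    node = tree.nodes.get(cluster_id)
    if node is None:
        raise KeyError(f"no cluster {cluster_id}")
    low = node.merge_threshold if node.merge_threshold is not None else 0.0
    if not low <= t <= node.formation_threshold:
        raise ValueError(
            f"cluster {cluster_id} does not exist at threshold {t:g} "
            f"(lives on [{low:g}, {node.formation_threshold:g}])"
        )
    sub = ld.values[np.ix_(node.members, node.members)]
    iu, ju = np.triu_indices(len(node.members), k=1)
    vals = sub[iu, ju]
    return int(np.sum(vals[~np.isnan(vals)] >= t))
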