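"""Cluster-tree construction from median marker profiles.

The hierarchy is the backbone of the whole analysis: every node of the
tree is a putative cell population (a union of clusters), and the tree's
parent/child edges define which %parent proportions exist.  Two families of
builders are provided:

* classic agglomerative clustering (average, Ward, single, complete,
  McQuitty/WPGMA linkage) on Euclidean distances between scaled cluster
  median profiles, giving strictly binary trees; and
* a HOPACH-style divisive builder that allows up to ``K`` children per
  node, choosing the number of children at each split by minimizing the
  median split silhouette (MSS) over PAM partitions.

Multi-way nodes matter scientifically: a binary tree forces every sibling
comparison to be pairwise, while a K-ary node lets one parent population
split directly into its natural subpopulations, so %parent matches how an
analyst would gate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .clustering import ClusterAssignment
from .io import EventTable

_LINKAGES = {
    "average": "average",
    "ward": "ward",
    "single": "single",
    "complete": "complete",
    "mcquitty": "weighted",  # WPGMA
}


# ---------------------------------------------------------------------------
# profiles


@dataclass
class ClusterProfile:
    """Per-cluster median marker expression, raw and column-scaled."""

    medians_raw: np.ndarray  # (n_clusters, n_markers)
    medians_scaled: np.ndarray
    cluster_ids: list
    marker_names: list
    cluster_sizes: np.ndarray
    scaling_method: str

    @property
    def n_clusters(self) -> int:
        return self.medians_raw.shape[0]


def _scale_columns(med: np.ndarray, method: str) -> np.ndarray:
    out = np.empty_like(med, dtype=float)
    for j in range(med.shape[1]):
        col = med[:, j]
        if method == "minmax":
            lo, hi = col.min(), col.max()
            out[:, j] = 0.5 if hi == lo else (col - lo) / (hi - lo)
        elif method == "zscore":
            mu, sd = col.mean(), col.std(ddof=0)
            out[:, j] = 0.0 if sd == 0 else (col - mu) / sd
        else:
            raise ValueError(f"unknown scaling method {method!r}")
    return out


def cluster_profiles(
    events: EventTable, assignment: ClusterAssignment, scaling: str = "minmax"
) -> ClusterProfile:
    """Median marker expression per cluster, scaled per marker across clusters.

    The scaled profile (default min-max to [0, 1] per marker) is what both
    tree builders and the heatmap consume: it puts every marker on the same
    footing regardless of its dynamic range.
    """
    if assignment.n_events != events.n_events:
        raise ValueError("assignment does not cover the event table")
    ids = assignment.cluster_ids
    med = np.empty((len(ids), events.n_markers), dtype=float)
    sizes = np.empty(len(ids), dtype=int)
    for i, cid in enumerate(ids):
        mask = assignment.labels == cid
        if not mask.any():  # guarded: ClusterAssignment forbids this
            raise ValueError(f"cluster {cid!r} has no events")
        med[i] = np.median(events.values[mask], axis=0)
        sizes[i] = int(mask.sum())
    return ClusterProfile(
        medians_raw=med,
        medians_scaled=_scale_columns(med, scaling),
        cluster_ids=list(ids),
        marker_names=list(events.marker_names),
        cluster_sizes=sizes,
        scaling_method=scaling,
    )


# ---------------------------------------------------------------------------
# tree container


@dataclass
class TreeNode:
    node_id: str
    parent: str | None = None
    children: list = field(default_factory=list)
    cluster: object | None = None  # set on leaves only
    height: float | None = None


class PhenoTree:
    """Rooted tree over clusters; leaves map 1:1 to cluster ids."""

    def __init__(self, method: str, max_children_K: int | None = None):
        self.nodes: dict[str, TreeNode] = {}
        self.root: str | None = None
        self.method = method
        self.max_children_K = max_children_K

    # -- construction -------------------------------------------------
    def _add(self, node: TreeNode) -> str:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node
        return node.node_id

    # -- queries ------------------------------------------------------
    def children(self, node_id: str) -> list[str]:
        return list(self.nodes[node_id].children)

    def parent(self, node_id: str) -> str | None:
        return self.nodes[node_id].parent

    def is_leaf(self, node_id: str) -> bool:
        return not self.nodes[node_id].children

    def leaves(self) -> list[str]:
        """Leaf node ids in depth-first order."""
        return [n for n in self.depth_first() if self.is_leaf(n)]

    def internal(self) -> list[str]:
        return [n for n in self.depth_first() if not self.is_leaf(n)]

    def depth_first(self) -> list[str]:
        out, stack = [], [self.root]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def postorder(self) -> list[str]:
        out: list[str] = []

        def rec(nid):
            for c in self.nodes[nid].children:
                rec(c)
            out.append(nid)

        rec(self.root)
        return out

    def leaf_clusters(self, node_id: str) -> frozenset:
        """Cluster ids of all leaves under (and including) a node."""
        out = set()
        stack = [node_id]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            if node.children:
                stack.extend(node.children)
            else:
                out.add(node.cluster)
        return frozenset(out)

    @property
    def leaf_to_cluster(self) -> dict:
        return {n: self.nodes[n].cluster for n in self.leaves()}

    def cluster_ids(self) -> list:
        return [self.nodes[n].cluster for n in self.leaves()]

    def root_path(self, node_id: str) -> list[str]:
        """Node ids from the root down to ``node_id`` inclusive."""
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path[::-1]

    # -- export -------------------------------------------------------
    def to_newick(self) -> str:
        def label(nid: str) -> str:
            node = self.nodes[nid]
            raw = str(node.cluster) if not node.children else nid
            if any(ch in raw for ch in "(),:;'\" \t\n[]"):
                return "'" + raw.replace("'", "''") + "'"
            return raw

        def branch_len(nid: str) -> float:
            node = self.nodes[nid]
            if node.parent is None:
                return 0.0
            ph = self.nodes[node.parent].height
            if self.method == "hopach" or ph is None:
                return 1.0
            return max(ph - (node.height or 0.0), 0.0)

        def rec(nid: str) -> str:
            node = self.nodes[nid]
            if not node.children:
                return f"{label(nid)}:{branch_len(nid):.10g}"
            inner = ",".join(rec(c) for c in node.children)
            if node.parent is None:
                return f"({inner}){label(nid)}"
            return f"({inner}){label(nid)}:{branch_len(nid):.10g}"

        return rec(self.root) + ";"

    def validate(self) -> None:
        """Check the structural invariants; raises on violation."""
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].node_id != self.root:
            raise ValueError("tree must have exactly one root")
        for nid, node in self.nodes.items():
            if node.children:
                union = set()
                total = 0
                for c in node.children:
                    if self.nodes[c].parent != nid:
                        raise ValueError(f"broken parent link at {c}")
                    cl = self.leaf_clusters(c)
                    total += len(cl)
                    union |= cl
                if total != len(union):
                    raise ValueError(f"children of {nid} overlap")
                if union != self.leaf_clusters(nid):
                    raise ValueError(f"children of {nid} do not partition its leaves")
            elif node.cluster is None:
                raise ValueError(f"leaf {nid} lacks a cluster id")
        clusters = self.cluster_ids()
        if len(set(clusters)) != len(clusters):
            raise ValueError("duplicate cluster ids on leaves")


def _leaf_id(cluster_id) -> str:
    return str(cluster_id)


# ---------------------------------------------------------------------------
# agglomerative builder


def build_tree_agglomerative(profile: ClusterProfile, linkage_method: str = "average") -> PhenoTree:
    """Binary tree from standard agglomerative clustering on scaled medians.

    Euclidean distances between the rows of ``medians_scaled``; merge
    heights are stored on internal nodes (leaves sit at height 0).
    """
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    n = profile.n_clusters
    if n < 2:
        raise ValueError("cannot build a tree over a single cluster")
    Z = linkage(profile.medians_scaled, method=_LINKAGES[linkage_method],
                metric="euclidean")
    tree = PhenoTree(method=linkage_method)
    ids = profile.cluster_ids
    node_of: dict[int, str] = {}
    for i, cid in enumerate(ids):
        nid = _leaf_id(cid)
        tree._add(TreeNode(node_id=nid, cluster=cid, height=0.0))
        node_of[i] = nid
    for k, (a, b, h, _size) in enumerate(Z):
        nid = f"N{k + 1}"
        ca, cb = node_of[int(a)], node_of[int(b)]
        tree._add(TreeNode(node_id=nid, children=[ca, cb], height=float(h)))
        tree.nodes[ca].parent = nid
        tree.nodes[cb].parent = nid
        node_of[n + k] = nid
    tree.root = node_of[2 * n - 2]
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# PAM (k-medoids): BUILD + SWAP, fully deterministic


def _assignment_cost(dist: np.ndarray, medoids: list[int]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


_EXHAUSTIVE_LIMIT = 5000  # max medoid subsets to enumerate exactly


def pam_partition(dist: np.ndarray, k: int) -> tuple[np.ndarray, list[int]]:
    """k-medoids partition: exact on small instances, classic PAM otherwise.

    When the number of candidate medoid subsets is small the optimum is
    found by enumeration; larger instances use PAM's greedy BUILD seeding
    followed by best-improvement SWAP.  Fully deterministic: all ties break
    toward the lowest index.  Returns ``(labels, medoid_indices)`` with
    labels in ``0..k-1`` ordered by medoid index.
    """
    dist = np.asarray(dist, dtype=float)
    m = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dist must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("dist must be symmetric")
    if not (2 <= k < m):
        raise ValueError(f"need 2 <= k < m; got k={k}, m={m}")

    from math import comb

    if comb(m, k) <= _EXHAUSTIVE_LIMIT:
        labels, medoids, _ = pam_brute_force(dist, k)
        return labels, medoids

    # BUILD: first medoid minimizes total distance; then greedily add the
    # point with the largest cost reduction.
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        best_gain, best_j = -np.inf, -1
        for j in range(m):
            if j in medoids:
                continue
            gain = np.maximum(nearest - dist[:, j], 0.0).sum()
            if gain > best_gain + 1e-15:
                best_gain, best_j = gain, j
        medoids.append(best_j)
        nearest = np.minimum(nearest, dist[:, best_j])

    # SWAP: repeat best single (medoid, candidate) swap while it strictly
    # lowers the total cost.
    medoids = sorted(medoids)
    cost = _assignment_cost(dist, medoids)
    while True:
        best_cost, best_swap = cost, None
        for mi_pos, mi in enumerate(medoids):
            for h in range(m):
                if h in medoids:
                    continue
                cand = medoids[:mi_pos] + [h] + medoids[mi_pos + 1 :]
                c = _assignment_cost(dist, cand)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi_pos, h)
        if best_swap is None:
            break
        mi_pos, h = best_swap
        medoids[mi_pos] = h
        medoids = sorted(medoids)
        cost = best_cost

    labels = np.argmin(dist[:, medoids], axis=1)
    for pos, med in enumerate(medoids):  # duplicates: a medoid stays in its own group
        labels[med] = pos
    return labels, medoids


def pam_brute_force(dist: np.ndarray, k: int) -> tuple[np.ndarray, list[int], float]:
    """Exhaustive search over all medoid subsets (small m only)."""
    m = dist.shape[0]
    best_cost, best_set = np.inf, None
    for subset in itertools.combinations(range(m), k):
        c = _assignment_cost(dist, list(subset))
        if c < best_cost - 1e-12:
            best_cost, best_set = c, list(subset)
    labels = np.argmin(dist[:, best_set], axis=1)
    for pos, med in enumerate(best_set):
        labels[med] = pos
    return labels, best_set, best_cost


# ---------------------------------------------------------------------------
# median split silhouette


def _silhouette_samples(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette width per item from a precomputed distance matrix.

    Items in singleton groups score 0 (no within-group distance exists).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("silhouette needs at least two groups")
    n = dist.shape[0]
    s = np.zeros(n, dtype=float)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == g].mean() for g in groups if g != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def mss(dist: np.ndarray, partition: np.ndarray, max_sub_k: int = 9) -> float:
    """Median split silhouette of a partition; lower = more homogeneous.

    Each group of size >= 3 is re-split by PAM with the sub-k (2..min
    (max_sub_k, size-1)) that maximizes the average silhouette; the group's
    score is the median of its members' silhouettes under that best
    sub-split.  Groups of size <= 2 score 0 by convention.  The MSS is the
    median of the group scores: a low value means groups have no crisp
    internal substructure left.
    """
    partition = np.asarray(partition)
    groups = list(dict.fromkeys(partition.tolist()))
    if len(groups) < 2:
        raise ValueError("MSS needs at least two groups")
    scores = []
    for g in groups:
        idx = np.flatnonzero(partition == g)
        if len(idx) <= 2:
            scores.append(0.0)
            continue
        sub = dist[np.ix_(idx, idx)]
        best_avg, best_sil = -np.inf, None
        for k in range(2, min(max_sub_k, len(idx) - 1) + 1):
            lab, _ = pam_partition(sub, k)
            sil = _silhouette_samples(sub, lab)
            if sil.mean() > best_avg + 1e-15:
                best_avg, best_sil = sil.mean(), sil
        scores.append(float(np.median(best_sil)))
    return float(np.median(scores))


# ---------------------------------------------------------------------------
# HOPACH-style divisive builder


def build_tree_hopach(profile: ClusterProfile, K: int = 5, seed: int = 0) -> PhenoTree:
    """Divisive K-ary tree: at each node, split by PAM with the child count
    (2..min(K, m-1)) minimizing the median split silhouette.

    Ties between candidate child counts break toward the smallest k.  The
    procedure is deterministic (PAM itself is deterministic); ``seed`` is
    accepted for interface symmetry with the other builders.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    n = profile.n_clusters
    if n < 2:
        raise ValueError("cannot build a tree over a single cluster")
    D = squareform(pdist(profile.medians_scaled, metric="euclidean"))
    tree = PhenoTree(method="hopach", max_children_K=K)
    counter = {"n": 0}
    ids = profile.cluster_ids

    def new_internal() -> str:
        counter["n"] += 1
        return f"N{counter['n']}"

    def make_leaf(item: int, parent: str) -> str:
        nid = _leaf_id(ids[item])
        tree._add(TreeNode(node_id=nid, parent=parent, cluster=ids[item]))
        return nid

    def split(items: list[int], parent: str | None) -> str:
        nid = new_internal()
        tree._add(TreeNode(node_id=nid, parent=parent))
        if len(items) == 2:
            tree.nodes[nid].children = [make_leaf(items[0], nid), make_leaf(items[1], nid)]
            return nid
        sub = D[np.ix_(items, items)]
        best_mss, best_labels, best_k = np.inf, None, None
        for k in range(2, min(K, len(items) - 1) + 1):
            lab, _ = pam_partition(sub, k)
            score = mss(sub, lab, max_sub_k=K)
            if score < best_mss - 1e-12:
                best_mss, best_labels, best_k = score, lab, k
        children = []
        for g in range(best_k):
            members = [items[i] for i in np.flatnonzero(best_labels == g)]
            if len(members) == 1:
                children.append(make_leaf(members[0], nid))
            else:
                children.append(split(members, nid))
        tree.nodes[nid].children = children
        return nid

    tree.root = split(list(range(n)), None)
    tree.validate()
    return tree


def build_tree(profile: ClusterProfile, method: str, K: int = 5, seed: int = 0) -> PhenoTree:
    """Dispatch to the HOPACH-style or an agglomerative builder."""
    if method == "hopach":
        return build_tree_hopach(profile, K=K, seed=seed)
    return build_tree_agglomerative(profile, linkage_method=method)


def export_newick(tree: PhenoTree) -> str:
    """Newick string: leaf labels are cluster ids, internal labels node ids."""
    return tree.to_newick()
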