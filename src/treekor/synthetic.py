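"""Ground-truth cytometry simulator with tree-structured compositions.

Samples are generated from a known cell-type tree by nested compositional
sampling: at every internal node each sample draws its own child split
proportions from a Dirichlet centred on the node's base proportions, cells
are allocated down the tree multinomially, and each cell's marker vector is
Gaussian around its leaf type's mean on the arcsinh scale (then mapped back
to the raw scale with ``sinh(x) * cofactor`` so the pipeline's own
transform reproduces the intended geometry).

Condition effects are injected on the logit of a single split proportion:

* ``effect_scale="parent"`` shifts the effect node's share of its direct
  parent in the second condition group — a pure %parent signal.  Making an
  ancestor's abundance highly variable (a low Dirichlet concentration at an
  ancestor split) then buries the corresponding %total signal in
  compositional noise, which is exactly the regime where parent-relative
  proportions outperform sample-relative ones.
* ``effect_scale="total"`` shifts the share of the effect node's depth-1
  ancestor at the root split, moving the node's %total while leaving its
  %parent untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._random import derive_seed
from .hierarchy import PhenoTree, TreeNode
from .io import EventTable, SampleMetadata


@dataclass
class SyntheticSpec:
    """Full parameterization of the generator."""

    truth_tree: dict                    # nested {child: subtree-or-None} under a root key
    base_split_props: dict              # internal node -> child proportions (sum to 1)
    marker_means: pd.DataFrame          # leaves x markers, arcsinh scale
    marker_sd: float = 0.6
    dirichlet_concentration: float | dict = 50.0
    effect_node: str | None = None
    effect_scale: str = "none"          # parent | total | none
    effect_delta: float = 0.0
    n_samples_per_group: int = 10
    cells_per_sample: int = 2000
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.effect_scale not in ("parent", "total", "none"):
            raise ValueError("effect_scale must be parent|total|none")
        if self.marker_sd <= 0:
            raise ValueError("marker_sd must be positive")
        concs = (self.dirichlet_concentration.values()
                 if isinstance(self.dirichlet_concentration, dict)
                 else [self.dirichlet_concentration])
        if any(c <= 0 for c in concs):
            raise ValueError("dirichlet concentrations must be positive")
        for node, props in self.base_split_props.items():
            if abs(sum(props) - 1.0) > 1e-12:
                raise ValueError(f"split proportions at {node!r} must sum to 1")

    def concentration_at(self, node: str) -> float:
        if isinstance(self.dirichlet_concentration, dict):
            return float(self.dirichlet_concentration.get(
                node, self.dirichlet_concentration.get("default", 50.0)))
        return float(self.dirichlet_concentration)


@dataclass
class GroundTruth:
    """What the generator actually drew, for validation against estimates."""

    labels: np.ndarray                   # per-event true leaf type
    realized_pct_total: pd.DataFrame     # nodes x samples, from the split draws
    realized_pct_parent: pd.DataFrame
    spec: SyntheticSpec
    tree: PhenoTree = None


def truth_phenotree(spec: SyntheticSpec) -> PhenoTree:
    """The ground-truth tree as a :class:`PhenoTree` (node ids = type names)."""
    (root_name, subtree), = spec.truth_tree.items()
    tree = PhenoTree(method="truth")

    def rec(name, sub, parent):
        node = TreeNode(node_id=name, parent=parent)
        tree._add(node)
        if sub is None:
            node.cluster = name
        else:
            node.children = [rec(cname, csub, name) for cname, csub in sub.items()]
        return name

    tree.root = rec(root_name, subtree, None)
    tree.validate()
    return tree


def _logit_shift(p: np.ndarray, idx: int, delta: float) -> np.ndarray:
    """Shift component ``idx`` on the logit scale, rescaling the rest."""
    p = np.asarray(p, dtype=float).copy()
    pi = p[idx]
    new = 1.0 / (1.0 + np.exp(-(np.log(pi / (1 - pi)) + delta)))
    rest = 1.0 - pi
    p *= (1.0 - new) / rest
    p[idx] = new
    return p


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[EventTable, SampleMetadata, GroundTruth]:
    """Draw one full dataset (events on the raw scale, metadata, truth).

    Deterministic for a fixed ``spec.seed``; regenerating with the same
    spec reproduces events bitwise.
    """
    tree = truth_phenotree(spec)
    leaves = tree.cluster_ids()
    if set(spec.marker_means.index) != set(leaves):
        raise ValueError("marker_means rows must match the truth-tree leaves")
    internal = [n for n in tree.depth_first() if not tree.is_leaf(n)]
    for n in internal:
        if len(spec.base_split_props.get(n, [])) != len(tree.children(n)):
            raise ValueError(f"base_split_props missing or mis-sized at {n!r}")

    effect_split_node, effect_child_idx = None, None
    if spec.effect_scale != "none":
        if spec.effect_node not in tree.nodes or spec.effect_node == tree.root:
            raise ValueError(
                f"effect_node {spec.effect_node!r} must be a non-root node of the truth tree")
        path = tree.root_path(spec.effect_node)
        if spec.effect_scale == "parent":
            effect_split_node = tree.parent(spec.effect_node)
            effect_child_idx = tree.children(effect_split_node).index(spec.effect_node)
        else:  # total: shift the depth-1 ancestor's share at the root
            effect_split_node = tree.root
            effect_child_idx = tree.children(tree.root).index(path[1])

    rng = np.random.default_rng(derive_seed(spec.seed, "synthetic"))
    n_per = spec.n_samples_per_group
    sample_ids = [f"s{i + 1:02d}" for i in range(2 * n_per)]
    groups = ["G1"] * n_per + ["G2"] * n_per

    all_nodes = tree.depth_first()
    node_row = {n: i for i, n in enumerate(all_nodes)}
    pct_total_arr = np.full((len(all_nodes), len(sample_ids)), np.nan)
    pct_parent_arr = np.full((len(all_nodes), len(sample_ids)), np.nan)

    marker_names = list(spec.marker_means.columns)
    mean_lookup = {leaf: spec.marker_means.loc[leaf].to_numpy(dtype=float)
                   for leaf in leaves}

    blocks, label_blocks, sid_blocks = [], [], []
    for s_i, (sid, grp) in enumerate(zip(sample_ids, groups)):
        splits = {}
        for node in internal:
            base = np.asarray(spec.base_split_props[node], dtype=float)
            if grp == "G2" and node == effect_split_node:
                base = _logit_shift(base, effect_child_idx, spec.effect_delta)
            splits[node] = rng.dirichlet(spec.concentration_at(node) * base)

        pct_parent_arr[node_row[tree.root], s_i] = 1.0
        pct_total_arr[node_row[tree.root], s_i] = 1.0
        for node in internal:
            for i, child in enumerate(tree.children(node)):
                pct_parent_arr[node_row[child], s_i] = splits[node][i]
                pct_total_arr[node_row[child], s_i] = (
                    pct_total_arr[node_row[node], s_i] * splits[node][i])

        counts = {tree.root: spec.cells_per_sample}
        for node in all_nodes:
            if tree.is_leaf(node):
                continue
            alloc = rng.multinomial(counts[node], splits[node])
            for child, c in zip(tree.children(node), alloc):
                counts[child] = int(c)

        n_cells = spec.cells_per_sample
        labels = np.empty(n_cells, dtype=object)
        vals = np.empty((n_cells, len(marker_names)), dtype=float)
        pos = 0
        for leaf in leaves:
            c = counts[leaf]
            if c == 0:
                continue
            labels[pos : pos + c] = leaf
            vals[pos : pos + c] = rng.normal(
                mean_lookup[leaf], spec.marker_sd, size=(c, len(marker_names)))
            pos += c
        blocks.append(vals)
        label_blocks.append(labels)
        sid_blocks.append(np.repeat(sid, n_cells))

    arcsinh_vals = np.vstack(blocks)
    events = EventTable(
        values=np.sinh(arcsinh_vals) * spec.cofactor,
        marker_names=marker_names,
        sample_ids=np.concatenate(sid_blocks),
        transformed=False,
    )
    meta = SampleMetadata(
        table=pd.DataFrame({"sample_id": sample_ids, "condition": groups}))
    truth = GroundTruth(
        labels=np.concatenate(label_blocks),
        realized_pct_total=pd.DataFrame(pct_total_arr, index=all_nodes, columns=sample_ids),
        realized_pct_parent=pd.DataFrame(pct_parent_arr, index=all_nodes, columns=sample_ids),
        spec=spec,
        tree=tree,
    )
    return events, meta, truth


# ---------------------------------------------------------------------------
# canned scenarios

_HI, _LO = 3.5, 0.5


def _default_tree() -> tuple[dict, dict]:
    # A1a is deliberately a minor subpopulation of A1 (25%), echoing the
    # activated subsets (e.g. HLA-DR+CD38+) whose %parent carries signal
    # that their %total misses.
    tree = {"root": {
        "A": {"A1": {"A1a": None, "A1b": None}, "A2": {"A2a": None, "A2b": None}},
        "B": {"B1": {"B1a": None, "B1b": None}, "B2": {"B2a": None, "B2b": None}},
        "C": {"C1": {"C1a": None, "C1b": None}, "C2": {"C2a": None, "C2b": None}},
    }}
    splits = {
        "root": [0.5, 0.3, 0.2],
        "A": [0.5, 0.5], "B": [0.6, 0.4], "C": [0.55, 0.45],
        "A1": [0.25, 0.75], "A2": [0.6, 0.4], "B1": [0.5, 0.5],
        "B2": [0.55, 0.45], "C1": [0.6, 0.4], "C2": [0.5, 0.5],
    }
    return tree, splits


def _default_marker_means() -> pd.DataFrame:
    """Hierarchical marker patterns: lineage markers dominate, as in real panels.

    M1-M3 are one-hot lineage markers (A/B/C) and M7 a lineage gradient, so
    cross-lineage phenotypic distance is largest; M4/M5 separate the
    depth-2 branches, the single marker M6 separates the two leaves of a
    pair, and M8 is uninformative.  Phenotypic similarity therefore mirrors
    the truth tree — sister leaves are closest, lineages farthest — so a
    hierarchy built on cluster medians can recover the nesting.
    """
    markers = [f"M{i}" for i in range(1, 9)]
    rows = {}
    for br_i, branch in enumerate("ABC"):
        for sub in ("1", "2"):
            for leaf in ("a", "b"):
                name = f"{branch}{sub}{leaf}"
                rows[name] = [
                    _HI if branch == "A" else _LO,
                    _HI if branch == "B" else _LO,
                    _HI if branch == "C" else _LO,
                    _HI if sub == "1" else _LO,
                    _HI if sub == "2" else _LO,
                    _HI if leaf == "a" else _LO,
                    1.0 + br_i,
                    1.5,
                ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=markers)


def default_spec(scenario: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Fixed, documented study conditions.

    ``paper_like`` is the base: a 3-level tree with 12 leaf cell types, 10
    samples per group, 2,000 cells per sample, 8 markers.  ``null`` adds no
    condition effect; ``parent_effect`` shifts the A1a:A1b split (logit
    shift 1.0) in group G2 while making the top-level lineage composition
    highly variable (concentration 4 at the root split), so the effect
    node's %total drowns in compositional noise while its %parent stays
    clean; ``total_effect`` shifts the A lineage's share at the root
    instead, moving A1a's %total but not its %parent.
    """
    tree, splits = _default_tree()
    base = dict(
        truth_tree=tree,
        base_split_props=splits,
        marker_means=_default_marker_means(),
        marker_sd=0.6,
        dirichlet_concentration=50.0,
        n_samples_per_group=10,
        cells_per_sample=2000,
        cofactor=5.0,
        seed=seed,
    )
    if scenario in ("null", "paper_like"):
        spec = SyntheticSpec(**base, effect_scale="none")
    elif scenario == "parent_effect":
        base["dirichlet_concentration"] = {"default": 50.0, "root": 4.0}
        spec = SyntheticSpec(
            **base,
            effect_node="A1a",
            effect_scale="parent",
            effect_delta=1.0,
        )
    elif scenario == "total_effect":
        spec = SyntheticSpec(
            **base,
            effect_node="A1a",
            effect_scale="total",
            effect_delta=1.0,
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def best_matching_node(tree: PhenoTree, assignment, target_mask: np.ndarray) -> str:
    """Derived-tree node whose event set best matches a truth event set.

    For every node of ``tree`` the induced event set is the set of events
    whose cluster lies under the node; the match score is the Jaccard index
    with ``target_mask``.  Used to locate a ground-truth population inside
    a data-derived hierarchy.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    n_target = int(target_mask.sum())
    inter_by_cluster: dict = {}
    size_by_cluster: dict = {}
    for cid in assignment.cluster_ids:
        m = assignment.labels == cid
        size_by_cluster[cid] = int(m.sum())
        inter_by_cluster[cid] = int((m & target_mask).sum())
    best, best_j = None, -1.0
    for nid in tree.depth_first():
        clusters = tree.leaf_clusters(nid)
        inter = sum(inter_by_cluster.get(c, 0) for c in clusters)
        size = sum(size_by_cluster.get(c, 0) for c in clusters)
        union = size + n_target - inter
        j = inter / union if union else 0.0
        if j > best_j + 1e-12:
            best, best_j = nid, j
    return best
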