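"""Per-node, per-sample cell counts and the two proportion scales.

Every node of the tree gets, per sample, its raw cell count, its
proportion of all cells in the sample (%total) and its proportion of its
direct parent node's cells (%parent).  The two scales answer different
questions: %total reflects absolute compositional shifts, while %parent
isolates the split between a population and its siblings, mimicking
sequential manual gating.  The telescoping identity

    %total(node) = prod of %parent over the root -> node path

holds exactly wherever all denominators are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .hierarchy import PhenoTree
from .io import EventTable


@dataclass
class ProportionMatrix:
    """%total and %parent per node x sample, with raw counts."""

    counts: pd.DataFrame       # nodes x samples, ints
    pct_total: pd.DataFrame    # nodes x samples, in [0, 1]
    pct_parent: pd.DataFrame   # nodes x samples, in [0, 1], NaN where parent empty
    tree: PhenoTree

    @property
    def node_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)


def node_counts(
    assignment: ClusterAssignment, tree: PhenoTree, events: EventTable
) -> pd.DataFrame:
    """Cell counts per tree node (rows) and sample (columns).

    Leaf counts come straight from the cluster assignment; internal counts
    are recursive sums over children, so for every internal node the count
    equals the children's total and the root row equals each sample's
    event count.
    """
    tree_clusters = set(tree.cluster_ids())
    missing = set(assignment.cluster_ids) - tree_clusters
    if missing:
        raise ValueError(f"clusters missing from tree leaves: {sorted(map(str, missing))}")
    samples = list(dict.fromkeys(events.sample_ids))
    cross = pd.crosstab(
        pd.Series(assignment.labels, name="cluster"),
        pd.Series(events.sample_ids, name="sample"),
    ).reindex(columns=samples, fill_value=0)

    order = tree.postorder()
    counts = pd.DataFrame(0, index=order, columns=samples, dtype=int)
    for nid in order:
        node = tree.nodes[nid]
        if not node.children:
            if node.cluster in cross.index:
                counts.loc[nid] = cross.loc[node.cluster].to_numpy()
        else:
            counts.loc[nid] = counts.loc[node.children].sum(axis=0).to_numpy()
    # present rows in depth-first order for readability
    return counts.loc[tree.depth_first()]


def percent_total(counts: pd.DataFrame, tree: PhenoTree) -> pd.DataFrame:
    """Each node's count divided by the sample's total (the root count)."""
    root_row = counts.loc[tree.root]
    zero = root_row[root_row <= 0]
    if len(zero):
        raise ValueError(f"samples with zero events: {list(zero.index)}")
    return counts / root_row


def percent_parent(counts: pd.DataFrame, tree: PhenoTree, depth: int = 1) -> pd.DataFrame:
    """Each node's count divided by its ancestor's count (direct parent by
    default).

    The root is 1 by definition.  With ``depth > 1`` the denominator is the
    ancestor ``depth`` levels up (clipped at the root), giving
    broader-reference proportions.  Where the ancestor has zero cells in a
    sample the ratio is undefined and stored as NaN rather than 0: a zero
    would assert an observed absence the data cannot support.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    out = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns, dtype=float)
    out.loc[tree.root] = 1.0
    for nid in counts.index:
        par = tree.parent(nid)
        if par is None:
            continue
        for _ in range(depth - 1):
            up = tree.parent(par)
            if up is None:
                break
            par = up
        denom = counts.loc[par].to_numpy(dtype=float)
        num = counts.loc[nid].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, num / denom, np.nan)
        out.loc[nid] = vals
    return out


def compute_proportions(
    assignment: ClusterAssignment, tree: PhenoTree, events: EventTable,
    parent_depth: int = 1,
) -> ProportionMatrix:
    """Convenience wrapper: counts + both proportion scales in one object."""
    counts = node_counts(assignment, tree, events)
    return ProportionMatrix(
        counts=counts,
        pct_total=percent_total(counts, tree),
        pct_parent=percent_parent(counts, tree, depth=parent_depth),
        tree=tree,
    )
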