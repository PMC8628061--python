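"""Result graphics: annotated tree + heatmap, statistic scatter, Q-Q plot.

All figures are written as SVG by default (PNG by extension) and every plot
also writes a CSV sidecar with the exact plotted coordinates, so figure
content is testable without parsing vector graphics.  Node glyphs are
colored by the %total statistic and the edge leading into each node by that
node's %parent statistic, on a shared symmetric diverging scale, so the two
statistics are directly visually comparable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")  # noqa: E402 — headless backend before pyplot
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import Normalize

from .hierarchy import ClusterProfile, PhenoTree

log = logging.getLogger(__name__)

_CMAP = "coolwarm"


def _tree_layout(tree: PhenoTree) -> dict[str, tuple[float, float]]:
    """x = depth from root, y = mean of children's y; leaves evenly spaced."""
    pos: dict[str, tuple[float, float]] = {}
    leaves = tree.leaves()
    y_of = {leaf: float(i) for i, leaf in enumerate(leaves)}

    def depth(nid):
        d = 0
        while tree.parent(nid) is not None:
            nid = tree.parent(nid)
            d += 1
        return d

    for nid in tree.postorder():
        if tree.is_leaf(nid):
            pos[nid] = (float(depth(nid)), y_of[nid])
        else:
            ys = [pos[c][1] for c in tree.children(nid)]
            pos[nid] = (float(depth(nid)), float(np.mean(ys)))
    return pos


def _stat_limits(results: pd.DataFrame) -> float:
    stats = np.concatenate([
        results["stat_total"].to_numpy(dtype=float),
        results["stat_parent"].to_numpy(dtype=float),
    ])
    stats = stats[np.isfinite(stats)]
    return float(np.max(np.abs(stats))) if len(stats) else 1.0


def plot_tree_heatmap(
    tree: PhenoTree,
    profile: ClusterProfile,
    results: pd.DataFrame,
    out,
) -> Path:
    """Tree colored by test statistics next to the leaf-profile heatmap.

    Nodes are colored by ``stat_total``, the edge from a node's parent by
    the node's ``stat_parent``; heatmap rows follow the depth-first leaf
    order of the tree.
    """
    out = Path(out)
    known = set(tree.nodes)
    if not set(results["node_id"]) <= known:
        raise ValueError("results contain node ids absent from the tree")
    stat_total = dict(zip(results["node_id"], results["stat_total"]))
    stat_parent = dict(zip(results["node_id"], results["stat_parent"]))
    lim = _stat_limits(results)
    norm = Normalize(vmin=-lim, vmax=lim)
    cmap = plt.get_cmap(_CMAP)
    pos = _tree_layout(tree)
    leaves = tree.leaves()
    cluster_row = {cid: i for i, cid in enumerate(profile.cluster_ids)}

    fig, (ax_tree, ax_hm) = plt.subplots(
        1, 2, figsize=(12, max(4, 0.3 * len(leaves))),
        gridspec_kw={"width_ratios": [2, 3]}, sharey=True)

    sidecar_rows = []
    for nid in tree.depth_first():
        x, y = pos[nid]
        st = stat_total.get(nid, np.nan)
        sp = stat_parent.get(nid, np.nan)
        parent = tree.parent(nid)
        if parent is not None:
            px, py = pos[parent]
            color = cmap(norm(sp)) if np.isfinite(sp) else "0.7"
            ax_tree.plot([px, px, x], [py, y, y], color=color, lw=2, zorder=1)
        node_color = cmap(norm(st)) if np.isfinite(st) else "0.7"
        ax_tree.scatter([x], [y], s=60, color=node_color, edgecolor="k",
                        linewidth=0.5, zorder=2)
        sidecar_rows.append({"node_id": nid, "x": x, "y": y,
                             "stat_total": st, "stat_parent": sp})
    ax_tree.set_title("node: %total stat, edge: %parent stat")
    ax_tree.set_xlabel("depth")
    ax_tree.invert_xaxis()
    ax_tree.set_yticks(range(len(leaves)))
    ax_tree.set_yticklabels([str(tree.nodes[n].cluster) for n in leaves])

    hm_rows = np.array([cluster_row[tree.nodes[n].cluster] for n in leaves])
    hm = profile.medians_scaled[hm_rows]
    ax_hm.imshow(hm, aspect="auto", cmap="viridis",
                 extent=(-0.5, hm.shape[1] - 0.5, len(leaves) - 0.5, -0.5))
    ax_hm.set_xticks(range(len(profile.marker_names)))
    ax_hm.set_xticklabels(profile.marker_names, rotation=90)
    ax_hm.set_title(f"scaled median expression ({profile.scaling_method})")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax_tree,
                 label="test statistic")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)

    pd.DataFrame(sidecar_rows).to_csv(out.with_suffix(".csv"), index=False)
    pd.DataFrame(hm, index=[str(tree.nodes[n].cluster) for n in leaves],
                 columns=profile.marker_names).to_csv(
        out.with_name(out.stem + "_heatmap.csv"))
    return out


def plot_stat_scatter(results: pd.DataFrame, out, highlight=None) -> Path:
    """One point per node at (stat_total, stat_parent), with identity line."""
    out = Path(out)
    if results.empty:
        raise ValueError("results table is empty")
    df = results[["node_id", "stat_total", "stat_parent"]].copy()
    finite = np.isfinite(df["stat_total"]) & np.isfinite(df["stat_parent"])
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.info("stat scatter: omitting %d nodes with missing statistics", n_dropped)
    df = df[finite]
    lim = _stat_limits(results) * 1.05 or 1.0

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([-lim, lim], [-lim, lim], ls="--", color="0.6", lw=1)
    ax.scatter(df["stat_total"], df["stat_parent"], s=25, color="tab:blue",
               edgecolor="k", linewidth=0.3)
    for nid in (highlight or []):
        row = df[df["node_id"] == nid]
        if not row.empty:
            ax.annotate(str(nid), (row["stat_total"].iloc[0], row["stat_parent"].iloc[0]),
                        color="tab:red")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("test statistic (%total)")
    ax.set_ylabel("test statistic (%parent)")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    df.to_csv(out.with_suffix(".csv"), index=False)
    return out


def plot_qq_comparison(results: pd.DataFrame, out) -> Path:
    """Rank-paired -log10 p of %total (x) vs %parent (y), identity dashed.

    Each family is sorted independently; if the families have unequal sizes
    after missing-value removal, pairs are truncated to the shorter list.
    """
    out = Path(out)
    pt = np.sort(results["p_total"].dropna().to_numpy(dtype=float))
    pp = np.sort(results["p_parent"].dropna().to_numpy(dtype=float))
    if min(len(pt), len(pp)) < 2:
        raise ValueError("need at least two tested nodes in each family")
    if len(pt) != len(pp):
        log.info("qq plot: truncating to %d rank pairs", min(len(pt), len(pp)))
        n = min(len(pt), len(pp))
        pt, pp = pt[:n], pp[:n]
    x = -np.log10(np.maximum(pt, 1e-300))[::-1]
    y = -np.log10(np.maximum(pp, 1e-300))[::-1]
    lim = max(x.max(), y.max()) * 1.05

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, lim], [0, lim], ls="--", color="0.6", lw=1)
    ax.scatter(x, y, s=25, color="tab:blue", edgecolor="k", linewidth=0.3)
    ax.set_xlabel("ordered -log10 p (%total)")
    ax.set_ylabel("ordered -log10 p (%parent)")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    pd.DataFrame({"neglog10_p_total": x, "neglog10_p_parent": y}).to_csv(
        out.with_suffix(".csv"), index=False)
    return out
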