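"""Two-group significance testing of node proportions.

Every non-root node of the tree is tested twice — once on its %total row
and once on its %parent row — against the binary sample condition, and the
two families of p-values are FDR-adjusted separately: the two
quantifications answer two distinct statistical hypotheses, so pooling
their p-values into one adjustment would be incoherent.

Sign convention: statistics are oriented as (reference group) minus
(second group), where the reference group is the first condition level in
metadata order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata
from .proportions import ProportionMatrix


def ttest_two_sample(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Welch (default) or pooled two-sample t-test; two-sided.

    Returns ``(stat, p)`` with the statistic signed as mean(x) - mean(y).
    Degenerate inputs (fewer than 2 finite values per group) yield
    ``(nan, nan)``; identical constant groups yield ``(0, 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return np.nan, np.nan
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return (0.0, 1.0) if mx == my else (np.inf * np.sign(mx - my), 0.0)
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    t = (mx - my) / se
    return float(t), float(2 * stats.t.sf(abs(t), df))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Exact p-value when the combined sample size is <= 20 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  The statistic is the centred Mann-Whitney U of the first
    group, ``U1 - n1*n2/2``, positive when the first group tends larger.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 1 or len(y) < 1:
        return np.nan, np.nan
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    stat = float(res.statistic) - len(x) * len(y) / 2.0
    return stat, float(res.pvalue)


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched.

    Sort the m finite p-values, multiply by m/rank, enforce monotonicity by
    cumulative minima from the largest rank down, cap at 1, and restore the
    input order.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


_TESTS = {"ttest": ttest_two_sample, "wilcoxon": wilcoxon_rank_sum}


def test_all_nodes(
    props: ProportionMatrix,
    meta: SampleMetadata,
    method: str = "ttest",
    fdr: bool = True,
    logit: bool = False,
) -> pd.DataFrame:
    """Test every non-root node on both proportion scales.

    Missing values (zero-count parents) are dropped pairwise per node; a
    node with too few usable samples in either group gets NaN results for
    that quantification only.  FDR is applied within each quantification
    family across nodes.  ``logit=True`` tests log(p/(1-p)) of the
    proportions instead of the raw values (proportions clipped away from 0
    and 1 by 1e-6); the default tests raw proportions.
    """
    if method not in _TESTS:
        raise ValueError(f"method must be one of {sorted(_TESTS)}")
    ref, other = meta.require_two_levels()
    testfun = _TESTS[method]
    tree = props.tree

    samples = props.sample_ids
    cond = np.array([meta.condition_of(s) for s in samples], dtype=object)
    g1 = cond == ref
    g2 = cond == other

    node_order = list(props.pct_total.index)
    row_of = {nid: i for i, nid in enumerate(node_order)}
    mats = {"total": props.pct_total.to_numpy(dtype=float),
            "parent": props.pct_parent.to_numpy(dtype=float)}
    if logit:
        mats = {k: np.log(np.clip(v, 1e-6, 1 - 1e-6)
                          / (1 - np.clip(v, 1e-6, 1 - 1e-6)))
                for k, v in mats.items()}
    rows = []
    for nid in tree.depth_first():
        if nid == tree.root:
            continue
        clusters = tree.leaf_clusters(nid)
        rec: dict = {
            "node_id": nid,
            "n_leaves": len(clusters),
            "clusters": "|".join(sorted(map(str, clusters))),
            "method": method,
        }
        for kind in ("total", "parent"):
            vals = mats[kind][row_of[nid]]
            x, y = vals[g1], vals[g2]
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            rec[f"n_{kind}_used"] = len(x) + len(y)
            stat, p = testfun(x, y) if (len(x) and len(y)) else (np.nan, np.nan)
            rec[f"stat_{kind}"] = stat
            rec[f"p_{kind}"] = p
        rows.append(rec)
    res = pd.DataFrame(rows)
    if fdr and not res.empty:
        res["fdr_total"] = adjust_fdr(res["p_total"])
        res["fdr_parent"] = adjust_fdr(res["p_parent"])
    else:
        res["fdr_total"] = np.nan
        res["fdr_parent"] = np.nan
    return res
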