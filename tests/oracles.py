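"""Independent, from-definition reference implementations used only in tests.

These are deliberately naive (enumeration, O(n^3) loops, direct formula
transcription) and share no code with the package paths they validate.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

# ---------------------------------------------------------------------------
# agglomerative clustering: naive Lance-Williams


_LW_COEFS = {
    # alpha_i, alpha_j, beta, gamma as functions of cluster sizes
    "single": lambda ni, nj, nk: (0.5, 0.5, 0.0, -0.5),
    "complete": lambda ni, nj, nk: (0.5, 0.5, 0.0, 0.5),
    "average": lambda ni, nj, nk: (ni / (ni + nj), nj / (ni + nj), 0.0, 0.0),
    "mcquitty": lambda ni, nj, nk: (0.5, 0.5, 0.0, 0.0),
}


def lance_williams_merges(X: np.ndarray, method: str):
    """Brute-force agglomerative clustering on Euclidean distances.

    Returns a list of merges ``(leafset_i, leafset_j, height)`` in merge
    order.  Ward follows the classical recurrence on squared distances with
    a final square root (the convention of the standard implementations).
    """
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    if method == "ward":
        D = D**2
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        h = np.sqrt(dij) if method == "ward" else dij
        merges.append((clusters[i], clusters[j], h))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            if method == "ward":
                nk = sizes[k]
                tot = ni + nj + nk
                dnew = ((ni + nk) / tot * dik + (nj + nk) / tot * djk
                        - nk / tot * dij)
            else:
                ai, aj, beta, gamma = _LW_COEFS[method](ni, nj, sizes[k])
                dnew = ai * dik + aj * djk + beta * dij + gamma * abs(dik - djk)
            dist[tuple(sorted((new, k)))] = dnew
        for k in list(dist):
            if i in k or j in k:
                del dist[k]
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = ni + nj
        del clusters[i], clusters[j], sizes[i], sizes[j]
    return merges


# ---------------------------------------------------------------------------
# statistics


def bh_adjust_reference(p: np.ndarray) -> np.ndarray:
    """BH step-up transcribed directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def wilcoxon_exact_reference(x, y) -> tuple[float, float]:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Works with ties (it enumerates assignments of the observed pooled
    values, i.e. the permutation distribution with midranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    # midranks
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    count_ge = count_le = 0
    total = comb(n, n1)
    for subset in itertools.combinations(range(n), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
        if u >= u_obs - 1e-9:
            count_ge += 1
        if u <= u_obs + 1e-9:
            count_le += 1
    p = 2 * min(count_ge, count_le) / total
    return u_obs - mu, min(p, 1.0)


def welch_t_reference(x, y) -> tuple[float, float]:
    """Welch t-test through scipy's implementation (independent code path)."""
    from scipy import stats

    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# MSS from definition (uses exhaustive PAM and sklearn silhouettes)


def mss_reference(dist: np.ndarray, partition: np.ndarray, max_sub_k: int) -> float:
    """Median split silhouette computed with independent building blocks.

    Sub-splits come from exhaustive medoid search (not the package's PAM)
    and silhouettes from scikit-learn; small instances only.
    """
    from sklearn.metrics import silhouette_samples, silhouette_score

    from treekor.hierarchy import pam_brute_force

    partition = np.asarray(partition)
    groups = list(dict.fromkeys(partition.tolist()))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    scores = []
    for g in groups:
        idx = np.flatnonzero(partition == g)
        if len(idx) <= 2:
            scores.append(0.0)
            continue
        sub = dist[np.ix_(idx, idx)]
        best_avg, best_sil = -np.inf, None
        for k in range(2, min(max_sub_k, len(idx) - 1) + 1):
            lab, _, _ = pam_brute_force(sub, k)
            avg = silhouette_score(sub, lab, metric="precomputed")
            if avg > best_avg + 1e-15:
                best_avg = avg
                best_sil = silhouette_samples(sub, lab, metric="precomputed")
        scores.append(float(np.median(best_sil)))
    return float(np.median(scores))
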