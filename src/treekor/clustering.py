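"""Self-organizing-map over-clustering of events.

Cells are deliberately over-clustered on a rectangular SOM grid (default
10x10, i.e. 100 units) so that rare populations are not merged away;
superfluous units are aggregated later by the hierarchy stage.  Precomputed
cell-type labels (manual gating, prior clustering) can be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._random import rng_for
from .io import EventTable


@dataclass
class SOMGrid:
    """Trained SOM codebook on a rectangular grid."""

    codebook: np.ndarray  # (grid_rows*grid_cols, n_markers)
    grid_rows: int
    grid_cols: int
    epochs: int
    seed: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("codebook contains non-finite values")


@dataclass
class ClusterAssignment:
    """Per-event cluster labels with the distinct ids in a fixed order."""

    labels: np.ndarray
    cluster_ids: list
    source: str  # "som" | "precomputed"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        known = set(self.cluster_ids)
        if not set(self.labels) <= known:
            raise ValueError("labels contain ids missing from cluster_ids")
        counts = {c: 0 for c in self.cluster_ids}
        for lab in self.labels:
            counts[lab] += 1
        if any(v == 0 for v in counts.values()):
            empty = [c for c, v in counts.items() if v == 0]
            raise ValueError(f"clusters with zero events: {empty}")

    @property
    def n_events(self) -> int:
        return len(self.labels)


@njit(cache=True)
def _som_train_loop(data, codebook, unit_rows, unit_cols, order,
                    lr_start, lr_end, radius_start, radius_end):  # pragma: no cover
    n_steps = order.shape[0]
    m, d = codebook.shape
    for step in range(n_steps):
        frac = step / max(n_steps - 1, 1)
        lr = lr_start + (lr_end - lr_start) * frac
        radius = radius_start + (radius_end - radius_start) * frac
        x = data[order[step]]
        # best matching unit by Euclidean distance, lowest index on ties
        best = 0
        best_d = np.inf
        for u in range(m):
            s = 0.0
            for j in range(d):
                diff = x[j] - codebook[u, j]
                s += diff * diff
            if s < best_d:
                best_d = s
                best = u
        br, bc = unit_rows[best], unit_cols[best]
        # Gaussian kernel of width `radius`, truncated at 3 radii: broad
        # early (grid ordering, no dead units), near-local late (prototypes
        # converge to local structure instead of a blurred mean)
        denom = 2.0 * radius * radius
        cut = 9.0 * radius * radius
        for u in range(m):
            dr = unit_rows[u] - br
            dc = unit_cols[u] - bc
            g2 = dr * dr + dc * dc
            if g2 <= cut:
                h = lr * np.exp(-g2 / denom)
                for j in range(d):
                    codebook[u, j] += h * (x[j] - codebook[u, j])
    return codebook


def train_som(
    events: EventTable,
    grid_rows: int = 10,
    grid_cols: int = 10,
    epochs: int = 10,
    seed: int = 0,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
    radius_end: float = 0.3,
) -> SOMGrid:
    """Train a rectangular-grid SOM on transformed events.

    Online updates with a Gaussian neighborhood whose width decays linearly
    from ``max(grid dims)/2`` to ``radius_end`` alongside a linearly
    decaying learning rate; the codebook is initialized from randomly drawn
    events.  The end width defaults below one grid step so prototypes
    decouple in the final training phase.  Deterministic for a fixed seed.
    """
    if not events.transformed:
        raise ValueError("events must be arcsinh-transformed before SOM training "
                         "(call preprocess.arcsinh_transform first)")
    m = grid_rows * grid_cols
    if m < 2:
        raise ValueError("SOM grid needs at least 2 units")
    n = events.n_events
    if n < m:
        raise ValueError(f"need at least {m} events to train a {grid_rows}x{grid_cols} grid")
    rng = rng_for(seed, "som")
    data = np.ascontiguousarray(events.values, dtype=np.float64)
    init_idx = rng.choice(n, size=m, replace=False)
    codebook = data[init_idx].copy()
    order = np.concatenate([rng.permutation(n) for _ in range(epochs)]).astype(np.int64)
    rows, cols = np.divmod(np.arange(m), grid_cols)
    codebook = _som_train_loop(
        data, codebook,
        rows.astype(np.float64), cols.astype(np.float64),
        order,
        float(lr_start), float(lr_end),
        float(max(grid_rows, grid_cols)) / 2.0, float(radius_end),
    )
    return SOMGrid(codebook=codebook, grid_rows=grid_rows, grid_cols=grid_cols,
                   epochs=epochs, seed=seed)


def assign_clusters(events: EventTable, som: SOMGrid) -> ClusterAssignment:
    """Label each event with its nearest codebook unit (lowest index on ties).

    Units with zero assigned events are dropped and the remaining cluster
    ids renumbered contiguously from 0.
    """
    if events.n_markers != som.codebook.shape[1]:
        raise ValueError(
            f"marker count {events.n_markers} does not match codebook "
            f"dimension {som.codebook.shape[1]}"
        )
    x = events.values
    # squared distances; argmin returns the lowest index on ties
    d2 = (
        np.sum(x * x, axis=1)[:, None]
        - 2.0 * x @ som.codebook.T
        + np.sum(som.codebook * som.codebook, axis=1)[None, :]
    )
    units = np.argmin(d2, axis=1)
    occupied = np.unique(units)
    remap = {int(u): i for i, u in enumerate(occupied)}
    labels = np.array([remap[int(u)] for u in units], dtype=object)
    return ClusterAssignment(labels=labels, cluster_ids=list(range(len(occupied))),
                             source="som")


def use_precomputed_labels(events: EventTable, labels) -> ClusterAssignment:
    """Wrap user-supplied per-event labels (e.g. manually gated cell types)."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != events.n_events:
        raise ValueError(
            f"got {len(labels)} labels for {events.n_events} events"
        )
    if any(str(lab) == "" for lab in labels):
        raise ValueError("labels must be non-empty")
    cluster_ids = list(dict.fromkeys(labels))
    return ClusterAssignment(labels=labels, cluster_ids=cluster_ids, source="precomputed")
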