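"""Normalization of raw cytometry intensities.

Raw mass/flow cytometry intensities are heavy-tailed and span several
decades; the field's standard variance-stabilizing transform is
``asinh(x / cofactor)`` with cofactor 5 for CyTOF.  Optional random
subsampling thins very large datasets before clustering.
"""

from __future__ import annotations

import numpy as np

from ._random import rng_for
from .io import EventTable


class DoubleTransformError(ValueError):
    """The event table was already arcsinh-transformed."""


def arcsinh_transform(events: EventTable, cofactor: float = 5.0) -> EventTable:
    """Apply ``asinh(x / cofactor)`` elementwise; marks the table transformed.

    The transform is strictly monotone, odd, ~linear near zero and
    logarithmic in the tails, so cluster geometry on the transformed scale
    is comparable across markers.
    """
    if events.transformed:
        raise DoubleTransformError("events are already arcsinh-transformed")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return EventTable(
        values=np.arcsinh(events.values / cofactor),
        marker_names=list(events.marker_names),
        sample_ids=events.sample_ids.copy(),
        transformed=True,
    )


def _n_keep(n: int, fraction: float) -> int:
    # round-half-to-even keeps expected counts unbiased across strata
    k = int(np.round(fraction * n))
    return min(max(k, 0), n)


def subsample_events(
    events: EventTable,
    fraction: float,
    seed: int = 0,
    stratify_by_sample: bool = True,
) -> EventTable:
    """Randomly retain ``round(fraction * n)`` events without replacement.

    With ``stratify_by_sample`` (default) each sample keeps its own share,
    so per-sample compositions are perturbed only by within-sample sampling
    noise.  Original event order is preserved; ``fraction=1`` is the
    identity.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return events
    rng = rng_for(seed, "subsample")
    n = events.n_events
    if stratify_by_sample:
        keep = np.zeros(n, dtype=bool)
        for sid in events.unique_samples():
            idx = np.flatnonzero(events.sample_ids == sid)
            k = _n_keep(len(idx), fraction)
            keep[rng.choice(idx, size=k, replace=False)] = True
        sel = np.flatnonzero(keep)
    else:
        k = _n_keep(n, fraction)
        sel = np.sort(rng.choice(n, size=k, replace=False))
    return EventTable(
        values=events.values[sel],
        marker_names=list(events.marker_names),
        sample_ids=events.sample_ids[sel],
        transformed=events.transformed,
    )
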