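"""Deterministic per-stage seed derivation.

A single top-level seed deterministically fans out into independent
sub-seeds for each pipeline stage (subsampling, SOM training, PAM,
cross-validation, synthesis), so a full run is bit-reproducible while
stages stay statistically independent.
"""

from __future__ import annotations

import numpy as np

# fixed stage indices; append only, never renumber
_STAGES = {
    "subsample": 0,
    "som": 1,
    "pam": 2,
    "cv": 3,
    "synthetic": 4,
}


def derive_seed(seed: int, stage: str | int) -> int:
    """Derive a stage-specific 31-bit seed from a top-level seed.

    Parameters
    ----------
    seed
        Top-level run seed.
    stage
        Stage name from the known stage table, or a raw integer key.
    """
    key = _STAGES[stage] if isinstance(stage, str) else int(stage)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, stage: str | int) -> np.random.Generator:
    """A numpy Generator seeded for the given stage."""
    return np.random.default_rng(derive_seed(seed, stage))
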