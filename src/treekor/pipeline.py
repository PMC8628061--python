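"""End-to-end orchestration of the five analysis stages.

transform -> (subsample) -> cluster -> tree -> proportions -> tests.
Each stage is importable on its own; this module only wires them together
with one top-level seed and one :class:`~treekor.config.AnalysisConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clustering import ClusterAssignment, assign_clusters, train_som, use_precomputed_labels
from .config import AnalysisConfig
from .hierarchy import ClusterProfile, PhenoTree, build_tree, cluster_profiles
from .io import EventTable, SampleMetadata
from .preprocess import arcsinh_transform, subsample_events
from .proportions import ProportionMatrix, compute_proportions
from .testing import test_all_nodes


@dataclass
class PipelineResult:
    events: EventTable            # transformed (and possibly subsampled) events
    assignment: ClusterAssignment
    profile: ClusterProfile
    tree: PhenoTree
    proportions: ProportionMatrix
    results: pd.DataFrame


def run_pipeline(
    events: EventTable,
    meta: SampleMetadata,
    config: AnalysisConfig | None = None,
    precomputed_labels=None,
    tree: PhenoTree | None = None,
) -> PipelineResult:
    """Run the full analysis on raw-scale events.

    ``precomputed_labels`` bypasses SOM clustering (e.g. manually gated
    cell types); a ``tree`` bypasses hierarchy construction (e.g. a known
    ground-truth tree).  Missing sample ids in the metadata are an error.
    """
    config = config or AnalysisConfig()
    unknown = set(events.unique_samples()) - set(meta.sample_ids)
    if unknown:
        raise ValueError(f"events reference samples absent from metadata: {sorted(unknown)}")

    data = events if events.transformed else arcsinh_transform(events, config.cofactor)
    if config.subsample_fraction < 1:
        if precomputed_labels is not None:
            raise ValueError("subsampling with precomputed labels is ambiguous; "
                             "subsample before labelling instead")
        data = subsample_events(data, config.subsample_fraction, seed=config.seed)

    if precomputed_labels is not None:
        assignment = use_precomputed_labels(data, precomputed_labels)
    else:
        som = train_som(
            data, grid_rows=config.grid_rows, grid_cols=config.grid_cols,
            epochs=config.som_epochs, seed=config.seed)
        assignment = assign_clusters(data, som)

    profile = cluster_profiles(data, assignment)
    if tree is None:
        tree = build_tree(profile, config.hierarchy_method,
                          K=config.max_children_K, seed=config.seed)
    props = compute_proportions(assignment, tree, data,
                                parent_depth=config.parent_depth)
    results = test_all_nodes(props, meta, method=config.test_method,
                             fdr=config.fdr, logit=config.logit)
    return PipelineResult(
        events=data, assignment=assignment, profile=profile,
        tree=tree, proportions=props, results=results)
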