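"""Run configuration for the full pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass

HIERARCHY_METHODS = ("hopach", "average", "ward", "single", "complete", "mcquitty")
TEST_METHODS = ("ttest", "wilcoxon")


@dataclass
class AnalysisConfig:
    """All tunables of a pipeline run.

    Defaults follow common CyTOF practice: arcsinh cofactor 5, a 10x10
    SOM grid (over-clustering into 100 units), HOPACH-style trees with at
    most 5 children per node, Welch t-tests with BH-FDR adjustment.
    """

    cofactor: float = 5.0
    grid_rows: int = 10
    grid_cols: int = 10
    hierarchy_method: str = "hopach"
    max_children_K: int = 5
    test_method: str = "ttest"
    fdr: bool = True
    seed: int = 0
    subsample_fraction: float = 1.0
    som_epochs: int = 10
    parent_depth: int = 1
    logit: bool = False

    def __post_init__(self):
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.hierarchy_method not in HIERARCHY_METHODS:
            raise ValueError(f"hierarchy_method must be one of {HIERARCHY_METHODS}")
        if self.max_children_K < 2:
            raise ValueError("max_children_K must be >= 2")
        if self.test_method not in TEST_METHODS:
            raise ValueError(f"test_method must be one of {TEST_METHODS}")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.som_epochs < 1:
            raise ValueError("som_epochs must be positive")
        if self.parent_depth < 1:
            raise ValueError("parent_depth must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
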