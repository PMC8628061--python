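"""Event-table and sample-metadata containers plus file I/O.

An :class:`EventTable` is the package's in-memory representation of pooled
cytometry data: one row per cell, one column per marker, plus a per-cell
sample identifier and a flag recording whether intensities are still on the
raw scale or already arcsinh-transformed.  :class:`SampleMetadata` maps each
sample to its binary condition (e.g. case/control).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import read_fcs


class PanelMismatchError(ValueError):
    """Input files do not share an identical marker panel."""


@dataclass
class EventTable:
    """Pooled cells x markers expression matrix.

    Attributes
    ----------
    values
        ``(n_events, n_markers)`` float matrix.
    marker_names
        Unique, non-empty marker names, one per column.
    sample_ids
        Per-event sample identifier (length ``n_events``).
    transformed
        True once the arcsinh transform has been applied.
    """

    values: np.ndarray
    marker_names: list[str]
    sample_ids: np.ndarray
    transformed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (events x markers)")
        if self.values.shape[0] < 1:
            raise ValueError("an EventTable needs at least one event")
        if self.values.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length must match value columns")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("one sample_id per event required")
        if len(set(self.marker_names)) != len(self.marker_names):
            dupes = sorted({m for m in self.marker_names if self.marker_names.count(m) > 1})
            raise PanelMismatchError(f"duplicate marker names: {dupes}")
        if any(not str(m) for m in self.marker_names):
            raise ValueError("marker names must be non-empty")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def unique_samples(self) -> list[str]:
        """Sample ids in first-appearance order."""
        seen: dict = {}
        for s in self.sample_ids:
            seen.setdefault(s, None)
        return list(seen)


@dataclass
class SampleMetadata:
    """Sample id -> binary condition mapping.

    ``condition_levels`` are recorded in first-seen file order; the first
    level is the reference group, fixing the sign convention of all test
    statistics downstream.
    """

    table: pd.DataFrame  # columns: sample_id, condition
    condition_levels: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id entries: {dupes}")
        if not self.condition_levels:
            self.condition_levels = list(dict.fromkeys(self.table["condition"]))
        if len(self.condition_levels) > 2:
            self.warnings.append(
                f"{len(self.condition_levels)} condition levels present; "
                "two-group testing will refuse to run"
            )

    @property
    def sample_ids(self) -> list:
        return self.table["sample_id"].tolist()

    def condition_of(self, sample_id) -> object:
        row = self.table.loc[self.table["sample_id"] == sample_id, "condition"]
        if row.empty:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        return row.iloc[0]

    def require_two_levels(self) -> tuple:
        if len(self.condition_levels) != 2:
            raise ValueError(
                "exactly two condition levels are required for testing; "
                f"found {self.condition_levels}"
            )
        return tuple(self.condition_levels)


def load_events(paths, format: str = "csv", sample_column: str = "sample_id") -> EventTable:
    """Load and pool per-sample event files into one :class:`EventTable`.

    All files must share an identical marker panel (same names, any order);
    columns are aligned by name to the panel of the first file.  For FCS
    files the sample id is the filename stem; for CSV it is taken from
    ``sample_column`` (one file may hold many samples).
    """
    paths = [Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    if not paths:
        raise ValueError("no input files given")
    blocks: list[np.ndarray] = []
    sample_ids: list[np.ndarray] = []
    panel: list[str] | None = None
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        if format == "fcs":
            vals, names = read_fcs(p)
            sids = np.repeat(p.stem, vals.shape[0])
        elif format == "csv":
            df = pd.read_csv(p)
            if df.empty:
                raise ValueError(f"empty event file: {p}")
            if sample_column not in df.columns:
                raise ValueError(f"{p}: missing sample column {sample_column!r}")
            names = [c for c in df.columns if c != sample_column]
            vals = df[names].to_numpy(dtype=float)
            sids = df[sample_column].to_numpy(dtype=object)
        else:
            raise ValueError(f"unknown format {format!r}")
        if vals.shape[0] == 0:
            raise ValueError(f"empty event file: {p}")
        if len(set(names)) != len(names):
            dupes = sorted({m for m in names if names.count(m) > 1})
            raise PanelMismatchError(f"{p}: duplicate marker names {dupes}")
        if panel is None:
            panel = list(names)
        elif set(names) != set(panel):
            missing = sorted(set(panel) - set(names))
            extra = sorted(set(names) - set(panel))
            raise PanelMismatchError(
                f"{p}: marker panel mismatch (missing {missing}, unexpected {extra})"
            )
        else:
            order = [names.index(m) for m in panel]
            vals = vals[:, order]
        blocks.append(vals)
        sample_ids.append(sids)
    return EventTable(
        values=np.vstack(blocks),
        marker_names=list(panel),
        sample_ids=np.concatenate(sample_ids),
        transformed=False,
    )


def load_metadata(path) -> SampleMetadata:
    """Read a sample metadata CSV with ``sample_id`` and ``condition`` columns."""
    df = pd.read_csv(path)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    return SampleMetadata(table=df[["sample_id", "condition"]].copy())


def write_results(results: pd.DataFrame, tree, out_dir, config: dict | None = None) -> dict:
    """Write the per-node test table, the tree (newick) and the resolved config.

    Returns the mapping of artifact name to written path.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    tree_ids = set(tree.nodes)
    if not results.empty:
        unknown = sorted(set(results["node_id"]) - tree_ids)
        if unknown:
            raise ValueError(f"result node ids absent from tree: {unknown}")
    paths = {
        "results": out_dir / "results.csv",
        "tree": out_dir / "tree.nwk",
        "config": out_dir / "config.json",
    }
    cols = [
        "node_id", "n_leaves", "clusters",
        "stat_total", "p_total", "fdr_total",
        "stat_parent", "p_parent", "fdr_parent",
    ]
    out = results.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    out[cols].to_csv(paths["results"], index=False)
    paths["tree"].write_text(tree.to_newick() + "\n")
    with open(paths["config"], "w") as fh:
        json.dump(config or {}, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths
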