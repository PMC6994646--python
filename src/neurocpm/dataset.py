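"""In-memory analysis dataset: phenotype table + edge matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MEASURE_COLUMNS
from .connectome import count_unique_edges


@dataclass
class CPMDataset:
    """Aligned phenotype rows and connectivity edge rows for one cohort.

    ``phenotype`` uses canonical lower-case column names (participant_id,
    site, group, motion_mm, brief_*_t, ...); row k of ``edges`` is the
    flat upper-triangle edge vector of the participant in phenotype row k.
    """

    phenotype: pd.DataFrame
    edges: np.ndarray
    node_count: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.phenotype) != self.edges.shape[0]:
            raise ValueError("phenotype rows and edge rows are misaligned")
        if self.edges.shape[1] != count_unique_edges(self.node_count):
            raise ValueError("edge matrix width does not match node_count")

    @property
    def n(self) -> int:
        return len(self.phenotype)

    @property
    def participant_ids(self) -> list[str]:
        return [str(v) for v in self.phenotype["participant_id"]]

    def behavior(self, behavior_name: str) -> np.ndarray:
        """Behavior scores; accepts a measure key (e.g. 'shift') or a column name."""
        col = MEASURE_COLUMNS.get(behavior_name, behavior_name)
        if col not in self.phenotype.columns:
            raise KeyError(f"phenotype has no column for behavior {behavior_name!r}")
        return self.phenotype[col].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.phenotype[name].to_numpy()

    def subset(self, index: np.ndarray) -> "CPMDataset":
        """Row subset (boolean or integer index), preserving alignment."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CPMDataset(
            phenotype=self.phenotype.iloc[index].reset_index(drop=True),
            edges=self.edges[index],
            node_count=self.node_count,
        )
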