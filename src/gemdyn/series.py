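"""Blocked per-trial data container shared by the simulator and the readers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import TaskConfig

#: canonical column order of the tabular representation
COLUMNS = ["condition", "block", "trial", "x", "v", "e"]


@dataclass
class TrialSeries:
    """Ordered per-trial release states and goal errors, in 50-trial blocks.

    ``data`` is a DataFrame with columns ``condition, block, trial, x, v, e``
    (all dimensionless), sorted by (block, trial); ``trial`` indexes within a
    block starting at 1.  ``provenance`` records whether the series came from a
    simulation spec or a file.
    """

    data: pd.DataFrame
    cfg: TaskConfig
    condition: str = "C0"
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in ("block", "trial", "x", "v", "e") if c not in self.data.columns]
        if missing:
            raise ValueError(f"TrialSeries missing columns: {missing}")
        if "condition" not in self.data.columns:
            self.data = self.data.assign(condition=self.condition)
        self.data = self.data[COLUMNS].reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return len(self.data)

    @property
    def blocks(self) -> list[int]:
        return sorted(self.data["block"].unique().tolist())

    def block_lengths(self) -> dict[int, int]:
        return self.data.groupby("block").size().to_dict()

    def states(self) -> np.ndarray:
        """(n, 2) array of release states in (x, v) order."""
        return self.data[["x", "v"]].to_numpy(dtype=float)

    def errors(self) -> np.ndarray:
        return self.data["e"].to_numpy(dtype=float)

    def block_index(self) -> np.ndarray:
        return self.data["block"].to_numpy()
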