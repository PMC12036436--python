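"""Core in-memory containers.

A :class:`CellTable` holds the configuration-space coordinates of every
observed cell: an expression vector ``x``, a velocity vector ``x_dot``
(the estimated instantaneous rate of change of expression, supplied as
input), a discrete time step and a categorical cell type.  Cells are
grouped into time *layers*; all downstream stages index cells by their
row in this table.

A :class:`TrajectoryEnsemble` is a set of equal-length state sequences.
Before tokenization the integer entries are row indices into a
``CellTable``; after tokenization they are vocabulary token ids.  The
optional ``cell_ids`` field preserves the originating cell id strings
across both representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError

__all__ = ["CellTable", "TrajectoryEnsemble"]

_META_COLUMNS = ("cell_id", "time", "cell_type")


@dataclass
class CellTable:
    """Cells-by-genes expression and velocity with per-cell metadata.

    Parameters
    ----------
    expression, velocity
        Dense ``(n_cells, n_genes)`` arrays of identical shape.
    obs
        One row per cell with columns ``cell_id`` (unique strings),
        ``time`` (contiguous 0-based integers) and ``cell_type``.
    time_mapping
        Original time label -> 0-based step, recorded when input labels
        were rank-mapped.
    """

    expression: np.ndarray
    velocity: np.ndarray
    obs: pd.DataFrame
    time_mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.expression.shape != self.velocity.shape:
            raise ValidationError(
                f"expression shape {self.expression.shape} != velocity shape "
                f"{self.velocity.shape}"
            )
        missing = [c for c in _META_COLUMNS if c not in self.obs.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if len(self.obs) != self.expression.shape[0]:
            raise ValidationError(
                f"{len(self.obs)} metadata rows for "
                f"{self.expression.shape[0]} expression rows"
            )
        times = np.asarray(self.obs["time"])
        uniq = np.unique(times)
        expected = np.arange(uniq.size)
        if not np.array_equal(uniq, expected):
            gaps = sorted(set(expected) - set(uniq.tolist()))
            raise ValidationError(
                f"time steps must form a contiguous 0-based range; "
                f"got {uniq.tolist()} (missing {gaps})"
            )
        self.obs = self.obs.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_layers(self) -> int:
        return int(np.asarray(self.obs["time"]).max()) + 1

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.obs["time"], dtype=int)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.obs["cell_id"], dtype=object)

    @property
    def cell_types(self) -> np.ndarray:
        return np.asarray(self.obs["cell_type"], dtype=object)

    def layer_indices(self, t: int) -> np.ndarray:
        """Row indices of the cells at time step ``t``, ascending."""
        return np.flatnonzero(self.times == t)

    @property
    def layer_sizes(self) -> np.ndarray:
        """``N_t`` for every layer."""
        return np.bincount(self.times, minlength=self.n_layers)


@dataclass
class TrajectoryEnsemble:
    """Equal-length integer state sequences (cell rows or token ids)."""

    tokens: np.ndarray
    cell_ids: list | None = None

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=int)
        if self.tokens.ndim != 2:
            raise ValidationError(
                "trajectories must form a 2-D (n_trajectories, length) array; "
                "ragged sequence lengths are not allowed"
            )
        if self.cell_ids is not None:
            if len(self.cell_ids) != self.tokens.shape[0]:
                raise ValidationError("cell_ids count != trajectory count")
            for ids in self.cell_ids:
                if len(ids) != self.tokens.shape[1]:
                    raise ValidationError("ragged cell_id sequence")

    @property
    def n_trajectories(self) -> int:
        return self.tokens.shape[0]

    @property
    def length(self) -> int:
        return self.tokens.shape[1]

    def __len__(self) -> int:
        return self.n_trajectories

    def __iter__(self):
        return iter(self.tokens)
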