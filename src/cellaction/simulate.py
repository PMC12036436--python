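"""Synthetic branching developmental processes with known ground truth.

The generator emulates the layered structure of time-stamped scRNA
datasets: ``T + 1`` time layers of cells, a lineage tree whose latent
mean-expression paths follow a seeded Gaussian random walk (step scale
``drift_scale``), designed branch points with fixed branch
probabilities, and an optional bottleneck layer where most lineages
collapse onto a single latent state before re-diversifying.

Each cell is a noisy observation of its lineage's latent mean at its
layer; its velocity points from the current latent mean toward the
lineage's next-layer mean (plus noise), so velocity is informative about
the true developmental direction.  The ``cell_type`` column carries the
lineage label active at the cell's layer.

Ground truth (per-cell lineage, a true parent in the previous layer, the
designed branch probabilities and the bottleneck location) is returned
alongside the table for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from ._rng import substream
from .datatypes import CellTable

__all__ = ["LineageSpec", "SyntheticTruth", "simulate_branching_process"]


@dataclass(frozen=True)
class LineageSpec:
    """Design of a branching process.

    ``branch_points`` is a list of ``(layer, n_branches, probabilities)``
    tuples; each splits every lineage active at that layer.  The
    optional ``bottleneck`` is ``(layer, surviving_fraction)``: the
    fraction of lineages that keep a distinct latent state at that
    layer; the rest pass through the first survivor's state exactly.
    """

    n_layers: int
    cells_per_layer: int
    n_genes: int
    branch_points: tuple = ()
    bottleneck: tuple | None = None
    noise_sd: float = 0.05
    drift_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValidationError("need at least 2 layers")
        if self.cells_per_layer < 1 or self.n_genes < 1:
            raise ValidationError("cells_per_layer and n_genes must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        T = self.n_layers - 1
        for layer, n_branches, probs in self.branch_points:
            if layer >= T:
                raise ValidationError(
                    f"branch point at layer {layer} >= final step {T}"
                )
            if layer < 1:
                raise ValidationError("branch points must lie at layer >= 1")
            if n_branches < 2 or len(probs) != n_branches:
                raise ValidationError(
                    "each branch point needs n_branches >= 2 matching probabilities"
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(
                    f"branch probabilities at layer {layer} sum to {sum(probs)}"
                )
        if self.bottleneck is not None:
            layer, frac = self.bottleneck
            if not (0 < frac <= 1):
                raise ValidationError("surviving_fraction must be in (0, 1]")
            if not (0 < layer <= T):
                raise ValidationError("bottleneck layer out of range")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated process."""

    lineage: np.ndarray            # per-cell lineage label at its own layer
    leaf_lineage: np.ndarray       # per-cell full root-to-leaf label
    parent: np.ndarray             # per-cell row index of true parent (-1 at layer 0)
    branch_probabilities: dict     # layer -> designed probabilities
    bottleneck: tuple | None
    latent_means: dict = field(default_factory=dict)  # (label, layer) -> mean


def _label(choices: tuple[int, ...]) -> str:
    return "L" + "".join(str(c) for c in choices)


def simulate_branching_process(spec: LineageSpec, seed: int):
    """Simulate a branching process; returns ``(CellTable, SyntheticTruth)``."""
    rng = substream(seed, "simulate")
    T = spec.n_layers - 1
    branch_at = {layer: (nb, tuple(p)) for layer, nb, p in spec.branch_points}

    # --- latent mean random walk over the lineage tree ---------------------
    # leaves(t): active branch-choice prefixes at layer t
    prefixes: list[tuple[int, ...]] = [()]
    means: dict[tuple[tuple[int, ...], int], np.ndarray] = {}
    start = rng.normal(0.0, spec.drift_scale, spec.n_genes)
    means[((), 0)] = start
    active_by_layer: list[list[tuple[int, ...]]] = [list(prefixes)]
    for t in range(1, spec.n_layers):
        if t in branch_at:
            nb, _ = branch_at[t]
            new = []
            for p in prefixes:
                # children start from the parent's previous-layer mean and
                # diverge immediately, so branch identity is reflected in
                # expression from the branch layer on (labels and states stay
                # consistent, which makes lineage recovery well-posed)
                for b in range(nb):
                    child = p + (b,)
                    means[(child, t)] = means[(p, t - 1)] + rng.normal(
                        0.0, spec.drift_scale, spec.n_genes
                    )
                    new.append(child)
            prefixes = new
        else:
            for p in prefixes:
                means[(p, t)] = means[(p, t - 1)] + rng.normal(
                    0.0, spec.drift_scale, spec.n_genes
                )
        if spec.bottleneck is not None and t == spec.bottleneck[0]:
            frac = spec.bottleneck[1]
            n_surv = max(1, math.ceil(frac * len(prefixes)))
            survivor = means[(prefixes[0], t)]
            for p in prefixes[n_surv:]:
                means[(p, t)] = survivor.copy()
        active_by_layer.append(list(prefixes))

    # continue each lineage one virtual step past T so last-layer velocity
    # has a defined direction
    for p in prefixes:
        means[(p, T + 1)] = means[(p, T)] + rng.normal(
            0.0, spec.drift_scale, spec.n_genes
        )

    leaves = prefixes
    leaf_probs = np.array(
        [
            np.prod([branch_at[l][1][leaf[i]]
                     for i, l in enumerate(sorted(branch_at))])
            if branch_at else 1.0
            for leaf in leaves
        ]
    )
    leaf_probs = leaf_probs / leaf_probs.sum()

    def prefix_at(leaf: tuple[int, ...], t: int) -> tuple[int, ...]:
        n_choices = sum(1 for l in sorted(branch_at) if l <= t)
        return leaf[:n_choices]

    # --- sample cells layer by layer ---------------------------------------
    n_total = spec.n_layers * spec.cells_per_layer
    expr = np.empty((n_total, spec.n_genes))
    vel = np.empty((n_total, spec.n_genes))
    times = np.empty(n_total, dtype=int)
    lineage = np.empty(n_total, dtype=object)
    leaf_lab = np.empty(n_total, dtype=object)
    parent = np.full(n_total, -1, dtype=int)
    cell_leaf: list[tuple[int, ...]] = []

    row = 0
    prev_rows_by_prefix: dict[tuple[int, ...], list[int]] = {}
    for t in range(spec.n_layers):
        leaf_idx = rng.choice(len(leaves), size=spec.cells_per_layer, p=leaf_probs)
        rows_by_prefix: dict[tuple[int, ...], list[int]] = {}
        for li in leaf_idx:
            leaf = leaves[li]
            p_now = prefix_at(leaf, t)
            mean_now = means[(p_now, t)]
            p_next = prefix_at(leaf, t + 1) if t < T else leaf
            mean_next = means[(p_next, t + 1)]
            expr[row] = mean_now + rng.normal(0.0, spec.noise_sd, spec.n_genes)
            vel[row] = (mean_next - mean_now) + rng.normal(
                0.0, spec.noise_sd, spec.n_genes
            )
            times[row] = t
            lineage[row] = _label(p_now)
            leaf_lab[row] = _label(leaf)
            cell_leaf.append(leaf)
            if t > 0:
                p_prev = prefix_at(leaf, t - 1)
                cands = prev_rows_by_prefix.get(p_prev)
                if not cands:  # branch unsampled at t-1: fall back to the layer
                    cands = [r for rs in prev_rows_by_prefix.values() for r in rs]
                parent[row] = int(rng.choice(cands))
            rows_by_prefix.setdefault(p_now, []).append(row)
            row += 1
        prev_rows_by_prefix = rows_by_prefix

    obs = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n_total)],
            "time": times,
            "cell_type": lineage,
        }
    )
    table = CellTable(expr, vel, obs)
    truth = SyntheticTruth(
        lineage=lineage,
        leaf_lineage=leaf_lab,
        parent=parent,
        branch_probabilities={l: branch_at[l][1] for l in branch_at},
        bottleneck=spec.bottleneck,
        latent_means={(_label(p), t): m for (p, t), m in means.items()},
    )
    return table, truth
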