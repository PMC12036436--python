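"""Entropy production: time-reversal asymmetry of trajectories.

A stochastic process in detailed balance assigns equal probability to
every trajectory and its time reversal; development does not.  The
entropy production of a trajectory under a model p_theta,

    sigma(gamma) = k_B [log p_theta(gamma) - log p_theta(gamma~)],

quantifies the violation (k_B = 1 here, so sigma is in nats).  Its
ensemble expectation equals k_B times the KL divergence between the
forward and time-reversed trajectory distributions, hence is
non-negative.  *Local* entropy production reverses only the segment
[i, j] (inclusive) of the trajectory, pinpointing where in development
reversals are cheap (near-zero sigma: local oscillations) and where
they are forbidden (large sigma: committed, irreversible stretches).

Reversed sequences place tokens at the "wrong" time steps; models score
any token sequence (token embeddings are position-independent inputs),
and steps a model gives zero probability yield an infinite sigma that
the summary maps report as counts rather than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import CapabilityError, ValidationError
from .armodel import ARModel, trajectory_logprob
from .datatypes import TrajectoryEnsemble

__all__ = [
    "reverse_trajectory",
    "local_reverse",
    "entropy_production",
    "local_entropy_production",
    "expected_entropy_production",
    "EPMap",
    "ep_map",
]

K_B = 1.0  # nats


def reverse_trajectory(trajectory) -> np.ndarray:
    """Full time reversal."""
    trajectory = np.asarray(trajectory)
    if trajectory.size == 0:
        raise ValidationError("trajectory must be non-empty")
    return trajectory[::-1].copy()


def local_reverse(trajectory, i: int, j: int) -> np.ndarray:
    """Reverse positions i..j inclusive, leaving the rest unchanged."""
    trajectory = np.asarray(trajectory)
    T = trajectory.size - 1
    if not (0 <= i <= j <= T):
        raise ValidationError(f"invalid interval ({i}, {j}) for length {T + 1}")
    out = trajectory.copy()
    out[i:j + 1] = out[i:j + 1][::-1]
    return out


def entropy_production(model: ARModel, trajectory) -> float:
    """sigma(gamma) = k_B [log p(gamma) - log p(gamma~)]; +inf sentinel."""
    lp = trajectory_logprob(model, trajectory)
    lr = trajectory_logprob(model, reverse_trajectory(trajectory))
    if lr == float("-inf"):
        return float("inf")
    if lp == float("-inf"):
        return float("-inf")
    return K_B * (lp - lr)


def local_entropy_production(model: ARModel, trajectory, i: int, j: int) -> float:
    """sigma_{i,j} = k_B [log p(gamma) - log p(gamma~[i,j])]."""
    rev = local_reverse(trajectory, i, j)
    lp = trajectory_logprob(model, trajectory)
    lr = trajectory_logprob(model, rev)
    if lr == float("-inf"):
        return float("inf")
    if lp == float("-inf"):
        return float("-inf")
    return K_B * (lp - lr)


def expected_entropy_production(
    model: ARModel,
    ensemble: TrajectoryEnsemble | None = None,
    max_len: int | None = None,
    guard: int = 1_000_000,
) -> float:
    """Ensemble-expected entropy production.

    With ``max_len`` given, sums k_B p(gamma) log[p(gamma)/p(gamma~)]
    over an exhaustive enumeration of the model's support — the KL
    divergence between the forward and reversed sequence distributions.
    With ``ensemble`` given, returns the sample mean of sigma (infinite
    sentinels propagate).
    """
    if (ensemble is None) == (max_len is None):
        raise ValidationError("provide exactly one of ensemble or max_len")
    if ensemble is not None:
        vals = [entropy_production(model, row) for row in ensemble.tokens]
        return float(np.mean(vals))

    total = 0.0
    n_seen = 0
    stack: list[tuple[list[int], float]] = [([], 1.0)]
    while stack:
        prefix, p = stack.pop()
        if len(prefix) == max_len:
            n_seen += 1
            if n_seen > guard:
                raise CapabilityError(f"enumeration exceeds guard of {guard}")
            lr = trajectory_logprob(model, prefix[::-1])
            if lr == float("-inf"):
                return float("inf")
            total += p * (np.log(p) - lr)
            continue
        dist = model.next_distribution(tuple(prefix))
        for tok in np.flatnonzero(dist > 0):
            stack.append((prefix + [int(tok)], p * float(dist[tok])))
    return K_B * float(total)


@dataclass
class EPMap:
    """Mean/variance of sigma_{i, i+length} across an ensemble.

    ``table`` columns: i (segment start), length (j - i), mean_sigma,
    var_sigma, n_finite, n_infinite.  The length-0 rows are identically
    zero (reversing a single state is the identity).
    """

    table: pd.DataFrame

    def mean_by_length(self) -> pd.Series:
        finite = self.table[self.table.n_finite > 0]
        return finite.groupby("length").mean_sigma.mean()


def ep_map(
    model: ARModel,
    ensemble: TrajectoryEnsemble,
    max_length: int | None = None,
) -> EPMap:
    """Local entropy production over all feasible (start, length) cells."""
    if ensemble.n_trajectories == 0:
        raise ValidationError("ensemble must be non-empty")
    T = ensemble.length - 1
    max_length = T if max_length is None else min(max_length, T)
    # score forward trajectories once
    fwd = {idx: trajectory_logprob(model, row)
           for idx, row in enumerate(ensemble.tokens)}
    rows = []
    for length in range(0, max_length + 1):
        for i in range(0, T - length + 1):
            j = i + length
            vals = []
            n_inf = 0
            for idx, row in enumerate(ensemble.tokens):
                if length == 0:
                    vals.append(0.0)
                    continue
                lr = trajectory_logprob(model, local_reverse(row, i, j))
                if lr == float("-inf") or fwd[idx] == float("-inf"):
                    n_inf += 1
                    continue
                vals.append(K_B * (fwd[idx] - lr))
            rows.append(
                {
                    "i": i,
                    "length": length,
                    "mean_sigma": float(np.mean(vals)) if vals else float("nan"),
                    "var_sigma": float(np.var(vals)) if vals else float("nan"),
                    "n_finite": len(vals),
                    "n_infinite": n_inf,
                }
            )
    return EPMap(pd.DataFrame(rows))
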