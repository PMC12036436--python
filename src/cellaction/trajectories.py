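"""Candidate transition kernels and trajectory sampling.

Each cell's *configuration* is the concatenation of its expression and
velocity after gene-wise standardization and projection onto the top
principal axes of the pooled expression: ``C = (x, w·ẋ)`` with
``velocity_weight`` w.  Candidate next states are the k nearest
next-layer cells in configuration space; transition probabilities are a
softmax over Pearson correlations between configurations,

    p(j -> k) = exp(corr(C_j, C_k)) / sum_l exp(corr(C_j, C_l)),

optionally with an exponential-decay memory over the last ``L`` visited
states (decay ``lambda`` in [0, 1], most recent state weighted
``lambda^0 = 1``), which makes the kernel non-Markovian.  Sampling a
trajectory starts from a uniformly drawn layer-0 cell and walks the
kernel to the final layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from ._errors import ValidationError
from ._rng import substream
from .datatypes import CellTable, TrajectoryEnsemble

__all__ = [
    "ConfigurationMatrix",
    "TransitionKernel",
    "build_configurations",
    "candidate_neighbors",
    "all_candidates",
    "markov_transition_probs",
    "memory_transition_probs",
    "sample_trajectories",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfigurationMatrix:
    """Per-cell configuration vectors plus the shared projection basis."""

    values: np.ndarray           # (n_cells, n_pcs or 2*n_pcs)
    basis: np.ndarray            # (n_pcs, n_genes_kept)
    kept_genes: np.ndarray       # indices of non-constant genes
    velocity_weight: float
    table: CellTable

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class TransitionKernel:
    """Per-step candidate sets and row-stochastic transition rows.

    ``candidates[t]`` is an ``(N_t, k_t)`` array of next-layer cell rows
    for every layer-``t`` cell; ``probs[t]`` the matching probability
    rows; ``corrs[t]`` the Pearson correlations they derive from.
    """

    candidates: list
    probs: list
    corrs: list
    configs: ConfigurationMatrix

    def __post_init__(self) -> None:
        for t, rows in enumerate(self.probs):
            sums = rows.sum(axis=1)
            if np.any(rows < 0) or np.any(np.abs(sums - 1.0) > 1e-12):
                raise ValidationError(f"kernel rows at step {t} are not stochastic")


def build_configurations(
    table: CellTable, n_pcs: int, velocity_weight: float
) -> ConfigurationMatrix:
    """Standardize, project and concatenate expression and velocity.

    Expression is standardized gene-wise over the pooled table (constant
    genes dropped with a warning) and projected onto its top ``n_pcs``
    principal axes.  Velocity is divided by the same gene scales,
    projected onto the same basis (it is a direction, so the centering
    offset is not subtracted) and scaled by ``velocity_weight``.  With
    ``velocity_weight = 0`` the configuration is expression-only.
    """
    if n_pcs > min(table.n_cells, table.n_genes):
        raise ValidationError(
            f"n_pcs={n_pcs} exceeds min(n_cells, n_genes)="
            f"{min(table.n_cells, table.n_genes)}"
        )
    X = table.expression
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < table.n_genes:
        logger.warning(
            "dropping %d zero-variance genes", table.n_genes - kept.size
        )
    if kept.size == 0:
        raise ValidationError("all genes have zero variance")
    n_pcs = min(n_pcs, kept.size)
    Z = (X[:, kept] - mu[kept]) / sd[kept]
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    pca.fit(Z)
    # project explicitly (not fit_transform): the matrix product maps
    # bitwise-identical cells to bitwise-identical configurations, which
    # the quantizer relies on for duplicate states
    proj = (Z - pca.mean_) @ pca.components_.T
    if velocity_weight == 0:
        values = proj
    else:
        V = table.velocity[:, kept] / sd[kept]
        vproj = V @ pca.components_.T
        values = np.concatenate([proj, velocity_weight * vproj], axis=1)
    return ConfigurationMatrix(
        values=values,
        basis=pca.components_,
        kept_genes=kept,
        velocity_weight=velocity_weight,
        table=table,
    )


def candidate_neighbors(
    configs: ConfigurationMatrix, layer_t: np.ndarray, layer_t1: np.ndarray, k: int
) -> np.ndarray:
    """k nearest next-layer cells per source cell, Euclidean distance.

    Ties at the k-th distance are broken by ascending cell index, so the
    candidate sets are deterministic.  If the next layer holds fewer
    than ``k`` cells, all of them are candidates.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    layer_t = np.asarray(layer_t, dtype=int)
    layer_t1 = np.asarray(layer_t1, dtype=int)
    if layer_t1.size == 0:
        raise ValidationError("next layer is empty")
    k_eff = min(k, layer_t1.size)
    D = cdist(configs.values[layer_t], configs.values[layer_t1])
    out = np.empty((layer_t.size, k_eff), dtype=int)
    for i in range(layer_t.size):
        order = np.lexsort((layer_t1, D[i]))  # distance, then cell index
        out[i] = layer_t1[order[:k_eff]]
    return out


def all_candidates(configs: ConfigurationMatrix, k: int) -> list:
    """Candidate sets for every consecutive layer pair, indexed by step."""
    table = configs.table
    return [
        candidate_neighbors(
            configs, table.layer_indices(t), table.layer_indices(t + 1), k
        )
        for t in range(table.n_layers - 1)
    ]


def _pearson_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``x`` with each row of ``Y``.

    A constant vector has undefined correlation; it is defined as 0 here
    (with a warning), matching the kernel's error contract.
    """
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc)
    yn = np.linalg.norm(Yc, axis=1)
    bad = (yn == 0) | (xn == 0)
    if np.any(bad):
        logger.warning("constant configuration vector: correlation set to 0")
    denom = np.where(bad, 1.0, xn * yn)
    r = (Yc @ xc) / denom
    r[bad] = 0.0
    return np.clip(r, -1.0, 1.0)


def _softmax(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max())
    return e / e.sum()


def markov_transition_probs(
    configs: ConfigurationMatrix, candidates: list
) -> TransitionKernel:
    """Softmax-over-correlation rows for every layer transition."""
    table = configs.table
    probs, corrs = [], []
    for t, cand in enumerate(candidates):
        layer = table.layer_indices(t)
        if cand.shape[1] == 0:
            raise ValidationError(f"empty candidate sets at step {t}")
        P = np.empty(cand.shape, dtype=float)
        R = np.empty(cand.shape, dtype=float)
        for i, j in enumerate(layer):
            r = _pearson_rows(configs.values[j], configs.values[cand[i]])
            R[i] = r
            P[i] = _softmax(r)
        probs.append(P)
        corrs.append(R)
    return TransitionKernel(candidates=candidates, probs=probs, corrs=corrs,
                            configs=configs)


def memory_transition_probs(
    configs: ConfigurationMatrix,
    candidates_row: np.ndarray,
    history: list,
    memory_lambda: float,
    memory_window: int,
) -> np.ndarray:
    """Memory-weighted transition row over one cell's candidates.

    ``history`` lists previously visited cell rows, most recent first.
    The score of candidate ``k`` is ``sum_m lambda^m corr(C_hist[m], C_k)``
    over the last ``min(L, len(history))`` states; ``lambda^0 = 1`` by
    convention even at ``lambda = 0``, so ``lambda = 0`` (or ``L = 1``)
    reduces exactly to the Markov kernel.
    """
    if not (0.0 <= memory_lambda <= 1.0):
        raise ValidationError("memory_lambda must lie in [0, 1]")
    if memory_window < 1:
        raise ValidationError("memory_window must be >= 1")
    if len(history) == 0:
        raise ValidationError("history must contain at least the current state")
    cand_vecs = configs.values[np.asarray(candidates_row, dtype=int)]
    scores = np.zeros(len(candidates_row))
    for m in range(min(memory_window, len(history))):
        w = 1.0 if m == 0 else memory_lambda ** m
        if w == 0.0:
            break
        scores += w * _pearson_rows(configs.values[history[m]], cand_vecs)
    return _softmax(scores)


def sample_trajectories(
    kernel: TransitionKernel,
    n_trajectories: int,
    seed: int,
    memory_lambda: float = 0.0,
    memory_window: int = 1,
) -> TrajectoryEnsemble:
    """Sample cell-level trajectories from the (memory-weighted) kernel.

    Each trajectory starts at a uniformly drawn layer-0 cell; element
    ``t`` always lies in layer ``t``.  With ``memory_window > 1`` and
    ``memory_lambda > 0`` each step re-weights the candidate row by the
    recent history; otherwise the precomputed Markov rows are used.
    """
    if n_trajectories < 1:
        raise ValidationError("n_trajectories must be >= 1")
    table = kernel.configs.table
    rng = substream(seed, "sample_trajectories")
    T = len(kernel.candidates)
    layer0 = table.layer_indices(0)
    pos_in_layer = [
        {int(c): i for i, c in enumerate(table.layer_indices(t))}
        for t in range(T + 1)
    ]
    use_memory = memory_window > 1 and memory_lambda > 0
    out = np.empty((n_trajectories, T + 1), dtype=int)
    for i in range(n_trajectories):
        cur = int(layer0[rng.integers(layer0.size)])
        path = [cur]
        for t in range(T):
            row_i = pos_in_layer[t][cur]
            cand = kernel.candidates[t][row_i]
            if use_memory:
                history = path[::-1]  # most recent first
                p = memory_transition_probs(
                    kernel.configs, cand, history, memory_lambda, memory_window
                )
            else:
                p = kernel.probs[t][row_i]
            cur = int(cand[rng.choice(cand.size, p=p)])
            path.append(cur)
        out[i] = path
    cell_ids = [[str(table.cell_ids[j]) for j in row] for row in out]
    return TrajectoryEnsemble(out, cell_ids)
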