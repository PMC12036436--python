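"""Vocabulary construction by per-layer Voronoi quantization.

Treating every cell as its own word would make the vocabulary as large
as the dataset, so configuration space is discretized per time layer
with centroid-based vector quantization (the Voronoi partition induced
by fitted centroids).  Quantizing within layers means a token identifies
both a region of state space and a time step, which keeps the temporal
order of generated sequences well defined.

Centroids are fitted with seeded k-means++ initialization followed by
Lloyd iterations; nearest-centroid ties break to the lowest token id and
empty tokens are dropped, so fitting is fully deterministic given the
seed.  When the requested size reaches the layer size every cell becomes
its own token (zero quantization error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._errors import LookupError_, ValidationError
from .datatypes import CellTable, TrajectoryEnsemble
from .trajectories import ConfigurationMatrix

__all__ = ["Vocabulary", "fit_vocabulary", "encode", "decode", "quantization_error"]

_MAX_LLOYD_ITER = 100


@dataclass
class Vocabulary:
    """Token centroids with layer/cell-type metadata and the cell map."""

    centroids: np.ndarray          # (n_tokens, dim)
    token_layer: np.ndarray        # (n_tokens,) time layer of each token
    token_cell_type: np.ndarray    # (n_tokens,) majority cell type
    cell_to_token: dict            # cell_id -> token id
    token_members: list = field(default_factory=list)  # cell rows per token

    @property
    def n_tokens(self) -> int:
        return self.centroids.shape[0]

    def layer_tokens(self, t: int) -> np.ndarray:
        """Token ids belonging to layer ``t``, ascending."""
        return np.flatnonzero(self.token_layer == t)

    @property
    def n_layers(self) -> int:
        return int(self.token_layer.max()) + 1

    @property
    def layer_sizes(self) -> np.ndarray:
        return np.bincount(self.token_layer, minlength=self.n_layers)


def _assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest centroid per point; ties break to the lowest centroid id."""
    D = cdist(points, centroids)
    return D.argmin(axis=1)  # argmin returns the first (lowest) minimizer


def _kmeanspp(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = [int(rng.integers(n))]
    d2 = np.sum((points - points[centers[0]]) ** 2, axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total == 0:
            centers.append(int(rng.integers(n)))
        else:
            centers.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, np.sum((points - points[centers[-1]]) ** 2, axis=1))
    return points[centers].copy()


def _lloyd(points: np.ndarray, k: int, rng: np.random.Generator):
    centroids = _kmeanspp(points, k, rng)
    labels = _assign(points, centroids)
    for _ in range(_MAX_LLOYD_ITER):
        for c in range(k):
            members = points[labels == c]
            if members.shape[0] > 0:
                centroids[c] = members.mean(axis=0)
        new_labels = _assign(points, centroids)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return centroids, labels


def fit_vocabulary(
    configs: ConfigurationMatrix,
    table: CellTable,
    vocab_size_per_layer: int,
    seed: int,
) -> Vocabulary:
    """Fit min(vocab_size_per_layer, N_t) centroids per layer."""
    if vocab_size_per_layer < 1:
        raise ValidationError("vocab_size_per_layer must be >= 1")
    from ._rng import substream

    rng = substream(seed, "fit_vocabulary")
    centroids, layers, types, members = [], [], [], []
    cell_to_token: dict = {}
    for t in range(table.n_layers):
        rows = table.layer_indices(t)
        pts = configs.values[rows]
        k = min(vocab_size_per_layer, rows.size)
        if k == rows.size:
            # saturation: every cell its own token
            cents = pts.copy()
            labels = np.arange(rows.size)
        else:
            cents, labels = _lloyd(pts, k, rng)
        for c in range(cents.shape[0]):
            member_rows = rows[labels == c]
            if member_rows.size == 0:
                continue  # empty token dropped
            token = len(centroids)
            centroids.append(cents[c])
            layers.append(t)
            ctypes, counts = np.unique(
                table.cell_types[member_rows].astype(str), return_counts=True
            )
            types.append(ctypes[counts.argmax()])
            members.append(member_rows)
            for r in member_rows:
                cell_to_token[str(table.cell_ids[r])] = token
    return Vocabulary(
        centroids=np.asarray(centroids),
        token_layer=np.asarray(layers, dtype=int),
        token_cell_type=np.asarray(types, dtype=object),
        cell_to_token=cell_to_token,
        token_members=members,
    )


def quantization_error(configs: ConfigurationMatrix, vocab: Vocabulary) -> float:
    """Total within-token sum of squared distances to the centroid."""
    sse = 0.0
    for token, rows in enumerate(vocab.token_members):
        diff = configs.values[rows] - vocab.centroids[token]
        sse += float(np.sum(diff**2))
    return sse


def encode(ensemble: TrajectoryEnsemble, vocab: Vocabulary) -> TrajectoryEnsemble:
    """Map cell-level trajectories to token sequences positionally."""
    if ensemble.cell_ids is None:
        raise ValidationError("encode requires cell ids on the ensemble")
    tokens = np.empty_like(ensemble.tokens)
    for i, ids in enumerate(ensemble.cell_ids):
        for t, cid in enumerate(ids):
            try:
                tok = vocab.cell_to_token[str(cid)]
            except KeyError:
                raise LookupError_(f"cell id {cid!r} not in vocabulary")
            if vocab.token_layer[tok] != t:
                raise ValidationError(
                    f"token {tok} of layer {vocab.token_layer[tok]} at "
                    f"position {t}"
                )
            tokens[i, t] = tok
    return TrajectoryEnsemble(tokens, ensemble.cell_ids)


def decode(tokens, vocab: Vocabulary) -> np.ndarray:
    """Centroid sequence of a token sequence, validating layer order."""
    tokens = np.asarray(tokens, dtype=int)
    if np.any(tokens < 0) or np.any(tokens >= vocab.n_tokens):
        raise LookupError_("token id out of range")
    for t, tok in enumerate(tokens):
        if vocab.token_layer[tok] != t:
            raise ValidationError(
                f"token {tok} belongs to layer {vocab.token_layer[tok]}, "
                f"not position {t}"
            )
    return vocab.centroids[tokens]
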