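"""Autoregressive trajectory models, the action functional, and metrics.

A trajectory's probability factorizes by the chain rule,

    p_theta(gamma) = prod_t p_theta(C_t | C_<t),

and its *action* is the surprise A(gamma) = -log p_theta(gamma), so the
mean action over an ensemble is exactly the cross-entropy loss used to
train a model.  All entropies and actions are in nats (k_B-free units).

This module provides the model interface, an exact count-based model
(:class:`TabularARModel`, the oracle realization of the chain rule),
two closed-form toy models used by the thermodynamic metrics, and the
action/entropy/accuracy/coverage operations.  The trained transformer
lives in :mod:`cellaction.transformer`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import CapabilityError, ValidationError
from .datatypes import TrajectoryEnsemble

__all__ = [
    "ARModel",
    "TabularARModel",
    "UniformARModel",
    "MarkovChainModel",
    "fit_tabular",
    "trajectory_logprob",
    "action",
    "ensemble_entropy",
    "model_trajectory_entropy",
    "accuracy",
    "AccuracyReport",
    "coverage",
]

NEG_INF = float("-inf")


class ARModel:
    """Interface: conditional next-token distributions over a vocabulary."""

    vocab_size: int

    def next_distribution(self, prefix: tuple) -> np.ndarray:
        """Probability vector over the vocabulary given the prefix."""
        raise NotImplementedError


class UniformARModel(ARModel):
    """I.i.d. uniform next-token model.

    Forward and reversed sequences are equally likely under this model,
    so it satisfies detailed balance exactly: entropy production is zero
    for every trajectory.
    """

    def __init__(self, vocab_size: int):
        self.vocab_size = vocab_size

    def next_distribution(self, prefix: tuple) -> np.ndarray:
        return np.full(self.vocab_size, 1.0 / self.vocab_size)


class MarkovChainModel(ARModel):
    """Stationary first-order chain with an explicit transition matrix.

    Used as a closed-form toy for irreversibility: a biased chain (e.g.
    forward probability 0.9 vs backward 0.1 on a ring) breaks detailed
    balance by ln(0.9/0.1) per biased transition.
    """

    def __init__(self, initial: np.ndarray, transition: np.ndarray):
        initial = np.asarray(initial, dtype=float)
        transition = np.asarray(transition, dtype=float)
        if abs(initial.sum() - 1.0) > 1e-9 or np.any(initial < 0):
            raise ValidationError("initial must be a probability vector")
        if np.any(np.abs(transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("transition rows must sum to 1")
        self.initial = initial
        self.transition = transition
        self.vocab_size = initial.size

    def next_distribution(self, prefix: tuple) -> np.ndarray:
        if len(prefix) == 0:
            return self.initial.copy()
        return self.transition[prefix[-1]].copy()


class TabularARModel(ARModel):
    """Empirical conditional-frequency model with suffix backoff.

    For a context seen in training the distribution equals count ratios
    exactly; an unseen context backs off to the longest seen suffix and
    ultimately to the position-wise marginal.
    """

    def __init__(self, counts: dict, marginals: list, vocab_size: int,
                 max_order: int):
        self._counts = counts
        self._marginals = marginals
        self.vocab_size = vocab_size
        self.max_order = max_order
        self.length = len(marginals)

    def next_distribution(self, prefix: tuple) -> np.ndarray:
        prefix = tuple(int(t) for t in prefix)
        for order in range(min(self.max_order, len(prefix)), 0, -1):
            ctx = prefix[-order:]
            if ctx in self._counts:
                c = self._counts[ctx]
                return c / c.sum()
        t = len(prefix)
        if t < self.length:
            m = self._marginals[t]
            return m / m.sum()
        return np.full(self.vocab_size, 1.0 / self.vocab_size)


def fit_tabular(ensemble: TrajectoryEnsemble, max_order: int,
                vocab_size: int | None = None) -> TabularARModel:
    """Fit empirical conditional distributions of orders 1..max_order.

    The order-0 distribution at position ``t`` is the marginal of
    position-``t`` tokens; it doubles as the empty-prefix distribution.
    """
    if ensemble.n_trajectories == 0:
        raise ValidationError("ensemble must be non-empty")
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    V = int(vocab_size if vocab_size is not None else ensemble.tokens.max() + 1)
    counts: dict = {}
    marginals = [np.zeros(V) for _ in range(ensemble.length)]
    for row in ensemble.tokens:
        for t, tok in enumerate(row):
            marginals[t][tok] += 1
            if t == 0:
                continue
            for order in range(1, min(max_order, t) + 1):
                ctx = tuple(int(x) for x in row[t - order:t])
                counts.setdefault(ctx, np.zeros(V))[tok] += 1
    return TabularARModel(counts, marginals, V, max_order)


def trajectory_logprob(model: ARModel, trajectory) -> float:
    """Chain-rule log-probability; -inf if any step has probability 0.

    Models exposing a ``sequence_logprob`` fast path (one forward pass
    over the whole sequence) are scored through it.
    """
    fast = getattr(model, "sequence_logprob", None)
    if fast is not None:
        return fast(trajectory)
    logp = 0.0
    prefix: list[int] = []
    for tok in np.asarray(trajectory, dtype=int):
        p = model.next_distribution(tuple(prefix))[int(tok)]
        if p <= 0.0:
            return NEG_INF
        logp += float(np.log(p))
        prefix.append(int(tok))
    return logp


def action(model: ARModel, trajectory) -> float:
    """Action A(gamma) = -log p_theta(gamma) >= 0, in nats."""
    return -trajectory_logprob(model, trajectory)


def ensemble_entropy(model: ARModel, ensemble: TrajectoryEnsemble) -> float:
    """Mean action over the ensemble — the cross-entropy training loss."""
    if ensemble.n_trajectories == 0:
        raise ValidationError("ensemble must be non-empty")
    return float(np.mean([action(model, row) for row in ensemble.tokens]))


def model_trajectory_entropy(
    model: ARModel, max_len: int, guard: int = 1_000_000
) -> tuple[float, float]:
    """Exact trajectory entropy by exhaustive support enumeration.

    Returns ``(H, expected_action)``: the Shannon entropy of the length-
    ``max_len`` sequence distribution and the expectation of the action
    under the model.  The two are equal identities computed through
    independent code paths (direct -p log p accumulation versus a
    per-sequence :func:`action` call) and cross-checked by callers.
    """
    n_seen = 0
    H = 0.0
    expected_action = 0.0

    stack: list[tuple[list[int], float]] = [([], 1.0)]
    while stack:
        prefix, p = stack.pop()
        if len(prefix) == max_len:
            n_seen += 1
            if n_seen > guard:
                raise CapabilityError(
                    f"enumeration exceeds guard of {guard} sequences"
                )
            H -= p * np.log(p)
            expected_action += p * action(model, prefix)
            continue
        dist = model.next_distribution(tuple(prefix))
        for tok in np.flatnonzero(dist > 0):
            stack.append((prefix + [int(tok)], p * float(dist[tok])))
    return float(H), float(expected_action)


@dataclass(frozen=True)
class AccuracyReport:
    """Argmax prediction quality; see :func:`accuracy`."""

    layer_order: float
    exact_token: float


def accuracy(
    model: ARModel,
    eval_ensemble: TrajectoryEnsemble,
    token_layers: np.ndarray | None = None,
) -> AccuracyReport:
    """Fraction of argmax predictions that are correct.

    ``exact_token``: predicted token equals the true next token.
    ``layer_order``: predicted token belongs to the correct time layer
    (requires ``token_layers``; the temporal-progression notion of
    correctness).  Predictions condition on the true prefix.
    """
    if eval_ensemble.n_trajectories == 0:
        raise ValidationError("eval ensemble must be non-empty")
    n = exact = layer_ok = 0
    for row in eval_ensemble.tokens:
        for t in range(len(row)):
            pred = int(np.argmax(model.next_distribution(tuple(row[:t]))))
            n += 1
            exact += pred == row[t]
            if token_layers is not None:
                layer_ok += int(token_layers[pred]) == t
    return AccuracyReport(
        layer_order=layer_ok / n if token_layers is not None else float("nan"),
        exact_token=exact / n,
    )


def coverage(
    generated: TrajectoryEnsemble, eval_ensemble: TrajectoryEnsemble
) -> float:
    """Fraction of evaluation tokens that appear anywhere in generation.

    Order-independent: only the sets of visited tokens matter.
    """
    eval_tokens = set(np.unique(eval_ensemble.tokens).tolist())
    if not eval_tokens:
        raise ValidationError("evaluation ensemble has no tokens")
    gen_tokens = set(np.unique(generated.tokens).tolist())
    return len(gen_tokens & eval_tokens) / len(eval_tokens)
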