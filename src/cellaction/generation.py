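"""Trajectory generation with nucleus sampling.

A trained autoregressive model defines a next-token distribution at each
step; nucleus sampling reshapes it with three knobs before drawing:

* temperature ``T`` — sharpen (``T < 1``) or flatten (``T > 1``) the
  distribution via ``p ∝ p^(1/T)``;
* top-k — keep only the ``k`` most likely tokens;
* top-p — keep the smallest probability-sorted prefix whose cumulative
  mass reaches ``p`` (the "nucleus").

Filters are applied in that order (temperature, top-k, top-p), the common
convention, then survivors are renormalized.  With the default settings
(unlimited k, ``p = 1``, ``T = 1``) the filter is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from ._rng import substream
from .datatypes import TrajectoryEnsemble

__all__ = ["SamplerSettings", "nucleus_filter", "generate"]


@dataclass(frozen=True)
class SamplerSettings:
    """Nucleus-sampling parameters; defaults make the filter a no-op."""

    top_k: int | None = None
    top_p: float = 1.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")
        if not (0 < self.top_p <= 1):
            raise ValidationError("top_p must be in (0, 1]")
        if self.top_k is not None and self.top_k < 1:
            raise ValidationError("top_k must be a positive integer")


def apply_temperature(probs: np.ndarray, temperature: float) -> np.ndarray:
    """Rescale ``p ∝ p^(1/T)`` in log space for numerical stability."""
    if temperature == 1.0:
        return probs.copy()
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    logp = logp / temperature
    logp -= logp.max()
    out = np.exp(logp)
    out[probs == 0] = 0.0
    return out / out.sum()


def nucleus_filter(probs: np.ndarray, settings: SamplerSettings) -> np.ndarray:
    """Temperature-scale, truncate to top-k then top-p, renormalize.

    Removed entries are exactly zero.  Ties at either truncation boundary
    are broken by ascending token id, so the result is deterministic.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise ValidationError("probs must be a non-empty 1-D vector")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("probs must be a probability vector")

    p = apply_temperature(probs, settings.temperature)
    # sort by (descending prob, ascending id): stable tie-break
    order = np.lexsort((np.arange(p.size), -p))
    keep = np.ones(p.size, dtype=bool)
    if settings.top_k is not None and settings.top_k < p.size:
        keep[order[settings.top_k:]] = False
    if settings.top_p < 1.0:
        masked = np.where(keep[order], p[order], 0.0)
        total = masked.sum()
        if total > 0:
            cum = np.cumsum(masked / total)
            # smallest prefix of surviving sorted entries with mass >= top_p
            cut = int(np.searchsorted(cum, settings.top_p, side="left"))
            keep[order[cut + 1:]] = False
    out = np.where(keep, p, 0.0)
    s = out.sum()
    if s == 0:  # pragma: no cover - unreachable: argmax always survives
        raise ValidationError("nucleus filter removed all mass")
    return out / s


def generate(
    model,
    n: int,
    settings: SamplerSettings,
    seed: int,
    length: int,
    record_distributions: bool = False,
):
    """Sample ``n`` token sequences of ``length`` steps from ``model``.

    Each step passes the model's next-token distribution through
    :func:`nucleus_filter` before drawing.  With ``record_distributions``
    the post-filter distribution at every step of every trajectory is
    returned alongside the ensemble (for the entropy metrics).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = substream(seed, "generate")
    tokens = np.empty((n, length), dtype=int)
    recorded = [] if record_distributions else None
    for i in range(n):
        prefix: list[int] = []
        dists = []
        for _ in range(length):
            probs = model.next_distribution(tuple(prefix))
            filtered = nucleus_filter(probs, settings)
            tok = int(rng.choice(filtered.size, p=filtered))
            prefix.append(tok)
            if record_distributions:
                dists.append(filtered)
        tokens[i] = prefix
        if record_distributions:
            recorded.append(dists)
    ensemble = TrajectoryEnsemble(tokens)
    if record_distributions:
        return ensemble, recorded
    return ensemble
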