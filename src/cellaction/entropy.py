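"""Stepwise normalized entropy of the developmental process.

At each time step the model's next-state distribution measures how
broadly the process explores the state space.  Because layer sizes
``N_t`` differ, raw Shannon entropies are not comparable across steps;
each is normalized by ``log N_t``, the maximum attainable at that step:

    H_normalized(t) = -sum_i p_i log p_i / log N_t  in [0, 1].

The distribution is the model's temperature-scaled next-token
distribution *restricted to layer-t tokens* and renormalized — the
normalization by the layer size presupposes that support.  Profiles are
averaged over sampled trajectories, optionally grouped by the cell type
of the current state; low-temperature profiles expose the deterministic
backbone of the process, and a developmental bottleneck appears as a
valley in the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .armodel import ARModel
from .generation import SamplerSettings, apply_temperature, generate
from .tokenize import Vocabulary

__all__ = ["EntropyProfile", "normalized_entropy", "entropy_profile"]


def normalized_entropy(p: np.ndarray, n_states: int) -> float:
    """Shannon entropy of ``p`` over ``n_states`` divided by ``log n_states``.

    ``0 log 0 := 0``; a single-state layer returns 0 by convention.
    """
    p = np.asarray(p, dtype=float)
    if n_states < 1:
        raise ValidationError("n_states must be >= 1")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("p must be a probability vector")
    if n_states == 1:
        return 0.0
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / np.log(n_states)


@dataclass
class EntropyProfile:
    """Normalized entropy per (step, temperature), with sample counts.

    ``table`` has columns step, temperature, cell_type, H, N_t,
    H_normalized, n_samples; ``cell_type`` is "all" for the ungrouped
    rows.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def values(self, temperature: float, cell_type: str = "all") -> np.ndarray:
        sub = self.table[
            (self.table.temperature == temperature)
            & (self.table.cell_type == cell_type)
        ].sort_values("step")
        return sub.H_normalized.to_numpy()


def _layer_restricted_entropy(
    dist: np.ndarray, vocab: Vocabulary, t: int, temperature: float
) -> tuple[float, float, int]:
    """(raw H, normalized H, N_t) of the layer-restricted distribution."""
    layer_toks = vocab.layer_tokens(t)
    sub = dist[layer_toks]
    total = sub.sum()
    if total <= 0:
        return 0.0, 0.0, layer_toks.size
    sub = sub / total
    sub = apply_temperature(sub, temperature)
    nz = sub[sub > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h, normalized_entropy(sub, layer_toks.size), layer_toks.size


def entropy_profile(
    model: ARModel,
    vocab: Vocabulary,
    temperatures,
    seed: int,
    n_samples: int = 100,
    by_cell_type: bool = False,
) -> EntropyProfile:
    """Sampled-average normalized entropy per step and temperature.

    For each temperature, ``n_samples`` trajectories are drawn from the
    model at that temperature; at every step the temperature-scaled
    next-token distribution given the sampled prefix is restricted to
    the step's layer, renormalized, and its normalized entropy averaged
    over the samples (optionally also grouped by the cell type of the
    current token).
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    T_steps = vocab.n_layers
    rows = []
    for temp in temperatures:
        settings = SamplerSettings(temperature=float(temp))
        ensemble = generate(
            model, n_samples, settings, seed, T_steps
        )
        acc: dict[tuple[int, str], list[float]] = {}
        raw: dict[tuple[int, str], list[float]] = {}
        for traj in ensemble.tokens:
            for t in range(T_steps):
                dist = model.next_distribution(tuple(traj[:t]))
                h, hn, _ = _layer_restricted_entropy(dist, vocab, t, float(temp))
                keys = [(t, "all")]
                if by_cell_type and t > 0:
                    keys.append(
                        (t, str(vocab.token_cell_type[traj[t - 1]]))
                    )
                for key in keys:
                    acc.setdefault(key, []).append(hn)
                    raw.setdefault(key, []).append(h)
        for (t, ct), vals in sorted(acc.items()):
            rows.append(
                {
                    "step": t,
                    "temperature": float(temp),
                    "cell_type": ct,
                    "H": float(np.mean(raw[(t, ct)])),
                    "N_t": int(vocab.layer_sizes[t]),
                    "H_normalized": float(np.mean(vals)),
                    "n_samples": len(vals),
                }
            )
    return EntropyProfile(pd.DataFrame(rows))
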