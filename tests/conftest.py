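"""Shared fixtures: seeded synthetic processes and derived pipeline stages.

All fixtures are deterministic (fixed seeds through the package's named
substreams) and small enough that the whole suite runs in minutes on one
CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellaction import (
    LineageSpec,
    all_candidates,
    build_configurations,
    encode,
    fit_tabular,
    fit_vocabulary,
    markov_transition_probs,
    sample_trajectories,
    simulate_branching_process,
)


@pytest.fixture(scope="session")
def noisy_process():
    """Three-branch process with observation noise (general pipeline)."""
    spec = LineageSpec(
        n_layers=6,
        cells_per_layer=60,
        n_genes=30,
        branch_points=((1, 3, (0.4, 0.35, 0.25)),),
        noise_sd=0.05,
        drift_scale=1.0,
    )
    table, truth = simulate_branching_process(spec, seed=7)
    return {"spec": spec, "table": table, "truth": truth}


@pytest.fixture(scope="session")
def noisefree():
    """Noise-free three-branch process: deterministic token dynamics.

    With zero noise every (branch, layer) pair of cells is a single
    point in configuration space, so the fitted vocabulary has one token
    per branch per layer and trajectory dynamics are exactly recoverable.
    """
    spec = LineageSpec(
        n_layers=6,
        cells_per_layer=45,
        n_genes=30,
        branch_points=((1, 3, (0.4, 0.35, 0.25)),),
        noise_sd=0.0,
        drift_scale=1.0,
    )
    table, truth = simulate_branching_process(spec, seed=11)
    configs = build_configurations(table, n_pcs=10, velocity_weight=1.0)
    kernel = markov_transition_probs(configs, all_candidates(configs, 8))
    ensemble = sample_trajectories(kernel, 300, seed=2)
    vocab = fit_vocabulary(configs, table, 4, seed=3)
    encoded = encode(ensemble, vocab)
    tabular = fit_tabular(encoded, max_order=1, vocab_size=vocab.n_tokens)
    return {
        "spec": spec,
        "table": table,
        "truth": truth,
        "configs": configs,
        "kernel": kernel,
        "ensemble": ensemble,
        "vocab": vocab,
        "encoded": encoded,
        "tabular": tabular,
    }


@pytest.fixture(scope="session")
def bottleneck_process():
    """Noise-free process with a designed full bottleneck at layer 4.

    Configurations are expression-only here: at the bottleneck all
    lineages occupy one expression state, so the layer quantizes to a
    single token and the stepwise entropy must dip to zero there.
    """
    spec = LineageSpec(
        n_layers=7,
        cells_per_layer=45,
        n_genes=30,
        branch_points=((1, 3, (0.4, 0.35, 0.25)),),
        bottleneck=(4, 0.3),
        noise_sd=0.0,
        drift_scale=1.0,
    )
    table, truth = simulate_branching_process(spec, seed=5)
    configs = build_configurations(table, n_pcs=10, velocity_weight=0.0)
    kernel = markov_transition_probs(configs, all_candidates(configs, 30))
    ensemble = sample_trajectories(kernel, 400, seed=3)
    vocab = fit_vocabulary(configs, table, 6, seed=4)
    encoded = encode(ensemble, vocab)
    tabular = fit_tabular(encoded, max_order=1, vocab_size=vocab.n_tokens)
    return {
        "spec": spec,
        "table": table,
        "truth": truth,
        "vocab": vocab,
        "encoded": encoded,
        "tabular": tabular,
    }


@pytest.fixture(scope="session")
def token_type_index():
    def _index(vocab):
        types = {t: i for i, t in
                 enumerate(sorted(set(str(x) for x in vocab.token_cell_type)))}
        return np.array([types[str(t)] for t in vocab.token_cell_type])

    return _index


@pytest.fixture(scope="session")
def trained_transformer(noisefree, token_type_index):
    """Transformer and tabular oracle fitted on the same training split."""
    from cellaction import ModelConfig, TrajectoryEnsemble, train_transformer

    encoded = noisefree["encoded"]
    vocab = noisefree["vocab"]
    n_hold = 60
    hold = TrajectoryEnsemble(encoded.tokens[:n_hold])
    train = TrajectoryEnsemble(encoded.tokens[n_hold:])
    model, log = train_transformer(
        train,
        token_type_index(vocab),
        ModelConfig(epochs=60),
        seed=5,
        token_layers=vocab.token_layer,
        vocab_size=vocab.n_tokens,
    )
    tabular = fit_tabular(train, max_order=1, vocab_size=vocab.n_tokens)
    return {"model": model, "log": log, "tabular": tabular,
            "holdout": hold, "train": train, "vocab": vocab}
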