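"""Causal transformer over token sequences, trained on the mean action.

The model follows the standard decoder-only recipe at desk scale: the
input at each position is the sum of a token embedding, a cell-type
embedding (the majority type of the token) and a learned position
embedding; a stack of pre-norm decoder blocks (causal multi-head
self-attention + GELU MLP) feeds a final layer norm and a projection to
vocabulary logits.  A learned begin-of-sequence token supplies the
empty-prefix distribution.  Minimizing the mean cross-entropy over
trajectories is exactly minimizing the ensemble-averaged action.

Everything — forward, backward, Adam — is implemented directly on numpy
arrays, which is entirely adequate for the vocabulary sizes (tens to a
few hundred tokens) and sequence lengths (tens of steps) this package
targets, and keeps training bit-reproducible for a given seed on one
thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from ._errors import ValidationError
from ._rng import substream
from .armodel import ARModel, coverage as _coverage
from .config import ModelConfig
from .datatypes import TrajectoryEnsemble

__all__ = ["TransformerARModel", "TrainingLog", "train_transformer"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _softmax_last(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class _LayerNorm:
    def __init__(self, params, prefix):
        self.g_key, self.b_key = f"{prefix}.g", f"{prefix}.b"
        self.params = params

    def forward(self, x):
        g, b = self.params[self.g_key], self.params[self.b_key]
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + 1e-5)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, g)
        return xhat * g + b

    def backward(self, dout, grads):
        xhat, inv, g = self._cache
        grads[self.g_key] += (dout * xhat).sum(axis=(0, 1))
        grads[self.b_key] += dout.sum(axis=(0, 1))
        dxhat = dout * g
        d = xhat.shape[-1]
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        return dx


class _Linear:
    def __init__(self, params, prefix):
        self.w_key, self.b_key = f"{prefix}.W", f"{prefix}.b"
        self.params = params

    def forward(self, x):
        self._x = x
        return x @ self.params[self.w_key] + self.params[self.b_key]

    def backward(self, dout, grads):
        W = self.params[self.w_key]
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        grads[self.w_key] += x2.T @ d2
        grads[self.b_key] += d2.sum(axis=0)
        return dout @ W.T


class _CausalAttention:
    def __init__(self, params, prefix, n_heads):
        self.qkv = _Linear(params, f"{prefix}.qkv")
        self.proj = _Linear(params, f"{prefix}.proj")
        self.n_heads = n_heads

    def forward(self, x):
        B, L, d = x.shape
        H = self.n_heads
        hd = d // H
        qkv = self.qkv.forward(x)  # (B, L, 3d)
        q, k, v = np.split(qkv, 3, axis=-1)
        # (B, H, L, hd)
        q = q.reshape(B, L, H, hd).transpose(0, 2, 1, 3)
        k = k.reshape(B, L, H, hd).transpose(0, 2, 1, 3)
        v = v.reshape(B, L, H, hd).transpose(0, 2, 1, 3)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(hd)  # (B,H,L,L)
        mask = np.triu(np.ones((L, L), dtype=bool), k=1)
        scores = np.where(mask, -1e30, scores)
        att = _softmax_last(scores)
        out = att @ v  # (B,H,L,hd)
        self._cache = (q, k, v, att, hd, B, L, d)
        merged = out.transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.proj.forward(merged)

    def backward(self, dout, grads):
        q, k, v, att, hd, B, L, d = self._cache
        H = self.n_heads
        dmerged = self.proj.backward(dout, grads)
        do = dmerged.reshape(B, L, H, hd).transpose(0, 2, 1, 3)
        datt = do @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ do
        # softmax backward per row
        dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(hd)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        def unheads(a):
            return a.transpose(0, 2, 1, 3).reshape(B, L, d)
        dqkv = np.concatenate([unheads(dq), unheads(dk), unheads(dv)], axis=-1)
        return self.qkv.backward(dqkv, grads)


class _Block:
    def __init__(self, params, prefix, n_heads):
        self.ln1 = _LayerNorm(params, f"{prefix}.ln1")
        self.att = _CausalAttention(params, f"{prefix}.att", n_heads)
        self.ln2 = _LayerNorm(params, f"{prefix}.ln2")
        self.fc1 = _Linear(params, f"{prefix}.fc1")
        self.fc2 = _Linear(params, f"{prefix}.fc2")

    def forward(self, x):
        x = x + self.att.forward(self.ln1.forward(x))
        h = self.fc1.forward(self.ln2.forward(x))
        self._h = h
        x = x + self.fc2.forward(_gelu(h))
        return x

    def backward(self, dout, grads):
        dg = self.fc2.backward(dout, grads)
        dh = dg * _gelu_grad(self._h)
        dx = dout + self.ln2.backward(self.fc1.backward(dh, grads), grads)
        da = self.att.backward(dx, grads)
        return dx + self.ln1.backward(da, grads)


@dataclass
class TrainingLog:
    """Per-epoch metrics on the held-out split."""

    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    holdout_loss: list = field(default_factory=list)
    exact_accuracy: list = field(default_factory=list)
    layer_accuracy: list = field(default_factory=list)
    coverage: list = field(default_factory=list)


class TransformerARModel(ARModel):
    """Decoder-only causal transformer implementing the ARModel interface."""

    def __init__(self, vocab_size: int, max_len: int, token_types: np.ndarray,
                 config: ModelConfig, seed: int):
        if len(token_types) != vocab_size:
            raise ValidationError(
                f"token_types length {len(token_types)} != vocab size {vocab_size}"
            )
        self.vocab_size = vocab_size
        self.max_len = max_len          # trajectory length (positions 0..T)
        self.token_types = np.asarray(token_types, dtype=int)
        self.n_types = int(self.token_types.max()) + 1 if vocab_size else 1
        self.config = config
        self.bos = vocab_size           # extra embedding row for BOS
        d = config.width
        rng = substream(seed, "transformer_init")

        def init(*shape):
            return rng.normal(0.0, 0.02, shape)

        p: dict[str, np.ndarray] = {
            "tok_emb": init(vocab_size + 1, d),
            "type_emb": init(self.n_types + 1, d),
            "pos_emb": init(max_len, d),
            "lnf.g": np.ones(d), "lnf.b": np.zeros(d),
            "out.W": init(d, vocab_size), "out.b": np.zeros(vocab_size),
        }
        for i in range(config.n_layers):
            pre = f"blk{i}"
            p[f"{pre}.ln1.g"] = np.ones(d); p[f"{pre}.ln1.b"] = np.zeros(d)
            p[f"{pre}.ln2.g"] = np.ones(d); p[f"{pre}.ln2.b"] = np.zeros(d)
            p[f"{pre}.att.qkv.W"] = init(d, 3 * d)
            p[f"{pre}.att.qkv.b"] = np.zeros(3 * d)
            p[f"{pre}.att.proj.W"] = init(d, d)
            p[f"{pre}.att.proj.b"] = np.zeros(d)
            p[f"{pre}.fc1.W"] = init(d, 4 * d); p[f"{pre}.fc1.b"] = np.zeros(4 * d)
            p[f"{pre}.fc2.W"] = init(4 * d, d); p[f"{pre}.fc2.b"] = np.zeros(d)
        self.params = p
        self.blocks = [_Block(p, f"blk{i}", config.n_heads)
                       for i in range(config.n_layers)]
        self.lnf = _LayerNorm(p, "lnf")
        self.out = _Linear(p, "out")

    # ---- forward / backward ----------------------------------------------
    def _type_ids(self, tokens: np.ndarray) -> np.ndarray:
        ids = np.where(tokens == self.bos, self.n_types,
                       self.token_types[np.minimum(tokens, self.vocab_size - 1)])
        return ids

    def _forward(self, inputs: np.ndarray) -> np.ndarray:
        """Logits (B, L, V) for input token matrix (B, L) incl. BOS column."""
        B, L = inputs.shape
        x = (
            self.params["tok_emb"][inputs]
            + self.params["type_emb"][self._type_ids(inputs)]
            + self.params["pos_emb"][np.arange(L)]
        )
        self._inputs = inputs
        for blk in self.blocks:
            x = blk.forward(x)
        x = self.lnf.forward(x)
        return self.out.forward(x)

    def _backward(self, dlogits: np.ndarray) -> dict:
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dx = self.lnf.backward(self.out.backward(dlogits, grads), grads)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx, grads)
        inputs = self._inputs
        L = inputs.shape[1]
        np.add.at(grads["tok_emb"], inputs, dx)
        np.add.at(grads["type_emb"], self._type_ids(inputs), dx)
        grads["pos_emb"] += dx.sum(axis=0)
        return grads

    def _loss_and_grads(self, tokens: np.ndarray):
        """Mean per-step cross-entropy (nats) and parameter gradients."""
        B, L = tokens.shape
        inputs = np.concatenate(
            [np.full((B, 1), self.bos, dtype=int), tokens[:, :-1]], axis=1
        )
        logits = self._forward(inputs)
        probs = _softmax_last(logits)
        idx = (np.arange(B)[:, None], np.arange(L)[None, :], tokens)
        loss = float(-np.mean(np.log(probs[idx] + 1e-300)))
        dlogits = probs.copy()
        dlogits[idx] -= 1.0
        dlogits /= B * L
        return loss, self._backward(dlogits)

    # ---- scoring ----------------------------------------------------------
    def step_distributions(self, tokens: np.ndarray) -> np.ndarray:
        """(B, L, V) conditional distributions for each next position."""
        tokens = np.asarray(tokens, dtype=int)
        squeeze = tokens.ndim == 1
        if squeeze:
            tokens = tokens[None]
        B, L = tokens.shape
        inputs = np.concatenate(
            [np.full((B, 1), self.bos, dtype=int), tokens[:, :-1]], axis=1
        )
        dists = _softmax_last(self._forward(inputs))
        return dists[0] if squeeze else dists

    def sequence_logprob(self, trajectory) -> float:
        """log p(trajectory) from a single forward pass."""
        seq = np.asarray(trajectory, dtype=int)
        dists = self.step_distributions(seq)
        p = dists[np.arange(seq.size), seq]
        return float(np.sum(np.log(p)))

    def next_distribution(self, prefix: tuple) -> np.ndarray:
        seq = np.asarray(
            [self.bos] + [int(t) for t in prefix], dtype=int
        )[None, :]
        if seq.shape[1] > self.max_len:
            raise ValidationError("prefix longer than the trained context")
        logits = self._forward(seq)
        return _softmax_last(logits[0, -1])


def save_model(model: TransformerARModel, path) -> None:
    """Checkpoint parameters + architecture metadata to an .npz file."""
    from dataclasses import asdict
    import json as _json

    meta = {
        "vocab_size": model.vocab_size,
        "max_len": model.max_len,
        "config": asdict(model.config),
    }
    np.savez(
        path,
        __meta__=np.frombuffer(_json.dumps(meta).encode(), dtype=np.uint8),
        __token_types__=model.token_types,
        **model.params,
    )


def load_model(path) -> TransformerARModel:
    import json as _json

    data = np.load(path)
    meta = _json.loads(bytes(data["__meta__"]).decode())
    model = TransformerARModel(
        meta["vocab_size"], meta["max_len"], data["__token_types__"],
        ModelConfig(**meta["config"]), seed=0,
    )
    for k in model.params:
        model.params[k] = data[k]
    return model


def _adam_update(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for k in params:
        m, v = state[k]
        m = beta1 * m + (1 - beta1) * grads[k]
        v = beta2 * v + (1 - beta2) * grads[k] ** 2
        state[k] = (m, v)
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def train_transformer(
    ensemble: TrajectoryEnsemble,
    token_types: np.ndarray,
    config: ModelConfig,
    seed: int,
    token_layers: np.ndarray | None = None,
    vocab_size: int | None = None,
    log_coverage: bool = False,
):
    """Fit the transformer by Adam on the mean trajectory action.

    Trajectories are split into train/held-out parts (seeded), trained
    in minibatches, and early-stopped on the held-out loss with the
    configured patience (best parameters restored).  The log records
    per-epoch train/holdout loss and argmax accuracy on the held-out
    split; token-set coverage of a small sampled ensemble is optional
    because it is the slowest metric.

    Returns ``(model, TrainingLog)``.
    """
    if ensemble.n_trajectories < 2:
        raise ValidationError("need at least 2 trajectories to hold out")
    tokens = ensemble.tokens
    V = int(vocab_size if vocab_size is not None else tokens.max() + 1)
    model = TransformerARModel(V, tokens.shape[1], token_types, config, seed)

    rng = substream(seed, "transformer_train")
    n = tokens.shape[0]
    perm = rng.permutation(n)
    n_hold = max(1, int(round(config.holdout_fraction * n)))
    hold, train = tokens[perm[:n_hold]], tokens[perm[n_hold:]]

    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in model.params.items()}
    log = TrainingLog()
    best_loss, best_params, best_age = np.inf, None, 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train.shape[0])
        epoch_losses = []
        for start in range(0, train.shape[0], config.batch_size):
            batch = train[order[start:start + config.batch_size]]
            loss, grads = model._loss_and_grads(batch)
            step += 1
            _adam_update(model.params, grads, state, config.learning_rate, step)
            epoch_losses.append(loss)

        dists = model.step_distributions(hold)
        idx = (np.arange(hold.shape[0])[:, None],
               np.arange(hold.shape[1])[None, :], hold)
        hold_loss = float(-np.mean(np.log(dists[idx] + 1e-300)))
        preds = dists.argmax(axis=-1)
        log.epoch.append(epoch)
        log.train_loss.append(float(np.mean(epoch_losses)))
        log.holdout_loss.append(hold_loss)
        log.exact_accuracy.append(float(np.mean(preds == hold)))
        if token_layers is not None:
            pred_layers = np.asarray(token_layers)[preds]
            log.layer_accuracy.append(
                float(np.mean(pred_layers == np.arange(hold.shape[1])[None, :]))
            )
        else:
            log.layer_accuracy.append(float("nan"))
        if log_coverage:
            gen = _sample_batch(model, 32, rng)
            log.coverage.append(
                _coverage(TrajectoryEnsemble(gen), TrajectoryEnsemble(hold))
            )
        else:
            log.coverage.append(float("nan"))

        if hold_loss < best_loss - 1e-6:
            best_loss = hold_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_age = 0
        else:
            best_age += 1
            if best_age >= config.patience:
                break
    if best_params is not None:
        model.params.update(best_params)
    return model, log


def _sample_batch(model: TransformerARModel, n: int, rng) -> np.ndarray:
    """Plain temperature-1 ancestral sampling, batched over sequences."""
    out = np.empty((n, model.max_len), dtype=int)
    for t in range(model.max_len):
        inputs = np.concatenate(
            [np.full((n, 1), model.bos, dtype=int), out[:, :t]], axis=1
        )
        dists = _softmax_last(model._forward(inputs))[:, -1, :]
        u = rng.random(n)
        cum = np.cumsum(dists, axis=1)
        out[:, t] = (u[:, None] > cum).sum(axis=1)
    return out
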