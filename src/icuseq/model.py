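"""Embedding + learned-weight aggregation + LSTM mortality model.

The model maps each hour's bag of event tokens to a single vector and
threads those vectors through a recurrent cell to produce an updated
in-hospital mortality probability every hour:

1. every vocabulary token ``v`` owns a learned embedding row ``E[v]`` and
   a scalar importance weight ``w[v]``;
2. the tokens present in one hour are combined by a softmax-weighted
   average ``sum_i a_i E[v_i]`` with ``a_i = exp(w_{v_i}) / sum_j
   exp(w_{v_j})`` over that hour — a convex combination, so ``w`` doubles
   as a global, trainable variable-importance ranking;
3. a single-layer LSTM (zero initial state) consumes the 48 hourly
   vectors; an affine head + sigmoid on every hidden state yields
   ``p_0 .. p_{T-1}``;
4. training minimizes binary cross entropy through time with the stay's
   final outcome replicated as the target at every hour.

Everything — forward pass, backpropagation through time, Adam — is
implemented directly on NumPy arrays, which keeps the package dependency-
light and the arithmetic bit-reproducible for a fixed seed.  An
embedding + per-hour MLP baseline (no recurrence) is provided for
ablation.  Empty hours feed the zero vector; the recurrent state carries
history across them.  Embedding dropout is whole-token ("word dropout"):
each present token is removed from the hour with probability ``p`` and
the softmax renormalized over the survivors.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelConfig",
    "ModelParams",
    "PredictionTrajectory",
    "init_params",
    "pack_stays",
    "embed",
    "aggregate_hour",
    "forward",
    "forward_batch",
    "loss",
    "loss_and_grads",
    "Adam",
    "importance_ranking",
    "save_checkpoint",
    "load_checkpoint",
]

EMBEDDING_DIMS = (16, 32, 48, 64)
HIDDEN_UNITS = (32, 64, 128, 256)
ARCHITECTURES = ("recurrent", "mlp-baseline")
AGGREGATIONS = ("learned-weights", "mean")

PROB_EPS = 1e-7  # clamp applied to probabilities before logs
_LOGIT_CLIP = 30.0  # importance logits are clipped before exp for safety


@dataclass
class ModelConfig:
    embedding_dim: int = 32
    hidden_units: int = 64
    embedding_dropout: float = 0.1
    bins: int = 10
    window: int = 48
    architecture: str = "recurrent"
    mlp_depth: int = 2
    aggregation: str = "learned-weights"

    def __post_init__(self):
        if self.embedding_dim not in EMBEDDING_DIMS:
            raise ValueError(f"embedding_dim must be one of {EMBEDDING_DIMS}")
        if self.hidden_units not in HIDDEN_UNITS:
            raise ValueError(f"hidden_units must be one of {HIDDEN_UNITS}")
        if not 0.0 <= self.embedding_dropout < 1.0:
            raise ValueError("embedding_dropout must be in [0, 1)")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.architecture == "mlp-baseline" and self.mlp_depth < 1:
            raise ValueError("mlp_depth must be >= 1")

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class ModelParams:
    """All trainable arrays.  ``E[0]`` (PAD) is pinned to the zero vector."""

    E: np.ndarray  # (V, d) embedding table
    w: np.ndarray  # (V,) importance logits
    Wx: np.ndarray  # (d, 4h) input->gates
    Wh: np.ndarray  # (h, 4h) state->gates
    b: np.ndarray  # (4h,) gate biases
    head_w: np.ndarray  # (h,)
    head_b: np.ndarray  # scalar ()
    mlp: list = field(default_factory=list)  # [(W, b), ...] for the baseline

    @property
    def vocab_size(self):
        return self.E.shape[0]

    def arrays(self):
        d = {"E": self.E, "w": self.w, "Wx": self.Wx, "Wh": self.Wh, "b": self.b,
             "head_w": self.head_w, "head_b": self.head_b}
        for i, (W, bb) in enumerate(self.mlp):
            d[f"mlp_W{i}"] = W
            d[f"mlp_b{i}"] = bb
        return d

    def copy(self):
        return ModelParams(
            E=self.E.copy(), w=self.w.copy(), Wx=self.Wx.copy(), Wh=self.Wh.copy(),
            b=self.b.copy(), head_w=self.head_w.copy(), head_b=self.head_b.copy(),
            mlp=[(W.copy(), bb.copy()) for W, bb in self.mlp],
        )

    def all_finite(self):
        return all(np.all(np.isfinite(a)) for a in self.arrays().values())


def init_params(config: ModelConfig, vocab_size: int, rng: np.random.Generator) -> ModelParams:
    """Seeded initialization: small-normal embeddings, Glorot gates,
    zero importance logits, forget-gate bias 1."""
    d, h = config.embedding_dim, config.hidden_units
    E = rng.normal(0.0, 0.1, size=(vocab_size, d))
    E[0] = 0.0  # PAD
    w = np.zeros(vocab_size)
    s_x = np.sqrt(6.0 / (d + 4 * h))
    s_h = np.sqrt(6.0 / (h + 4 * h))
    Wx = rng.uniform(-s_x, s_x, size=(d, 4 * h))
    Wh = rng.uniform(-s_h, s_h, size=(h, 4 * h))
    b = np.zeros(4 * h)
    b[h:2 * h] = 1.0  # forget gate bias
    head_w = rng.uniform(-np.sqrt(6.0 / (h + 1)), np.sqrt(6.0 / (h + 1)), size=h)
    head_b = np.zeros(())
    mlp = []
    if config.architecture == "mlp-baseline":
        fan_in = d
        for _ in range(config.mlp_depth):
            s = np.sqrt(6.0 / (fan_in + h))
            mlp.append((rng.uniform(-s, s, size=(fan_in, h)), np.zeros(h)))
            fan_in = h
    return ModelParams(E=E, w=w, Wx=Wx, Wh=Wh, b=b, head_w=head_w, head_b=head_b, mlp=mlp)


# ---------------------------------------------------------------------------
# batching


def pack_stays(stays, window: int):
    """Flatten a list of TokenizedStay into (tokens, seg, outcomes).

    ``seg[i] = stay_position * window + hour`` identifies the (stay, hour)
    cell of token i; empty hours simply own no tokens.
    """
    toks, segs, ys = [], [], np.empty(len(stays), dtype=float)
    for s_pos, stay in enumerate(stays):
        ys[s_pos] = stay.outcome
        base = s_pos * window
        for t, idx in enumerate(stay.hours):
            if len(idx):
                toks.append(np.asarray(idx, dtype=np.int64))
                segs.append(np.full(len(idx), base + t, dtype=np.int64))
    if toks:
        tokens = np.concatenate(toks)
        seg = np.concatenate(segs)
    else:
        tokens = np.empty(0, dtype=np.int64)
        seg = np.empty(0, dtype=np.int64)
    return tokens, seg, ys


# ---------------------------------------------------------------------------
# forward


def embed(indices, E: np.ndarray) -> np.ndarray:
    """Row lookup: k indices -> k embedding vectors (empty list allowed)."""
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= E.shape[0]):
        raise IndexError("vocabulary index out of range")
    return E[idx]


def aggregate_hour(indices, E: np.ndarray, w: np.ndarray, aggregation="learned-weights"):
    """Softmax-weighted average of one hour's token embeddings.

    Returns the zero vector for an empty hour.  With ``aggregation=
    'mean'`` the weights are uniform (equivalently, all-equal ``w``).
    """
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size == 0:
        return np.zeros(E.shape[1])
    e = embed(idx, E)
    if aggregation == "mean":
        a = np.full(idx.size, 1.0 / idx.size)
    else:
        logit = w[idx]
        logit = logit - logit.max()
        ex = np.exp(logit)
        a = ex / ex.sum()
    return a @ e


def _aggregate_batch(tokens, seg, n_seg, params, config, keep=None):
    """Batched per-(stay,hour) softmax aggregation over the flat token array.

    ``keep`` is the boolean word-dropout mask; dropped tokens leave the
    softmax (renormalizing over survivors) and an hour losing all its
    tokens collapses to the zero vector, like an empty hour.
    """
    d = config.embedding_dim
    e = params.E[tokens]
    if config.aggregation == "mean":
        logit = np.zeros(len(tokens))
    else:
        logit = np.clip(params.w[tokens], -_LOGIT_CLIP, _LOGIT_CLIP)
    ex = np.exp(logit)
    if keep is not None:
        ex = ex * keep
    denom = np.bincount(seg, weights=ex, minlength=n_seg)
    safe = np.where(denom[seg] > 0.0, denom[seg], 1.0)
    a = ex / safe
    X = np.empty((n_seg, d))
    for j in range(d):
        X[:, j] = np.bincount(seg, weights=a * e[:, j], minlength=n_seg)
    cache = {"tokens": tokens, "seg": seg, "a": a, "e": e, "n_seg": n_seg}
    return X, cache


def _aggregate_backward(dX, cache, V, d, config):
    tokens, seg, a, e = cache["tokens"], cache["seg"], cache["a"], cache["e"]
    dX_seg = dX[seg]  # (n, d)
    de = a[:, None] * dX_seg
    dE = np.zeros((V, d))
    for j in range(d):
        dE[:, j] = np.bincount(tokens, weights=de[:, j], minlength=V)
    dw = np.zeros(V)
    if config.aggregation == "learned-weights":
        g = np.einsum("nd,nd->n", e, dX_seg)
        s = np.bincount(seg, weights=a * g, minlength=cache["n_seg"])
        dlogit = a * (g - s[seg])
        dw = np.bincount(tokens, weights=dlogit, minlength=V)
    return dE, dw


def _lstm_forward(X, params, h_units):
    """X: (B, T, d) -> probs (B, T); caches every gate for BPTT."""
    B, T, _ = X.shape
    h = np.zeros((B, h_units))
    c = np.zeros((B, h_units))
    caches = []
    logits = np.empty((B, T))
    for t in range(T):
        z = X[:, t] @ params.Wx + h @ params.Wh + params.b
        i = expit(z[:, :h_units])
        f = expit(z[:, h_units:2 * h_units])
        g = np.tanh(z[:, 2 * h_units:3 * h_units])
        o = expit(z[:, 3 * h_units:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        caches.append((i, f, g, o, c, tc, h))
        h, c = h_new, c_new
        logits[:, t] = h @ params.head_w + params.head_b
    return logits, caches


def _lstm_backward(dlogits, X, hs_caches, params, h_units, grads):
    B, T, d = X.shape
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, h_units))
    dc_next = np.zeros((B, h_units))
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = hs_caches[t]
        h_t = o * tc
        dl = dlogits[:, t]
        grads["head_w"] += h_t.T @ dl
        grads["head_b"] += dl.sum()
        dh = dh_next + np.outer(dl, params.head_w)
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        grads["Wx"] += X[:, t].T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dX[:, t] = dz @ params.Wx.T
        dh_next = dz @ params.Wh.T
    return dX


def _mlp_forward(X, params):
    """Per-hour feedforward baseline: ReLU stack applied independently per hour."""
    B, T, d = X.shape
    a = X.reshape(B * T, d)
    acts = [a]
    for W, b in params.mlp:
        a = np.maximum(a @ W + b, 0.0)
        acts.append(a)
    logits = (a @ params.head_w + params.head_b).reshape(B, T)
    return logits, acts


def _mlp_backward(dlogits, acts, params, grads):
    B, T = dlogits.shape
    dl = dlogits.reshape(B * T)
    grads["head_w"] += acts[-1].T @ dl
    grads["head_b"] += dl.sum()
    da = np.outer(dl, params.head_w)
    for i in range(len(params.mlp) - 1, -1, -1):
        W, _ = params.mlp[i]
        da = da * (acts[i + 1] > 0.0)
        grads[f"mlp_W{i}"] += acts[i].T @ da
        grads[f"mlp_b{i}"] += da.sum(axis=0)
        da = da @ W.T
    d = acts[0].shape[1]
    return da.reshape(B, T, d)


def forward_batch(tokens, seg, n_stays, params, config, training_mode=False, rng=None):
    """Probabilities (n_stays, T) for a packed batch; returns (probs, cache)."""
    T = config.window
    keep = None
    if training_mode and config.embedding_dropout > 0.0:
        if rng is None:
            raise ValueError("training_mode with dropout requires an rng")
        keep = (rng.random(len(tokens)) >= config.embedding_dropout).astype(float)
    X, agg_cache = _aggregate_batch(tokens, seg, n_stays * T, params, config, keep)
    X = X.reshape(n_stays, T, config.embedding_dim)
    if config.architecture == "recurrent":
        logits, net_cache = _lstm_forward(X, params, config.hidden_units)
    else:
        logits, net_cache = _mlp_forward(X, params)
    probs = expit(logits)
    cache = {"X": X, "agg": agg_cache, "net": net_cache, "probs": probs}
    return probs, cache


@dataclass
class PredictionTrajectory:
    """Per-hour mortality probability plus per-hour token importance.

    ``hour_tokens[t]`` / ``hour_weights[t]`` hold that hour's vocabulary
    indices and their softmax aggregation weights (descending order not
    applied; see :func:`icuseq.evaluate.trajectory_report`).
    """

    stay_id: str
    probs: np.ndarray  # (T,)
    hour_tokens: list
    hour_weights: list


def forward(stay, params: ModelParams, config: ModelConfig, training_mode=False, rng=None):
    """Full trajectory for one tokenized stay.

    With dropout 0 (or ``training_mode=False``) this is deterministic.
    The prediction at hour ``t`` depends only on hours ``<= t``.
    """
    tokens, seg, _ = pack_stays([stay], config.window)
    probs, _ = forward_batch(tokens, seg, 1, params, config, training_mode, rng)
    hour_tokens, hour_weights = [], []
    for t in range(config.window):
        idx = np.asarray(stay.hours[t], dtype=np.int64)
        hour_tokens.append(idx)
        if idx.size == 0 or config.aggregation == "mean":
            hour_weights.append(
                np.full(idx.size, 1.0 / idx.size) if idx.size else np.empty(0)
            )
        else:
            logit = params.w[idx] - (params.w[idx].max() if idx.size else 0.0)
            ex = np.exp(logit)
            hour_weights.append(ex / ex.sum())
    return PredictionTrajectory(
        stay_id=stay.stay_id, probs=probs[0], hour_tokens=hour_tokens,
        hour_weights=hour_weights,
    )


# ---------------------------------------------------------------------------
# loss


def loss(probs, outcomes) -> float:
    """Summed binary cross entropy through time.

    ``probs`` is (N, T); ``outcomes`` in {0,1} (death = 1) is replicated
    as the target at every hour.  Probabilities are clamped to
    ``[eps, 1-eps]`` before the logs.
    """
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary (death = 1, survival = 0)")
    p = np.clip(np.atleast_2d(probs), PROB_EPS, 1.0 - PROB_EPS)
    yy = y[:, None]
    return float(-(yy * np.log(p) + (1.0 - yy) * np.log(1.0 - p)).sum())


def loss_and_grads(tokens, seg, outcomes, params, config, training_mode=True, rng=None):
    """Mean-per-(stay,hour) BCE and its gradients for one packed batch.

    The optimizer minimizes the *mean* of the summed loss so the stated
    learning rate is stable across batch sizes.
    """
    n = len(outcomes)
    T = config.window
    probs, cache = forward_batch(tokens, seg, n, params, config, training_mode, rng)
    p = np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    y = np.asarray(outcomes, dtype=float)[:, None]
    L = float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())

    grads = {k: np.zeros_like(v) for k, v in params.arrays().items()}
    dlogits = (probs - y) / (n * T)  # d mean-BCE / d pre-sigmoid logit
    if config.architecture == "recurrent":
        dX = _lstm_backward(dlogits, cache["X"], cache["net"], params,
                            config.hidden_units, grads)
    else:
        dX = _mlp_backward(dlogits, cache["net"], params, grads)
    dE, dw = _aggregate_backward(
        dX.reshape(n * T, config.embedding_dim), cache["agg"],
        params.vocab_size, config.embedding_dim, config,
    )
    grads["E"] += dE
    grads["E"][0] = 0.0  # PAD row stays pinned
    grads["w"] += dw
    return L, grads


class Adam:
    """Plain Adam on the parameter dict (lr 0.0005 by default)."""

    def __init__(self, params: ModelParams, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays().items()}

    def step(self, params: ModelParams, grads: dict):
        self.t += 1
        arrs = params.arrays()
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            arrs[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        params.E[0] = 0.0


def importance_ranking(w, vocab, top_k=None):
    """Tokens sorted by descending learned importance weight.

    Reserved PAD/UNK entries are excluded; exact ties break
    lexicographically so the ranking is deterministic across runs.
    Returns a list of ``(token, weight)`` pairs.
    """
    items = [
        (vocab.index_to_token[i], float(w[i]))
        for i in range(2, len(vocab.index_to_token))
    ]
    items.sort(key=lambda tw: (-tw[1], tw[0]))
    return items if top_k is None else items[:top_k]


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, params: ModelParams, config: ModelConfig, vocab=None):
    """Write config.json + params.npz (+ optional vocab.json) under ``path``."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "config.json"), "w", encoding="utf-8") as fh:
        json.dump({"config": config.to_dict(), "vocab_size": int(params.vocab_size),
                   "n_mlp_layers": len(params.mlp)}, fh, indent=1)
    arrs = params.arrays()
    np.savez(os.path.join(path, "params.npz"), **arrs)
    if vocab is not None:
        vocab.save(os.path.join(path, "vocab.json"))


def load_checkpoint(path, expected_vocab_size=None):
    """Load a checkpoint; validates parameter shapes against the vocabulary."""
    with open(os.path.join(path, "config.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    config = ModelConfig.from_dict(meta["config"])
    data = np.load(os.path.join(path, "params.npz"))
    mlp = [(data[f"mlp_W{i}"], data[f"mlp_b{i}"]) for i in range(meta["n_mlp_layers"])]
    params = ModelParams(
        E=data["E"], w=data["w"], Wx=data["Wx"], Wh=data["Wh"], b=data["b"],
        head_w=data["head_w"], head_b=data["head_b"], mlp=mlp,
    )
    V = meta["vocab_size"]
    if params.E.shape != (V, config.embedding_dim) or params.w.shape != (V,):
        raise ValueError("checkpoint parameter shapes do not match its vocabulary size")
    if expected_vocab_size is not None and V != expected_vocab_size:
        raise ValueError(
            f"checkpoint vocabulary size {V} != expected {expected_vocab_size}"
        )
    return params, config
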