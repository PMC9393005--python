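"""Recurrent sequence classifiers for location-name verification and
relation classification.

Both classifiers share one architecture: frozen token embeddings (the
verifier concatenates a frozen 2-d indicator embedding marking the
candidate span), two stacked LSTM layers with input dropout, the final
time step of the second layer into a 2-unit softmax head, cross-entropy
loss, ADAM updates.  Variable-length sentences are padded and masked so
padded steps never update the recurrent state.  After every epoch the
validation F1 is computed and the weights are checkpointed whenever it
beats the previous best; training runs a fixed number of epochs and the
best checkpoint is returned.

The network is implemented directly in numpy with hand-derived
backpropagation-through-time gradients (verified against numerical
differentiation in the test suite).  Runs are deterministic given the
config seed in single-threaded execution.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .relations import ConfusionCounts, compute_metrics

__all__ = [
    "ModelConfig",
    "EmbeddingTable",
    "SequenceExample",
    "TrainedModel",
    "train_classifier",
    "train_verifier",
    "train_relation_classifier",
    "verifier_examples",
    "relation_examples",
    "synthetic_embeddings",
]


@dataclass
class ModelConfig:
    embedding_dim: int = 300
    indicator_dim: int = 2
    recurrent_hidden: int = 64
    recurrent_hidden2: int | None = None  # defaults to recurrent_hidden
    dropout: float = 0.2
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recurrent_hidden2 is None:
            self.recurrent_hidden2 = self.recurrent_hidden
        if min(self.embedding_dim, self.recurrent_hidden, self.recurrent_hidden2) <= 0:
            raise ValueError("dimensions must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


class EmbeddingTable:
    """Static word-vector table with a shared unknown-word vector.

    Vectors are frozen: they are inputs, never trained.  The text format
    is one token per line, token followed by its floats.
    """

    def __init__(self, vectors: dict[str, np.ndarray], dim: int, seed: int = 0):
        self.dim = dim
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        rng = np.random.default_rng(seed)
        self.unk = rng.normal(0.0, 0.1, size=dim)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def lookup(self, word: str) -> np.ndarray:
        return self.vectors.get(word, self.unk)

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack([self.lookup(t) for t in tokens]) if tokens else np.zeros((0, self.dim))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for w, v in self.vectors.items():
                fh.write(w + " " + " ".join(f"{x:.6g}" for x in v) + "\n")

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        dim = 0
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if len(parts) < 2:
                continue
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
            dim = len(parts) - 1
        return cls(vectors, dim=dim, seed=seed)


def synthetic_embeddings(
    vocab: Iterable[str], dim: int = 300, seed: int = 0
) -> EmbeddingTable:
    """Deterministic random unit-scale vectors for a closed vocabulary.

    Each token's vector is seeded from a stable hash of the token, so the
    table does not depend on iteration order.
    """
    import hashlib

    vectors = {}
    for w in vocab:
        h = int.from_bytes(hashlib.sha256(f"{seed}:{w}".encode()).digest()[:8], "big")
        rng = np.random.default_rng(h % (2**63))
        vectors[w] = rng.normal(0.0, 1.0 / math.sqrt(dim), size=dim)
    return EmbeddingTable(vectors, dim=dim, seed=seed)


@dataclass(frozen=True)
class SequenceExample:
    """One classifier input: a token sequence with an optional indicator track."""

    tokens: tuple[str, ...]
    label: int
    doc_id: str = ""
    indicators: tuple[int, ...] | None = None  # 1 inside the candidate span
    flagged_fallback: bool = False

    def __post_init__(self) -> None:
        if self.indicators is not None and len(self.indicators) != len(self.tokens):
            raise ValueError("indicator track must match token count")


# ---------------------------------------------------------------------------
# LSTM internals


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMLayer:
    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / math.sqrt(input_dim + hidden)
        self.W = rng.uniform(-scale, scale, size=(input_dim + hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        # forget-gate bias 1: standard initialization for stable training
        self.b[hidden : 2 * hidden] = 1.0
        self.hidden = hidden
        self.input_dim = input_dim

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray):
        """x: (B, T, D); mask: (B, T) floats. Returns h_seq (B, T, H) + cache."""
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        h_seq = np.zeros((B, T, H))
        cache = []
        for t in range(T):
            m = mask[:, t][:, None]
            xh = np.concatenate([x[:, t, :], h], axis=1)
            z = xh @ self.W + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            c_next = m * c_new + (1 - m) * c
            h_next = m * h_new + (1 - m) * h
            cache.append((xh, i, f, g, o, c, c_new, h, m))
            h, c = h_next, c_next
            h_seq[:, t, :] = h
        return h_seq, cache

    def backward(self, dh_seq: np.ndarray, cache):
        """dh_seq: (B, T, H) gradients on the layer's outputs. Returns dx (B, T, D)."""
        B, T, H = dh_seq.shape
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.zeros((B, T, self.input_dim))
        dh_carry = np.zeros((B, H))
        dc_carry = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, c_new, h_prev, m = cache[t]
            dh = dh_seq[:, t, :] + dh_carry
            dc = dc_carry
            # undo the masked state update
            dh_new = m * dh
            dh_prev = (1 - m) * dh
            dc_new = m * dc
            dc_prev = (1 - m) * dc
            tc = np.tanh(c_new)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc * tc)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc_prev = dc_prev + dc_new * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += xh.T @ dz
            db += dz.sum(axis=0)
            dxh = dz @ self.W.T
            dx[:, t, :] = dxh[:, : self.input_dim]
            dh_carry = dh_prev + dxh[:, self.input_dim :]
            dc_carry = dc_prev
        return dx, dW, db


class _Network:
    """Two stacked LSTM layers + dense softmax head over the final time step."""

    def __init__(self, input_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.l1 = _LSTMLayer(input_dim, cfg.recurrent_hidden, rng)
        self.l2 = _LSTMLayer(cfg.recurrent_hidden, cfg.recurrent_hidden2, rng)
        scale = 1.0 / math.sqrt(cfg.recurrent_hidden2)
        self.Wd = rng.uniform(-scale, scale, size=(cfg.recurrent_hidden2, 2))
        self.bd = np.zeros(2)

    def params(self):
        return [self.l1.W, self.l1.b, self.l2.W, self.l2.b, self.Wd, self.bd]

    def set_params(self, params):
        self.l1.W, self.l1.b, self.l2.W, self.l2.b, self.Wd, self.bd = [
            p.copy() for p in params
        ]

    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray,
        rng: np.random.Generator | None = None,
    ):
        """Returns class probabilities (B, 2) and a cache for backward.

        With ``rng`` given, inverted dropout is applied to the inputs of
        both recurrent layers (one mask per sample, shared over time, as
        in the usual recurrent-dropout convention).
        """
        p = self.cfg.dropout
        drop1 = drop2 = None
        if rng is not None and p > 0:
            drop1 = (rng.random((x.shape[0], 1, x.shape[2])) >= p) / (1 - p)
            x = x * drop1
        h1, c1 = self.l1.forward(x, mask)
        h1_in = h1
        if rng is not None and p > 0:
            drop2 = (rng.random((h1.shape[0], 1, h1.shape[2])) >= p) / (1 - p)
            h1_in = h1 * drop2
        h2, c2 = self.l2.forward(h1_in, mask)
        h_final = h2[:, -1, :]  # masking carries the last valid state forward
        logits = h_final @ self.Wd + self.bd
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (c1, c2, h_final, probs, drop1, drop2, mask, x.shape)
        return probs, cache

    def backward(self, cache, labels: np.ndarray):
        """Mean cross-entropy gradients for all parameters."""
        c1, c2, h_final, probs, drop1, drop2, mask, xshape = cache
        B, T, _ = xshape
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        dWd = h_final.T @ dlogits
        dbd = dlogits.sum(axis=0)
        dh_final = dlogits @ self.Wd.T
        dh2 = np.zeros((B, T, self.cfg.recurrent_hidden2))
        dh2[:, -1, :] = dh_final
        dh1_in, dW2, db2 = self.l2.backward(dh2, c2)
        if drop2 is not None:
            dh1_in = dh1_in * drop2
        dx, dW1, db1 = self.l1.backward(dh1_in, c1)
        if drop1 is not None:
            dx = dx * drop1
        return [dW1, db1, dW2, db2, dWd, dbd]

    def loss(self, probs: np.ndarray, labels: np.ndarray) -> float:
        B = len(labels)
        return float(-np.log(probs[np.arange(B), labels] + 1e-12).mean())


class _Adam:
    def __init__(self, shapes, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Featurization and training


#: Orthogonal unit vectors embedding the in-span / out-of-span indicator.
_INDICATOR_VECTORS = np.array([[1.0, 0.0], [0.0, 1.0]])


def _batch_arrays(
    examples: Sequence[SequenceExample],
    embeddings: EmbeddingTable,
    use_indicators: bool,
):
    T = max((len(e.tokens) for e in examples), default=1)
    T = max(T, 1)
    D = embeddings.dim + (2 if use_indicators else 0)
    x = np.zeros((len(examples), T, D))
    mask = np.zeros((len(examples), T))
    labels = np.array([e.label for e in examples], dtype=int)
    for i, e in enumerate(examples):
        L = len(e.tokens)
        if L:
            x[i, :L, : embeddings.dim] = embeddings.embed(list(e.tokens))
            if use_indicators:
                ind = e.indicators or tuple([0] * L)
                x[i, :L, embeddings.dim :] = _INDICATOR_VECTORS[list(ind)]
            mask[i, :L] = 1.0
    return x, mask, labels


@dataclass
class TrainedModel:
    """Best-checkpoint classifier with its full training history."""

    config: ModelConfig
    embeddings: EmbeddingTable
    use_indicators: bool
    network: _Network
    history: list[dict] = field(default_factory=list)

    @property
    def best_val_f1(self) -> float:
        defined = [h["val_f1"] for h in self.history]
        return max(defined) if defined else float("nan")

    def predict_proba(self, examples: Sequence[SequenceExample]) -> np.ndarray:
        if not len(examples):
            return np.zeros((0, 2))
        x, mask, _ = _batch_arrays(examples, self.embeddings, self.use_indicators)
        probs, _ = self.network.forward(x, mask, rng=None)
        return probs

    def predict(self, examples: Sequence[SequenceExample], threshold: float = 0.5):
        return (self.predict_proba(examples)[:, 1] >= threshold).astype(int)


def _f1_score(labels: np.ndarray, preds: np.ndarray) -> float:
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def train_classifier(
    train: Sequence[SequenceExample],
    val: Sequence[SequenceExample],
    cfg: ModelConfig,
    embeddings: EmbeddingTable,
    use_indicators: bool,
) -> TrainedModel:
    """Train the two-layer LSTM classifier with best-val-F1 checkpointing.

    Runs exactly ``cfg.epochs`` epochs; after each, validation F1 is
    computed at threshold 0.5 and the parameters are saved whenever the
    F1 strictly improves.  A validation set with no positive labels makes
    F1 degenerate; it is treated as 0 with a warning rather than aborting.
    """
    if not train:
        raise ValueError("empty training set")
    if val and not any(e.label == 1 for e in val):
        warnings.warn("validation set has no positive labels; F1 treated as 0")
    input_dim = embeddings.dim + (2 if use_indicators else 0)
    rng = np.random.default_rng(cfg.seed)
    net = _Network(input_dim, cfg, rng)
    opt = _Adam([p.shape for p in net.params()], lr=cfg.learning_rate)
    model = TrainedModel(
        config=cfg, embeddings=embeddings, use_indicators=use_indicators, network=net
    )
    best_params = [p.copy() for p in net.params()]
    best_f1 = -1.0
    order = np.arange(len(train))
    val_x = val_mask = val_labels = None
    if val:
        val_x, val_mask, val_labels = _batch_arrays(val, embeddings, use_indicators)
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        total_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train[i] for i in order[start : start + cfg.batch_size]]
            x, mask, labels = _batch_arrays(batch, embeddings, use_indicators)
            probs, fcache = net.forward(x, mask, rng=rng)
            total_loss += net.loss(probs, labels)
            n_batches += 1
            grads = net.backward(fcache, labels)
            opt.step(net.params(), grads)
        if val:
            vprobs, _ = net.forward(val_x, val_mask, rng=None)
            vpred = (vprobs[:, 1] >= 0.5).astype(int)
            val_f1 = _f1_score(val_labels, vpred)
        else:
            val_f1 = 0.0
        model.history.append(
            {"epoch": epoch, "train_loss": total_loss / max(n_batches, 1), "val_f1": val_f1}
        )
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_params = [p.copy() for p in net.params()]
    net.set_params(best_params)
    return model


def verifier_examples(location_labels: Sequence) -> list[SequenceExample]:
    """Featurize labeled location spans for the verifier.

    Input items carry ``.sentence_tokens``, ``.span`` (start, end),
    ``.label`` and ``.doc_id``; the indicator track marks the span tokens.
    """
    out = []
    for item in location_labels:
        tokens = tuple(item.sentence_tokens)
        ind = tuple(
            1 if item.span[0] <= i < item.span[1] else 0 for i in range(len(tokens))
        )
        out.append(
            SequenceExample(
                tokens=tokens, label=item.label, doc_id=item.doc_id, indicators=ind
            )
        )
    return out


def relation_examples(
    labeled, documents: dict[str, "AnnotatedDocument"]
) -> list[SequenceExample]:
    """Featurize labeled candidates as shortest-dependency-path sequences.

    Falls back to the inter-span surface tokens (flagged) when the
    dependency graph does not connect the spans.
    """
    from .relations import path_tokens_with_fallback

    out = []
    for lc in labeled:
        cand = lc.candidate
        sent = documents[cand.doc_id].sentences[cand.sent_index]
        tokens, fallback = path_tokens_with_fallback(
            sent, cand.taxon_span, cand.location_span
        )
        out.append(
            SequenceExample(
                tokens=tuple(tokens),
                label=lc.label,
                doc_id=cand.doc_id,
                flagged_fallback=fallback,
            )
        )
    return out


def train_verifier(
    train: Sequence[SequenceExample],
    val: Sequence[SequenceExample],
    cfg: ModelConfig,
    embeddings: EmbeddingTable,
) -> TrainedModel:
    """Location-name verifier: whole sentence + indicator track."""
    return train_classifier(train, val, cfg, embeddings, use_indicators=True)


def train_relation_classifier(
    train: Sequence[SequenceExample],
    val: Sequence[SequenceExample],
    cfg: ModelConfig,
    embeddings: EmbeddingTable,
) -> TrainedModel:
    """Relation classifier: dependency-path tokens only, no indicators."""
    return train_classifier(train, val, cfg, embeddings, use_indicators=False)
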