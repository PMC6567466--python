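"""Neural text-pair matchers: a bag-of-embeddings name model and a BiLSTM
definition model, implemented directly on NumPy.

Both matchers share one architecture family: each text is encoded into a
fixed-length vector, the two encodings are concatenated and passed through
two fully connected layers, and a sigmoid maps the single output logit to a
similarity score in (0, 1).

* The **name model** encodes a name as the sum of its word embeddings —
  order-insensitive by construction, which suits short noun-phrase names.
* The **definition model** encodes a definition with a bidirectional LSTM
  and concatenates the final hidden states of the forward and backward
  passes — order-sensitive, which suits longer free text.

Word embeddings are pre-trained inputs and stay frozen during training;
the encoder (for the BiLSTM) and the decision layers are trained to minimise
binary cross-entropy with the Adam optimiser.  Model selection is
recall-oriented: after every epoch the development-set recall at threshold
0.5 is evaluated and the best-recall snapshot (ties broken by lower dev
loss) is kept, because in a curation pipeline missing a true mapping costs
more than surfacing a spurious one.
"""

from __future__ import annotations

import copy
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .lexical import word_tokens
from .types import POSITIVE, TrainingPair
from .training_data import TrainingSet

DEFAULT_EMBEDDING_DIM = 200
DEFAULT_LSTM_HIDDEN = 100
DEFAULT_DECISION_HIDDEN = 128
MAX_DEFINITION_TOKENS = 256


# ---------------------------------------------------------------------------
# Embeddings


@dataclass
class EmbeddingStore:
    """Token -> dense vector lookup; unknown tokens map to the zero vector."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._zero = np.zeros(self.dim)
        for token, vec in self.vectors.items():
            if len(vec) != self.dim:
                raise ValueError(
                    f"vector for {token!r} has length {len(vec)}, expected {self.dim}"
                )

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self._zero)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def lookup_all(self, tokens: Sequence[str]) -> np.ndarray:
        """(len(tokens), dim) matrix of embeddings."""
        if not tokens:
            return np.zeros((0, self.dim))
        return np.vstack([self[t] for t in tokens])


def read_word_vectors(path: str | Path) -> EmbeddingStore:
    """Read embeddings in the standard word-vector text format.

    One token per line followed by its floats; an optional first line holding
    just ``<count> <dim>`` (word2vec text header) is skipped.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            parts = line.rstrip("\n").split(" ")
            if lineno == 1 and len(parts) == 2:
                continue  # header line
            if len(parts) < 2:
                continue
            token, values = parts[0], np.array([float(v) for v in parts[1:]])
            if dim is None:
                dim = len(values)
            elif len(values) != dim:
                raise ValueError(f"inconsistent vector length at line {lineno}")
            vectors[token] = values
    if dim is None:
        raise ValueError(f"no vectors found in {path}")
    return EmbeddingStore(dim=dim, vectors=vectors)


def write_word_vectors(store: EmbeddingStore, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for token in sorted(store.vectors):
            floats = " ".join(repr(float(v)) for v in store.vectors[token])
            handle.write(f"{token} {floats}\n")


def concat_stores(first: EmbeddingStore, second: EmbeddingStore) -> EmbeddingStore:
    """Concatenate two stores token-wise (e.g. a word2vec half and a fasttext
    half); a token missing from one side gets zeros for that half."""
    dim = first.dim + second.dim
    tokens = set(first.vectors) | set(second.vectors)
    return EmbeddingStore(
        dim=dim,
        vectors={t: np.concatenate([first[t], second[t]]) for t in tokens},
    )


def embed_name_bag(tokens: Sequence[str], store: EmbeddingStore) -> np.ndarray:
    """Bag-of-embeddings encoding: element-wise sum of the token vectors.

    Empty or all-unknown input yields the zero vector.
    """
    if not tokens:
        return np.zeros(store.dim)
    return store.lookup_all(tokens).sum(axis=0)


# ---------------------------------------------------------------------------
# Layers


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping keeps exp() finite; sigmoid saturates far before +-60 anyway
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    """Fully connected layer with optional rectifier nonlinearity."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, relu: bool):
        self.w = _glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.relu = relu
        self._x: np.ndarray | None = None
        self._pre: np.ndarray | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        pre = x @ self.w + self.b
        self._pre = pre
        return np.maximum(pre, 0.0) if self.relu else pre

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * (self._pre > 0)
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]


class LSTM:
    """Single-direction LSTM returning the final hidden state per sequence.

    Operates on padded batches with a {0,1} mask; padded steps carry the
    previous hidden and cell state through unchanged, so the state after the
    last step equals the state at each sequence's true end.  Gradients flow
    to the weights only — inputs (frozen embeddings) receive none.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        self.n_in, self.hidden = n_in, hidden
        self.wx = _glorot(rng, n_in, 4 * hidden)
        self.wh = _glorot(rng, hidden, 4 * hidden)
        self.b = np.zeros(4 * hidden)
        # Forget-gate bias starts at 1 so early training does not wash out state.
        self.b[hidden : 2 * hidden] = 1.0
        self._cache: list[tuple] = []
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """x: (B, T, n_in); mask: (B, T) -> final hidden (B, hidden)."""
        batch, steps, _ = x.shape
        h = np.zeros((batch, self.hidden))
        c = np.zeros((batch, self.hidden))
        self._cache = []
        hs = self.hidden
        for t in range(steps):
            xt = x[:, t, :]
            m = mask[:, t : t + 1]
            z = xt @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :hs])
            f = _sigmoid(z[:, hs : 2 * hs])
            g = np.tanh(z[:, 2 * hs : 3 * hs])
            o = _sigmoid(z[:, 3 * hs :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((xt, h, c, i, f, g, o, c_new, tanh_c, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        return h

    def backward(self, dh_final: np.ndarray) -> None:
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for xt, h_prev, c_prev, i, f, g, o, c_new, tanh_c, m in reversed(self._cache):
            dh_new = m * dh
            dh_skip = (1.0 - m) * dh
            dc_new = m * dc
            dc_skip = (1.0 - m) * dc
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1.0 - tanh_c**2)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc = dc_new * f + dc_skip
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dwx += xt.T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dh = dz @ self.wh.T + dh_skip

    def params(self) -> list[np.ndarray]:
        return [self.wx, self.wh, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dwx, self.dwh, self.db]


class Adam:
    """Adaptive-moment optimiser over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Matchers


class NameMatcher:
    """Bag-of-embeddings name matcher.

    Each name is encoded as the sum of its word embeddings; the two
    encodings are concatenated and fed through the decision layers.  Only
    the decision layers hold trainable weights.
    """

    kind = "name"

    def __init__(
        self,
        store: EmbeddingStore,
        decision_hidden: int = DEFAULT_DECISION_HIDDEN,
        seed: int = 0,
        threshold: float = 0.5,
    ):
        self.store = store
        self.threshold = threshold
        rng = np.random.default_rng(seed)
        self.fc1 = Dense(rng, 2 * store.dim, decision_hidden, relu=True)
        self.fc2 = Dense(rng, decision_hidden, 1, relu=False)

    def encode(self, text: str) -> np.ndarray:
        return embed_name_bag(word_tokens(text), self.store)

    def _encode_batch(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([self.encode(t) for t in texts])

    def logits(self, texts_a: Sequence[str], texts_b: Sequence[str]) -> np.ndarray:
        x = np.hstack([self._encode_batch(texts_a), self._encode_batch(texts_b)])
        return self.fc2.forward(self.fc1.forward(x))[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        self.fc1.backward(self.fc2.backward(dlogits[:, None]))

    def score_batch(self, texts_a: Sequence[str], texts_b: Sequence[str]) -> np.ndarray:
        return _sigmoid(self.logits(texts_a, texts_b))

    def score(self, text_a: str, text_b: str) -> float:
        return float(self.score_batch([text_a], [text_b])[0])

    def params(self) -> list[np.ndarray]:
        return self.fc1.params() + self.fc2.params()

    def grads(self) -> list[np.ndarray]:
        return self.fc1.grads() + self.fc2.grads()


class DefinitionMatcher:
    """BiLSTM definition matcher with a shared (siamese) encoder.

    A definition is truncated to ``max_tokens`` word tokens, embedded, and
    run through forward and backward LSTMs; the two final hidden states are
    concatenated into a 2H encoding.  An empty definition encodes to the
    zero vector.  Both texts share the same encoder weights.
    """

    kind = "definition"

    def __init__(
        self,
        store: EmbeddingStore,
        hidden: int = DEFAULT_LSTM_HIDDEN,
        decision_hidden: int = DEFAULT_DECISION_HIDDEN,
        seed: int = 0,
        threshold: float = 0.5,
        max_tokens: int = MAX_DEFINITION_TOKENS,
    ):
        self.store = store
        self.hidden = hidden
        self.threshold = threshold
        self.max_tokens = max_tokens
        rng = np.random.default_rng(seed)
        self.fw = LSTM(rng, store.dim, hidden)
        self.bw = LSTM(rng, store.dim, hidden)
        self.fc1 = Dense(rng, 4 * hidden, decision_hidden, relu=True)
        self.fc2 = Dense(rng, decision_hidden, 1, relu=False)

    def _pack(self, texts: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Padded (B, T, dim) embedding tensors for forward and reversed
        token order, plus the (B, T) mask."""
        token_lists = [word_tokens(t)[: self.max_tokens] for t in texts]
        steps = max((len(ts) for ts in token_lists), default=0)
        steps = max(steps, 1)
        batch = len(texts)
        x_fw = np.zeros((batch, steps, self.store.dim))
        x_bw = np.zeros((batch, steps, self.store.dim))
        mask = np.zeros((batch, steps))
        for row, tokens in enumerate(token_lists):
            if not tokens:
                continue
            emb = self.store.lookup_all(tokens)
            x_fw[row, : len(tokens)] = emb
            x_bw[row, : len(tokens)] = emb[::-1]
            mask[row, : len(tokens)] = 1.0
        return x_fw, x_bw, mask

    def encode_batch(self, texts: Sequence[str]) -> np.ndarray:
        """(B, 2H) encodings; empty texts row is all zeros."""
        x_fw, x_bw, mask = self._pack(texts)
        h_fw = self.fw.forward(x_fw, mask)
        h_bw = self.bw.forward(x_bw, mask)
        return np.hstack([h_fw, h_bw])

    def encode(self, text: str) -> np.ndarray:
        return self.encode_batch([text])[0]

    def logits(self, texts_a: Sequence[str], texts_b: Sequence[str]) -> np.ndarray:
        # Encode both sides in one pass through the shared encoder so that
        # backward() can split the gradient again.
        enc = self.encode_batch(list(texts_a) + list(texts_b))
        n = len(texts_a)
        x = np.hstack([enc[:n], enc[n:]])
        return self.fc2.forward(self.fc1.forward(x))[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.fc1.backward(self.fc2.backward(dlogits[:, None]))
        h2 = 2 * self.hidden
        denc = np.vstack([dx[:, :h2], dx[:, h2:]])
        self.fw.backward(denc[:, : self.hidden])
        self.bw.backward(denc[:, self.hidden :])

    def score_batch(self, texts_a: Sequence[str], texts_b: Sequence[str]) -> np.ndarray:
        return _sigmoid(self.logits(texts_a, texts_b))

    def score(self, text_a: str, text_b: str) -> float:
        return float(self.score_batch([text_a], [text_b])[0])

    def params(self) -> list[np.ndarray]:
        return self.fw.params() + self.bw.params() + self.fc1.params() + self.fc2.params()

    def grads(self) -> list[np.ndarray]:
        return self.fw.grads() + self.bw.grads() + self.fc1.grads() + self.fc2.grads()


Matcher = NameMatcher | DefinitionMatcher


def encode_definition(
    tokens: Sequence[str], store: EmbeddingStore, encoder: DefinitionMatcher
) -> np.ndarray:
    """BiLSTM encoding of a token sequence (2H); empty input -> zero vector."""
    if store is not encoder.store:
        raise ValueError("encoder was built over a different embedding store")
    return encoder.encode(" ".join(tokens))


def score_pair(text_a: str, text_b: str, matcher: Matcher) -> float:
    """Similarity of a text pair under a trained matcher, in (0, 1)."""
    return matcher.score(text_a, text_b)


# ---------------------------------------------------------------------------
# Training


def split_train_dev(
    training: TrainingSet, dev_frac: float = 0.10, seed: int = 0
) -> tuple[TrainingSet, TrainingSet]:
    """Label-stratified, disjoint, seed-reproducible train/dev split."""
    if not 0.0 < dev_frac < 1.0:
        raise ValueError("dev_frac must lie in (0, 1)")
    labels = [p.label for p in training.pairs]
    for label in set(labels):
        if labels.count(label) < 2:
            raise ValueError(f"label {label!r} has fewer than 2 pairs; cannot stratify")
    train_pairs, dev_pairs = train_test_split(
        training.pairs, test_size=dev_frac, random_state=seed, stratify=labels
    )
    return TrainingSet(list(train_pairs)), TrainingSet(list(dev_pairs))


def pair_texts(pairs: Iterable[TrainingPair], kind: str) -> tuple[list[str], list[str], np.ndarray]:
    """Extract the matcher-relevant texts and 0/1 labels from training pairs.

    For the name matcher the canonical names are used; for the definition
    matcher only pairs where both sides carry a definition are kept.
    """
    texts_a: list[str] = []
    texts_b: list[str] = []
    y: list[int] = []
    for pair in pairs:
        if kind == "name":
            texts_a.append(pair.a_name)
            texts_b.append(pair.b_name)
        elif kind == "definition":
            if not pair.a_def or not pair.b_def:
                continue
            texts_a.append(pair.a_def)
            texts_b.append(pair.b_def)
        else:
            raise ValueError(f"unknown matcher kind {kind!r}")
        y.append(1 if pair.label == POSITIVE else 0)
    return texts_a, texts_b, np.array(y, dtype=float)


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    train_accuracy: float
    dev_loss: float
    dev_recall: float


def _bce_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    # log(1+e^z) computed stably; gradient is sigmoid(z) - y.
    loss = float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    return loss, (_sigmoid(logits) - y) / len(y)


def _recall(scores: np.ndarray, y: np.ndarray, threshold: float) -> float:
    positives = y == 1
    if not positives.any():
        return 0.0
    return float(np.mean(scores[positives] >= threshold))


def train_matcher(
    matcher: Matcher,
    train: TrainingSet,
    dev: TrainingSet,
    epochs: int = 50,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[Matcher, list[EpochStats]]:
    """Train a matcher with Adam on binary cross-entropy; return the epoch
    snapshot with maximum dev recall (ties -> lower dev loss).

    Raises ``RuntimeError`` naming the epoch if the loss becomes non-finite.
    """
    ta, tb, ty = pair_texts(train.pairs, matcher.kind)
    da, db, dy = pair_texts(dev.pairs, matcher.kind)
    if len(ty) == 0 or len(dy) == 0:
        raise ValueError("train and dev sets must both be non-empty for this matcher")
    if ty.min() == ty.max() or dy.min() == dy.max():
        raise ValueError("train and dev sets must each contain both labels")

    opt = Adam(matcher.params(), lr=lr)
    rng = np.random.default_rng(seed)
    best: tuple[float, float, list[np.ndarray]] | None = None  # (recall, -loss, params)
    history: list[EpochStats] = []
    n = len(ty)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_correct = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = matcher.logits([ta[i] for i in idx], [tb[i] for i in idx])
            loss, dlogits = _bce_and_grad(logits, ty[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            n_correct += int(
                np.sum((_sigmoid(logits) >= matcher.threshold) == (ty[idx] == 1))
            )
            matcher.backward(dlogits)
            opt.step(matcher.grads())
            epoch_loss += loss * len(idx)
        # running accuracy: each batch is scored just before its update
        train_acc = n_correct / n
        dev_logits = matcher.logits(da, db)
        dev_loss, _ = _bce_and_grad(dev_logits, dy)
        dev_recall = _recall(_sigmoid(dev_logits), dy, matcher.threshold)
        history.append(EpochStats(epoch, epoch_loss / n, train_acc, dev_loss, dev_recall))
        key = (dev_recall, -dev_loss)
        if best is None or key > (best[0], best[1]):
            best = (dev_recall, -dev_loss, [p.copy() for p in matcher.params()])
    assert best is not None
    for param, snapshot in zip(matcher.params(), best[2]):
        param[...] = snapshot
    return matcher, history


def snapshot_params(matcher: Matcher) -> list[np.ndarray]:
    return copy.deepcopy([p.copy() for p in matcher.params()])


def save_matcher(matcher: Matcher, path: str | Path) -> None:
    """Serialise a matcher's weights and hyper-shape to an .npz file.

    The embedding store is not included; it is an input and must be supplied
    again at load time.
    """
    meta = {"kind": matcher.kind, "threshold": matcher.threshold, "dim": matcher.store.dim}
    if isinstance(matcher, DefinitionMatcher):
        meta["hidden"] = matcher.hidden
        meta["max_tokens"] = matcher.max_tokens
    arrays = {f"param_{i}": p for i, p in enumerate(matcher.params())}
    np.savez(path, meta=np.array([repr(meta)]), **arrays)


def load_matcher(path: str | Path, store: EmbeddingStore) -> Matcher:
    import ast

    data = np.load(path, allow_pickle=False)
    meta = ast.literal_eval(str(data["meta"][0]))
    if meta["dim"] != store.dim:
        raise ValueError(
            f"matcher was trained over {meta['dim']}-d embeddings, store has {store.dim}"
        )
    params = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    if meta["kind"] == "name":
        hidden = params[0].shape[1]
        matcher: Matcher = NameMatcher(store, decision_hidden=hidden, threshold=meta["threshold"])
    else:
        matcher = DefinitionMatcher(
            store,
            hidden=meta["hidden"],
            decision_hidden=params[-2].shape[0],
            threshold=meta["threshold"],
            max_tokens=meta["max_tokens"],
        )
    for param, value in zip(matcher.params(), params):
        param[...] = value
    return matcher
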