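"""Distributed-memory paragraph vectors (PV-DM) for cell documents.

Training contract
-----------------
For every position t in a document, the model predicts token w_t from the
average of the document vector and the vectors of context tokens within a
fixed window around t.  The output distribution over the vocabulary is
normalized through a hierarchical-softmax binary Huffman tree, giving
log-time updates.  The learning rate decays linearly from ``initial_lr``
to ``min_lr`` over all (epoch, position) pairs.  With a fixed seed and the
single-threaded SGD kernel used here, training is bit-reproducible.

Transfer learning warm-starts a target model from a pre-trained one: the
vocabulary becomes the union of source and target tokens (training is never
limited to the intersecting genes), pre-existing token vectors are copied,
and novel tokens are seeded deterministically from their names.

The SGD inner loops are numba-compiled; the rest is plain numpy.
"""

from __future__ import annotations

import heapq
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .corpus import Corpus

logger = logging.getLogger(__name__)

_MAX_EXP = 6.0  # clamp on the sigmoid argument, as in classic word2vec


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Vocabulary and Huffman tree
# ---------------------------------------------------------------------------

def _build_vocab(freqs: dict[str, int], min_count: int = 1) -> tuple[list[str], np.ndarray]:
    items = [(t, f) for t, f in freqs.items() if f >= min_count]
    items.sort(key=lambda tf: (-tf[1], tf[0]))
    tokens = [t for t, _ in items]
    counts = np.array([f for _, f in items], dtype=np.int64)
    return tokens, counts


def _build_huffman(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary Huffman tree over token frequencies.

    Returns ``(codes, points, code_lens)`` where row w of ``codes`` holds the
    0/1 branch decisions from the root to leaf w and ``points`` the matching
    internal-node rows of the output-weight matrix (V-1 internal nodes).
    Heap ties are broken by node id, so the tree is deterministic.
    """
    V = counts.shape[0]
    if V < 2:
        raise ValueError("hierarchical softmax needs a vocabulary of >= 2 tokens")
    parent = np.zeros(2 * V - 1, dtype=np.int64)
    branch = np.zeros(2 * V - 1, dtype=np.uint8)
    heap: list[tuple[int, int]] = [(int(counts[i]), i) for i in range(V)]
    heapq.heapify(heap)
    nxt = V
    while len(heap) > 1:
        f1, i1 = heapq.heappop(heap)
        f2, i2 = heapq.heappop(heap)
        parent[i1] = nxt
        parent[i2] = nxt
        branch[i2] = 1
        heapq.heappush(heap, (f1 + f2, nxt))
        nxt += 1
    root = 2 * V - 2
    paths = []
    maxlen = 0
    for w in range(V):
        code, point = [], []
        node = w
        while node != root:
            code.append(branch[node])
            point.append(parent[node] - V)  # internal-node row in syn1
            node = parent[node]
        code.reverse()
        point.reverse()
        paths.append((code, point))
        maxlen = max(maxlen, len(code))
    codes = np.zeros((V, maxlen), dtype=np.uint8)
    points = np.zeros((V, maxlen), dtype=np.int32)
    lens = np.zeros(V, dtype=np.int32)
    for w, (code, point) in enumerate(paths):
        lens[w] = len(code)
        codes[w, : len(code)] = code
        points[w, : len(point)] = point
    return codes, points, lens


# ---------------------------------------------------------------------------
# Numba SGD kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sigmoid(x):
    if x > _MAX_EXP:
        x = _MAX_EXP
    elif x < -_MAX_EXP:
        x = -_MAX_EXP
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=False)
def _train_pvdm(tokens, doc_offsets, codes, points, code_lens,
                syn0, syn1, docvecs, window, alpha0, alpha_min, epochs,
                update_words):
    """PV-DM epochs over a packed corpus; documents in corpus order.

    ``tokens`` is the concatenation of all documents' token indices;
    ``doc_offsets[d] .. doc_offsets[d+1]`` delimits document d.  When
    ``update_words`` is false only document vectors receive gradients
    (inference mode with frozen token and output weights).
    """
    dim = syn0.shape[1]
    total = tokens.shape[0] * epochs
    if total == 0:
        return 0
    h = np.empty(dim, dtype=np.float32)
    neu = np.empty(dim, dtype=np.float32)
    processed = 0
    for _ep in range(epochs):
        for d in range(doc_offsets.shape[0] - 1):
            s, e = doc_offsets[d], doc_offsets[d + 1]
            for t in range(s, e):
                alpha = alpha0 - (alpha0 - alpha_min) * (processed / total)
                processed += 1
                w = tokens[t]
                lo = t - window if t - window > s else s
                hi = t + window + 1 if t + window + 1 < e else e
                cnt = 1
                for k in range(dim):
                    h[k] = docvecs[d, k]
                for j in range(lo, hi):
                    if j == t:
                        continue
                    cnt += 1
                    wj = tokens[j]
                    for k in range(dim):
                        h[k] += syn0[wj, k]
                inv = np.float32(1.0 / cnt)
                for k in range(dim):
                    h[k] *= inv
                    neu[k] = 0.0
                for b in range(code_lens[w]):
                    node = points[w, b]
                    f = np.float32(0.0)
                    for k in range(dim):
                        f += h[k] * syn1[node, k]
                    f = _sigmoid(f)
                    g = np.float32((1.0 - codes[w, b] - f) * alpha)
                    for k in range(dim):
                        neu[k] += g * syn1[node, k]
                    if update_words:
                        for k in range(dim):
                            syn1[node, k] += g * h[k]
                for k in range(dim):
                    docvecs[d, k] += neu[k]
                if update_words:
                    for j in range(lo, hi):
                        if j == t:
                            continue
                        wj = tokens[j]
                        for k in range(dim):
                            syn0[wj, k] += neu[k]
    return processed


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingMatrix:
    """ids x dim fixed-length embeddings."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be (len(ids), dim)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embeddings contain NaN/Inf")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, id_: str) -> np.ndarray:
        return self.vectors[self.ids.index(id_)]

    def subset(self, ids: list[str]) -> "EmbeddingMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return EmbeddingMatrix(ids=list(ids), vectors=self.vectors[idx])


@dataclass
class EmbeddingModel:
    """Trained PV-DM model with hierarchical-softmax output weights."""

    dim: int
    window: int
    initial_lr: float
    min_lr: float
    seed: int
    tokens: list[str]
    freqs: np.ndarray              # per-token corpus frequency
    token_vectors: np.ndarray      # (V, dim) float32 input vectors
    output_weights: np.ndarray     # (V-1, dim) float32 Huffman-node weights
    doc_tags: list[str]
    doc_vectors: np.ndarray        # (n_docs, dim) float32 training-doc vectors
    trained_on: list[dict] = field(default_factory=list)
    epochs_pretrain: int = 0
    epochs_finetune: int = 0

    @property
    def vocab(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    @property
    def is_trained(self) -> bool:
        return bool(self.trained_on)

    def huffman(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return _build_huffman(self.freqs)


# ---------------------------------------------------------------------------
# Training, fine-tuning, inference
# ---------------------------------------------------------------------------

def _pack_corpus(corpus: Corpus, vocab: dict[str, int]) -> tuple[np.ndarray, np.ndarray, int]:
    idx_lists = []
    n_oov = 0
    for d in corpus.documents:
        ids = [vocab[t] for t in d.tokens if t in vocab]
        n_oov += len(d.tokens) - len(ids)
        idx_lists.append(np.asarray(ids, dtype=np.int32))
    offsets = np.zeros(len(idx_lists) + 1, dtype=np.int64)
    for i, a in enumerate(idx_lists):
        offsets[i + 1] = offsets[i] + a.shape[0]
    tokens = (np.concatenate(idx_lists) if idx_lists else np.empty(0, dtype=np.int32))
    return tokens.astype(np.int32), offsets, n_oov


def _init_vectors(shape: tuple[int, ...], rng: np.random.Generator, dim: int) -> np.ndarray:
    return ((rng.random(shape) - 0.5) / dim).astype(np.float32)


def _count_tokens(corpus: Corpus) -> dict[str, int]:
    freqs: dict[str, int] = {}
    for d in corpus.documents:
        for t in d.tokens:
            freqs[t] = freqs.get(t, 0) + 1
    return freqs


def pretrain(
    source_corpus: Corpus,
    dim: int = 300,
    window: int = 5,
    initial_lr: float = 0.025,
    epochs: int = 40,
    seed: int = 0,
    min_count: int = 1,
    min_lr: float = 1e-4,
) -> EmbeddingModel:
    """Train a PV-DM model from scratch on the source corpus.

    ``min_count`` defaults to 1 (no frequency-based subsampling either), so
    rare marker genes are never dropped from the vocabulary.
    """
    if len(source_corpus) == 0:
        raise ValueError("cannot pretrain on an empty corpus")
    tokens, counts = _build_vocab(_count_tokens(source_corpus), min_count)
    if len(tokens) < 2:
        raise ValueError("vocabulary must contain >= 2 tokens")
    vocab = {t: i for i, t in enumerate(tokens)}
    codes, points, lens = _build_huffman(counts)
    packed, offsets, n_oov = _pack_corpus(source_corpus, vocab)
    if n_oov:
        logger.info("pretrain: %d tokens below min_count ignored", n_oov)

    syn0 = _init_vectors((len(tokens), dim), np.random.default_rng([seed, 0]), dim)
    syn1 = np.zeros((len(tokens) - 1, dim), dtype=np.float32)
    docvecs = np.vstack(
        [_init_vectors((1, dim), np.random.default_rng([seed, 2, i]), dim)
         for i in range(len(source_corpus))]
    )
    _train_pvdm(packed, offsets, codes, points, lens, syn0, syn1, docvecs,
                window, np.float32(initial_lr), np.float32(min_lr), epochs, True)
    return EmbeddingModel(
        dim=dim, window=window, initial_lr=initial_lr, min_lr=min_lr, seed=seed,
        tokens=tokens, freqs=counts, token_vectors=syn0, output_weights=syn1,
        doc_tags=[d.tag for d in source_corpus.documents], doc_vectors=docvecs,
        trained_on=[{"stage": "pretrain", "n_docs": len(source_corpus),
                     "vocab_size": len(tokens), "epochs": epochs, "seed": seed}],
        epochs_pretrain=epochs,
    )


def finetune(model: EmbeddingModel, target_corpus: Corpus, epochs: int, seed: int) -> EmbeddingModel:
    """Warm-start training on a target corpus (vocabulary union).

    Pre-existing token vectors carry over; tokens novel to the target are
    seeded from their names.  The Huffman tree is rebuilt on the combined
    frequencies and its output weights re-estimated during fine-tuning.
    The input model is never mutated.
    """
    if not model.is_trained:
        raise ValueError("finetune requires a pretrained model")
    combined = {t: int(f) for t, f in zip(model.tokens, model.freqs)}
    for t, f in _count_tokens(target_corpus).items():
        combined[t] = combined.get(t, 0) + f
    tokens, counts = _build_vocab(combined, min_count=1)
    vocab = {t: i for i, t in enumerate(tokens)}
    old = model.vocab
    dim = model.dim
    syn0 = np.empty((len(tokens), dim), dtype=np.float32)
    for t, i in vocab.items():
        if t in old:
            syn0[i] = model.token_vectors[old[t]]
        else:
            syn0[i] = _init_vectors((dim,), np.random.default_rng([seed, 0, _stable_hash(t)]), dim)
    syn1 = np.zeros((len(tokens) - 1, dim), dtype=np.float32)
    docvecs = np.vstack(
        [_init_vectors((1, dim), np.random.default_rng([seed, 2, i]), dim)
         for i in range(len(target_corpus))]
    ) if len(target_corpus) else np.empty((0, dim), dtype=np.float32)
    if epochs > 0 and len(target_corpus):
        codes, points, lens = _build_huffman(counts)
        packed, offsets, _ = _pack_corpus(target_corpus, vocab)
        _train_pvdm(packed, offsets, codes, points, lens, syn0, syn1, docvecs,
                    model.window, np.float32(model.initial_lr), np.float32(model.min_lr),
                    epochs, True)
    return EmbeddingModel(
        dim=dim, window=model.window, initial_lr=model.initial_lr, min_lr=model.min_lr,
        seed=model.seed, tokens=tokens, freqs=counts, token_vectors=syn0,
        output_weights=syn1, doc_tags=[d.tag for d in target_corpus.documents],
        doc_vectors=docvecs,
        trained_on=model.trained_on + [{"stage": "finetune", "n_docs": len(target_corpus),
                                        "vocab_size": len(tokens), "epochs": epochs,
                                        "seed": seed}],
        epochs_pretrain=model.epochs_pretrain, epochs_finetune=epochs,
    )


def infer_vectors(model: EmbeddingModel, corpus: Corpus, infer_epochs: int = 50,
                  seed: int = 0) -> EmbeddingMatrix:
    """Gradient inference of document vectors with frozen model weights.

    Each document's vector is initialized from the stream
    ``(seed, hash(token sequence))`` — identical documents therefore map to
    identical embeddings — and refined by ``infer_epochs`` PV-DM passes that
    update only the document vector.  Tokens absent from the vocabulary are
    ignored (their count is logged); a fully out-of-vocabulary or empty
    document keeps its deterministic initialization.
    """
    if not model.is_trained:
        raise ValueError("infer_vectors requires a trained model")
    vocab = model.vocab
    codes, points, lens = model.huffman()
    syn0 = model.token_vectors
    syn1 = model.output_weights
    dim = model.dim
    out = np.empty((len(corpus), dim), dtype=np.float32)
    n_oov = 0
    n_empty = 0
    offsets1 = np.array([0, 0], dtype=np.int64)
    for i, doc in enumerate(corpus.documents):
        ids = np.asarray([vocab[t] for t in doc.tokens if t in vocab], dtype=np.int32)
        n_oov += len(doc.tokens) - ids.shape[0]
        rng = np.random.default_rng([seed, _stable_hash(" ".join(doc.tokens))])
        vec = _init_vectors((1, dim), rng, dim)
        if ids.shape[0] == 0:
            n_empty += 1
        else:
            offsets1[1] = ids.shape[0]
            _train_pvdm(ids, offsets1, codes, points, lens, syn0, syn1, vec,
                        model.window, np.float32(model.initial_lr),
                        np.float32(model.min_lr), infer_epochs, False)
        out[i] = vec[0]
    if n_oov:
        logger.info("infer_vectors: %d out-of-vocabulary tokens ignored", n_oov)
    if n_empty:
        logger.warning("infer_vectors: %d document(s) had no in-vocabulary tokens; "
                       "returning their seed-driven initialization", n_empty)
    return EmbeddingMatrix(ids=[d.tag for d in corpus.documents], vectors=out.astype(np.float64))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a.b / (||a|| ||b||), defined only for non-zero vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Write arrays to one ``.npz`` file plus a JSON sidecar of metadata."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez(
        path,
        freqs=model.freqs,
        token_vectors=model.token_vectors,
        output_weights=model.output_weights,
        doc_vectors=model.doc_vectors,
    )
    side = {
        "dim": model.dim, "window": model.window, "initial_lr": model.initial_lr,
        "min_lr": model.min_lr, "seed": model.seed, "tokens": model.tokens,
        "doc_tags": model.doc_tags, "trained_on": model.trained_on,
        "epochs_pretrain": model.epochs_pretrain, "epochs_finetune": model.epochs_finetune,
    }
    Path(str(path) + ".json").write_text(json.dumps(side))


def load_model(path: str | Path) -> EmbeddingModel:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    arrays = np.load(npz_path)
    side = json.loads(Path(str(npz_path) + ".json").read_text())
    return EmbeddingModel(
        dim=side["dim"], window=side["window"], initial_lr=side["initial_lr"],
        min_lr=side["min_lr"], seed=side["seed"], tokens=side["tokens"],
        freqs=arrays["freqs"], token_vectors=arrays["token_vectors"],
        output_weights=arrays["output_weights"], doc_vectors=arrays["doc_vectors"],
        doc_tags=side["doc_tags"], trained_on=side["trained_on"],
        epochs_pretrain=side["epochs_pretrain"], epochs_finetune=side["epochs_finetune"],
    )
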