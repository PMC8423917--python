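"""Skip-gram word embeddings trained from scratch, plus pretrained-vector loading.

``train_sgns`` implements skip-gram with negative sampling: for each
(center, context) pair inside a dynamically shrunk window, the model pulls
the pair's vectors together while pushing the center away from ``negative``
sampled words (unigram^0.75 noise distribution).  Words appearing in similar
contexts therefore end up close in vector space, which is what makes cosine
similarity between vectors usable as a semantic edge weight.

Training is single-threaded and fully determined by the seed: the same
corpus, config and seed reproduce the table bitwise.  Updates are applied in
mini-batches with scatter-add, so repeated indices within a batch accumulate
correctly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .corpus import Corpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters for skip-gram training.

    ``dim`` and ``window`` default to the common 300/5 choice for corpus
    semantics; ``min_count=1`` keeps every word of the training sentences so
    networks can cover the full vocabulary.
    """

    dim: int = 300
    window: int = 5
    epochs: int = 5
    negative_k: int = 5
    min_count: int = 1
    alpha: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.epochs < 1 or self.negative_k < 1:
            raise ValueError("epochs and negative_k must be >= 1")


class EmbeddingTable:
    """Mapping word -> dense vector, all of one dimensionality."""

    def __init__(self, words: Sequence[str], matrix: np.ndarray):
        if len(words) != matrix.shape[0]:
            raise ValueError("words and matrix rows must align")
        if len(set(words)) != len(words):
            raise ValueError("duplicate words in embedding table")
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        self.words = list(words)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __getitem__(self, word: str) -> np.ndarray:
        return self.matrix[self._index[word]]

    def get(self, word: str) -> np.ndarray | None:
        i = self._index.get(word)
        return None if i is None else self.matrix[i]

    def subset(self, words: Iterable[str]) -> "EmbeddingTable":
        kept = [w for w in words if w in self._index]
        rows = [self._index[w] for w in kept]
        return EmbeddingTable(kept, self.matrix[rows].copy())

    def save(self, path: str | Path, header: bool = True) -> None:
        """Write in the common text dialect: optional "count dim" header, then
        one "word v1 ... vd" line per word."""
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"{len(self.words)} {self.dim}\n")
            for w, row in zip(self.words, self.matrix):
                fh.write(w + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


class VectorFormatError(ValueError):
    """Raised for malformed pretrained-vector files."""


def load_vectors(path: str | Path, expected_words: set[str] | None = None) -> EmbeddingTable:
    """Load pretrained vectors from the one-word-per-line text dialect.

    When ``expected_words`` is given only that subset is materialized, so
    loading a huge pretrained file to look up a few thousand words stays
    cheap.  The dimensionality is inferred from the first vector line; any
    line that disagrees raises ``VectorFormatError`` with its line number.
    Duplicate words keep their first occurrence (warning logged).
    """
    path = Path(path)
    words: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.split()
        has_header = len(parts) == 2 and all(p.isdigit() for p in parts)
        data = [] if has_header or not first.strip() else [(1, first)]
        data.extend(enumerate(fh, start=2))
        for lineno, line in data:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(" ")
            word = fields[0]
            values = [f for f in fields[1:] if f]
            if dim is None:
                if len(values) < 1:
                    raise VectorFormatError(f"{path}:{lineno}: no vector values")
                dim = len(values)
            elif len(values) != dim:
                raise VectorFormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(values)}"
                )
            if word in seen:
                logger.warning("%s:%d: duplicate word %r ignored", path, lineno, word)
                continue
            if expected_words is not None and word not in expected_words:
                continue
            try:
                vec = np.array([float(v) for v in values], dtype=np.float64)
            except ValueError as exc:
                raise VectorFormatError(f"{path}:{lineno}: non-numeric value") from exc
            seen.add(word)
            words.append(word)
            rows.append(vec)
    if not words:
        raise VectorFormatError(f"{path}: no vectors loaded")
    return EmbeddingTable(words, np.vstack(rows))


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _sentences_of(corpus) -> list[list[str]]:
    if isinstance(corpus, Corpus):
        return [[t.form for t in utt.tokens] for utt in corpus.utterances]
    return [list(s) for s in corpus]


def train_sgns(corpus, config: EmbeddingConfig) -> EmbeddingTable:
    """Train skip-gram-with-negative-sampling vectors on a corpus.

    ``corpus`` may be a :class:`~csnet.corpus.Corpus` or any iterable of
    token-string lists.  The learning rate decays linearly from
    ``config.alpha`` over all (sentence, epoch) work; frequency subsampling
    is off so rare words keep all their contexts.  Returns the input-side
    vectors for every word with count >= ``min_count``.
    """
    sentences = _sentences_of(corpus)
    counts = Counter(w for s in sentences for w in s)
    vocab = sorted(
        (w for w, c in counts.items() if c >= config.min_count),
        key=lambda w: (-counts[w], w),
    )
    if not vocab:
        raise ValueError("empty vocabulary after min_count filtering")
    index = {w: i for i, w in enumerate(vocab)}
    n_vocab = len(vocab)
    dim = config.dim

    rng = np.random.default_rng(config.seed)
    W = (rng.random((n_vocab, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((n_vocab, dim))                  # output (context) vectors

    # unigram^0.75 negative-sampling distribution
    freqs = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    neg_cdf = np.cumsum(freqs / freqs.sum())

    encoded = [
        np.array([index[w] for w in s if w in index], dtype=np.int64) for s in sentences
    ]
    encoded = [s for s in encoded if len(s) > 0]
    total_tokens = sum(len(s) for s in encoded)
    if total_tokens == 0:
        raise ValueError("corpus is empty after vocabulary filtering")

    batch_size = 1024
    k = config.negative_k
    min_alpha = config.alpha * 1e-4
    total_work = config.epochs * total_tokens
    done = 0

    buf_center: list[np.ndarray] = []
    buf_context: list[np.ndarray] = []
    buf_n = 0

    def flush(lr: float) -> None:
        nonlocal buf_center, buf_context, buf_n
        if buf_n == 0:
            return
        centers = np.concatenate(buf_center)
        contexts = np.concatenate(buf_context)
        buf_center, buf_context, buf_n = [], [], 0
        b = len(centers)
        negs = np.searchsorted(neg_cdf, rng.random((b, k)))
        targets = np.concatenate([contexts[:, None], negs], axis=1)  # (b, k+1)
        labels = np.zeros((b, k + 1))
        labels[:, 0] = 1.0
        h = W[centers]                      # (b, d)
        v = C[targets]                      # (b, k+1, d)
        scores = np.einsum("bd,bkd->bk", h, v)
        g = (labels - expit(scores)) * lr   # (b, k+1)
        grad_h = np.einsum("bk,bkd->bd", g, v)
        grad_v = g[:, :, None] * h[:, None, :]
        np.add.at(W, centers, grad_h)
        np.add.at(C, targets.reshape(-1), grad_v.reshape(-1, dim))

    for epoch in range(config.epochs):
        for sent in encoded:
            lr = max(min_alpha, config.alpha * (1.0 - done / total_work))
            n = len(sent)
            # dynamic window: each position uses a uniform width in [1, window]
            widths = rng.integers(1, config.window + 1, size=n)
            for i in range(n):
                lo = max(0, i - int(widths[i]))
                hi = min(n, i + int(widths[i]) + 1)
                ctx = np.concatenate([sent[lo:i], sent[i + 1 : hi]])
                if len(ctx) == 0:
                    continue
                buf_center.append(np.full(len(ctx), sent[i], dtype=np.int64))
                buf_context.append(ctx)
                buf_n += len(ctx)
            if buf_n >= batch_size:
                flush(lr)
            done += n
        flush(max(min_alpha, config.alpha * (1.0 - done / total_work)))
        logger.debug("sgns epoch %d/%d done", epoch + 1, config.epochs)
    flush(min_alpha)
    return EmbeddingTable(vocab, W)
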