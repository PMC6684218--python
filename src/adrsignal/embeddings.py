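"""Word embeddings trained by skip-gram with negative sampling.

Token vectors feed the window features of the entity tagger.  The trainer is
a compact numpy implementation of SGNS: for every (center, context) pair
within a symmetric window it pushes the pair's vectors together and pushes
the center away from ``k`` noise words drawn from the unigram distribution
raised to the 3/4 power.  Tokens below the frequency cutoff share a single
out-of-vocabulary (OOV) vector.  Everything is driven by one seeded
generator, so a fixed seed reproduces the table bit for bit.

A pretrained table in the plain-text word-vector format (first line
``<n_words> <dim>``, then ``word v1 ... v_dim`` per line) can be loaded with
:func:`load_word_vectors` instead of training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .text import TokenizedSentence

__all__ = ["EmbeddingTable", "train_embeddings", "load_word_vectors"]

OOV = "<oov>"


@dataclass
class EmbeddingTable:
    """Vocabulary → fixed-dimension real vectors with an OOV fallback."""

    vocab: dict[str, int]  # token → row index; OOV has its own row
    vectors: np.ndarray  # (len(vocab), dim) float64

    def __post_init__(self):
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        if OOV not in self.vocab:
            raise ValueError("embedding table must contain the OOV entry")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, token: str) -> np.ndarray:
        idx = self.vocab.get(token.lower(), self.vocab[OOV])
        return self.vectors[idx]

    def index(self, token: str) -> int:
        return self.vocab.get(token.lower(), self.vocab[OOV])

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab)} {self.dim}\n")
            for token, idx in sorted(self.vocab.items(), key=lambda kv: kv[1]):
                vec = " ".join(repr(float(v)) for v in self.vectors[idx])
                fh.write(f"{token} {vec}\n")


def load_word_vectors(path: str | Path) -> EmbeddingTable:
    """Load a plain-text word-vector file; adds a zero OOV row if absent."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    n, dim = (int(x) for x in lines[0].split())
    vocab: dict[str, int] = {}
    rows = []
    for line in lines[1 : n + 1]:
        parts = line.rstrip().split(" ")
        vocab[parts[0]] = len(rows)
        rows.append(np.array([float(v) for v in parts[1:]], dtype=np.float64))
        if rows[-1].shape != (dim,):
            raise ValueError(f"bad vector length for {parts[0]!r}")
    if OOV not in vocab:
        vocab[OOV] = len(rows)
        rows.append(np.zeros(dim))
    return EmbeddingTable(vocab=vocab, vectors=np.vstack(rows))


def _sentence_lemmas(sentences: Iterable[TokenizedSentence]) -> list[list[str]]:
    return [[t.lemma for t in s.tokens] for s in sentences]


def train_embeddings(
    sentences: Sequence[TokenizedSentence],
    dim: int = 150,
    seed: int = 0,
    window: int = 5,
    min_count: int = 2,
    negatives: int = 5,
    epochs: int = 3,
    lr: float = 0.05,
) -> EmbeddingTable:
    """Train skip-gram-with-negative-sampling embeddings on lemma sequences.

    Parameters mirror the conventional SGNS setup: symmetric context
    ``window``, ``negatives`` noise samples per positive pair, unigram^0.75
    noise distribution.  Tokens occurring fewer than ``min_count`` times are
    dropped from the vocabulary and resolve to the OOV vector at lookup.
    """
    if not sentences:
        raise ValueError("cannot train embeddings on an empty corpus")
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")

    corpus = _sentence_lemmas(sentences)
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(t for t, c in counts.items() if c >= min_count)
    vocab = {t: i for i, t in enumerate(kept)}
    vocab[OOV] = len(kept)
    n_vocab = len(vocab)

    rng = np.random.default_rng(seed)
    W = (rng.random((n_vocab, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((n_vocab, dim))  # output (context) vectors

    # (center, context) training pairs over in-vocabulary tokens
    pairs: list[tuple[int, int]] = []
    for sent in corpus:
        ids = [vocab[t] for t in sent if t in vocab]
        for i, center in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, ids[j]))
    if not pairs:
        # degenerate corpus (all tokens below min_count): random table only
        return EmbeddingTable(vocab=vocab, vectors=W)

    pair_arr = np.array(pairs, dtype=np.int64)
    freq = np.zeros(n_vocab)
    for t, c in counts.items():
        if t in vocab:
            freq[vocab[t]] = c
    noise = freq**0.75
    noise_p = noise / noise.sum() if noise.sum() > 0 else None

    batch = 512
    for _ in range(epochs):
        order = rng.permutation(len(pair_arr))
        for start in range(0, len(order), batch):
            sel = pair_arr[order[start : start + batch]]
            centers, contexts = sel[:, 0], sel[:, 1]
            neg = rng.choice(n_vocab, size=(len(sel), negatives), p=noise_p)
            w = W[centers]  # (b, dim)
            # positive pairs (logits clipped: sigmoid saturates anyway)
            z_pos = np.clip(np.einsum("bd,bd->b", w, C[contexts]), -30.0, 30.0)
            pos_score = 1.0 / (1.0 + np.exp(-z_pos))
            g_pos = (pos_score - 1.0)[:, None]  # (b, 1)
            # negative samples
            neg_c = C[neg]  # (b, k, dim)
            z_neg = np.clip(np.einsum("bd,bkd->bk", w, neg_c), -30.0, 30.0)
            neg_score = 1.0 / (1.0 + np.exp(-z_neg))
            g_neg = neg_score[:, :, None]  # (b, k, 1)
            grad_w = g_pos * C[contexts] + np.einsum("bkd,bko->bd", neg_c, g_neg)
            np.add.at(C, contexts, -lr * g_pos * w)
            np.add.at(
                C.reshape(-1, dim),
                neg.ravel(),
                (-lr * g_neg * w[:, None, :]).reshape(-1, dim),
            )
            np.add.at(W, centers, -lr * grad_w)

    return EmbeddingTable(vocab=vocab, vectors=W)
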