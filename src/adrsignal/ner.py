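"""Named entity recognition of ADR and indication mentions.

The tagger is a per-token feed-forward classifier: each token is represented
by the concatenated embeddings of a symmetric context window (half-width 2
by default, i.e. five tokens), passed through one tanh hidden layer and a
softmax over the five BIO tags {B-ADR, I-ADR, B-IND, I-IND, O}.  Training is
mini-batch gradient descent on cross-entropy with a fixed epoch count; all
randomness (initialisation, shuffling) comes from one seeded generator, so a
fixed seed reproduces the weights exactly.

Decoding repairs invalid BIO sequences (an ``I-x`` with no open entity is
reinterpreted as ``B-x``) and emits maximal runs as character-offset spans.
Evaluation is micro-averaged precision / recall / F over pooled true and
false positives, in either ``strict`` (exact offsets + label) or ``overlap``
(same label, >= 1 shared character, greedy one-to-one matching) mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Post
from .embeddings import EmbeddingTable
from .text import TokenizedSentence, split_sentences

__all__ = [
    "EntitySpan",
    "TaggerModel",
    "NerMetrics",
    "LABELS",
    "TAGS",
    "train_tagger",
    "tag_post",
    "tag_sentence",
    "evaluate_ner",
    "annotator_agreement",
    "read_standoff",
    "write_standoff",
]

LABELS = ("ADR", "IND")
TAGS = ("O", "B-ADR", "I-ADR", "B-IND", "I-IND")
_TAG_INDEX = {t: i for i, t in enumerate(TAGS)}


@dataclass(frozen=True)
class EntitySpan:
    """An extracted mention with half-open character offsets."""

    post_id: str
    char_start: int
    char_end: int
    surface: str
    label: str
    score: float = 1.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.char_start < self.char_end:
            raise ValueError("char_start must be < char_end")

    def overlap(self, other: "EntitySpan") -> int:
        return max(
            0, min(self.char_end, other.char_end) - max(self.char_start, other.char_start)
        )


# ---------------------------------------------------------------------------
# standoff annotation format: post_id \t start \t end \t label \t surface
# ---------------------------------------------------------------------------


def read_standoff(path: str | Path) -> list[EntitySpan]:
    spans = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"standoff line {i}: expected 5 columns, got {len(parts)}")
        post_id, start, end, label, surface = parts
        spans.append(
            EntitySpan(
                post_id=post_id,
                char_start=int(start),
                char_end=int(end),
                surface=surface,
                label=label,
            )
        )
    return spans


def write_standoff(spans: Iterable[EntitySpan], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in spans:
            fh.write(f"{s.post_id}\t{s.char_start}\t{s.char_end}\t{s.label}\t{s.surface}\n")


# ---------------------------------------------------------------------------
# tag encoding
# ---------------------------------------------------------------------------


def encode_tags(sentence: TokenizedSentence, spans: Sequence[EntitySpan]) -> list[int]:
    """Per-token BIO tag ids for the gold spans falling in this sentence.

    A gold span not aligned to token boundaries is snapped *outward* to the
    covering tokens, so gold text is never truncated.  A span that overlaps
    no token of the sentence but lies inside its character range raises.
    """
    tags = [0] * len(sentence.tokens)
    if not sentence.tokens:
        return tags
    sent_start = sentence.tokens[0].char_start
    sent_end = sentence.tokens[-1].char_end
    for span in spans:
        if span.post_id != sentence.post_id:
            continue
        if span.char_end <= sent_start or span.char_start >= sent_end:
            continue
        covered = [
            i
            for i, t in enumerate(sentence.tokens)
            if t.char_end > span.char_start and t.char_start < span.char_end
        ]
        if not covered:
            raise ValueError(f"span {span} aligns to no token in its sentence")
        tags[covered[0]] = _TAG_INDEX[f"B-{span.label}"]
        for i in covered[1:]:
            tags[i] = _TAG_INDEX[f"I-{span.label}"]
    return tags


def _window_features(
    sentence: TokenizedSentence, embeddings: EmbeddingTable, half_width: int
) -> np.ndarray:
    """(n_tokens, (2w+1)*dim) matrix of concatenated window embeddings."""
    n = len(sentence.tokens)
    dim = embeddings.dim
    rows = np.vstack([embeddings.lookup(t.lemma) for t in sentence.tokens])
    pad = np.zeros((half_width, dim))
    padded = np.vstack([pad, rows, pad])
    feats = np.hstack(
        [padded[k : k + n] for k in range(2 * half_width + 1)]
    )
    return feats


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class TaggerModel:
    """Window feed-forward tagger: weights, context width and its embeddings."""

    half_width: int
    embeddings: EmbeddingTable
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    seed: int
    epoch_losses: list[float] = field(default_factory=list)

    def predict_proba(self, sentence: TokenizedSentence) -> np.ndarray:
        """(n_tokens, 5) softmax tag probabilities."""
        if not sentence.tokens:
            return np.zeros((0, len(TAGS)))
        x = _window_features(sentence, self.embeddings, self.half_width)
        h = np.tanh(x @ self.w1 + self.b1)
        z = h @ self.w2 + self.b2
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- deterministic single-file serialization ---------------------------

    def save(self, path: str | Path) -> None:
        header = {
            "half_width": self.half_width,
            "seed": self.seed,
            "epoch_losses": self.epoch_losses,
            "vocab": sorted(self.embeddings.vocab, key=self.embeddings.vocab.get),
        }
        with Path(path).open("wb") as fh:
            fh.write(json.dumps(header, sort_keys=True).encode() + b"\n")
            for arr in (self.embeddings.vectors, self.w1, self.b1, self.w2, self.b2):
                np.save(fh, arr)

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        with Path(path).open("rb") as fh:
            header = json.loads(fh.readline().decode())
            arrays = [np.load(fh) for _ in range(5)]
        vocab = {tok: i for i, tok in enumerate(header["vocab"])}
        table = EmbeddingTable(vocab=vocab, vectors=arrays[0])
        return cls(
            half_width=header["half_width"],
            embeddings=table,
            w1=arrays[1],
            b1=arrays[2],
            w2=arrays[3],
            b2=arrays[4],
            seed=header["seed"],
            epoch_losses=list(header["epoch_losses"]),
        )


def train_tagger(
    labeled: Sequence[tuple[TokenizedSentence, Sequence[EntitySpan]]],
    embeddings: EmbeddingTable,
    seed: int = 0,
    half_width: int = 2,
    hidden: int = 300,
    epochs: int = 25,
    lr: float = 0.5,
    batch: int = 64,
) -> TaggerModel:
    """Train the window tagger on (sentence, gold spans) pairs.

    Gold spans must fall within their sentence (outward snapping to token
    boundaries is applied); a span covering no token raises.  Training loss
    per epoch is recorded on the returned model.
    """
    if not labeled:
        raise ValueError("at least one labeled sentence is required")
    feats, tags = [], []
    for sentence, spans in labeled:
        if not sentence.tokens:
            continue
        feats.append(_window_features(sentence, embeddings, half_width))
        tags.extend(encode_tags(sentence, spans))
    x = np.vstack(feats)
    y = np.array(tags, dtype=np.int64)
    n, d = x.shape
    k = len(TAGS)

    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, k))
    b2 = np.zeros(k)

    losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch):
            sel = order[start : start + batch]
            xb, yb = x[sel], y[sel]
            h = np.tanh(xb @ w1 + b1)
            z = h @ w2 + b2
            z -= z.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            total += -np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-300)).sum()
            g = p
            g[np.arange(len(yb)), yb] -= 1.0
            g /= len(yb)
            gw2 = h.T @ g
            gb2 = g.sum(axis=0)
            gh = (g @ w2.T) * (1.0 - h**2)
            gw1 = xb.T @ gh
            gb1 = gh.sum(axis=0)
            w2 -= lr * gw2
            b2 -= lr * gb2
            w1 -= lr * gw1
            b1 -= lr * gb1
        losses.append(total / n)

    model = TaggerModel(
        half_width=half_width,
        embeddings=embeddings,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        seed=seed,
        epoch_losses=losses,
    )
    return model


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _decode_sentence(
    sentence: TokenizedSentence, proba: np.ndarray, body: str
) -> list[EntitySpan]:
    tag_ids = proba.argmax(axis=1)
    tags = [TAGS[i] for i in tag_ids]
    # repair: I-x with no open entity of type x becomes B-x
    for i, tag in enumerate(tags):
        if tag.startswith("I-"):
            prev = tags[i - 1] if i > 0 else "O"
            if prev == "O" or prev[2:] != tag[2:]:
                tags[i] = "B-" + tag[2:]
    spans: list[EntitySpan] = []
    i = 0
    while i < len(tags):
        if tags[i].startswith("B-"):
            label = tags[i][2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{label}":
                j += 1
            start = sentence.tokens[i].char_start
            end = sentence.tokens[j - 1].char_end
            score = float(
                np.mean([proba[t, tag_ids[t]] for t in range(i, j)])
            )
            spans.append(
                EntitySpan(
                    post_id=sentence.post_id,
                    char_start=start,
                    char_end=end,
                    surface=body[start:end],
                    label=label,
                    score=score,
                )
            )
            i = j
        else:
            i += 1
    return spans


def tag_sentence(model: TaggerModel, sentence: TokenizedSentence, body: str) -> list[EntitySpan]:
    return _decode_sentence(sentence, model.predict_proba(sentence), body)


def tag_post(model: TaggerModel, post: Post) -> list[EntitySpan]:
    """Extract ADR and indication spans from one post."""
    spans: list[EntitySpan] = []
    for sentence in split_sentences(post.body, post_id=post.post_id):
        spans.extend(tag_sentence(model, sentence, post.body))
    return spans


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NerMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _match_overlap(pred: list[EntitySpan], gold: list[EntitySpan]) -> int:
    """Greedy one-to-one same-label matching by descending overlap length."""
    candidates = []
    for i, p in enumerate(pred):
        for j, g in enumerate(gold):
            if p.label == g.label:
                ov = p.overlap(g)
                if ov > 0:
                    candidates.append((-ov, p.char_start, g.char_start, i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for _, _, _, i, j in candidates:
        if i not in used_p and j not in used_g:
            used_p.add(i)
            used_g.add(j)
            tp += 1
    return tp


def evaluate_ner(
    predicted: Sequence[EntitySpan],
    gold: Sequence[EntitySpan],
    mode: str = "strict",
    known_posts: set[str] | None = None,
) -> NerMetrics:
    """Micro-averaged span evaluation.

    ``strict``: a true positive needs identical offsets and label.
    ``overlap``: same label and >= 1 shared character, with greedy
    one-to-one matching by overlap length.  TP/FP/FN are pooled over all
    posts before computing precision, recall and F.
    """
    if mode not in ("strict", "overlap"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if known_posts is not None:
        for s in list(predicted) + list(gold):
            if s.post_id not in known_posts:
                raise ValueError(f"span references unknown post_id {s.post_id!r}")
    if mode == "strict":
        pkeys = {(s.post_id, s.char_start, s.char_end, s.label) for s in predicted}
        gkeys = {(s.post_id, s.char_start, s.char_end, s.label) for s in gold}
        tp = len(pkeys & gkeys)
        return NerMetrics(tp=tp, fp=len(pkeys) - tp, fn=len(gkeys) - tp)
    by_post_p: dict[str, list[EntitySpan]] = {}
    by_post_g: dict[str, list[EntitySpan]] = {}
    for s in predicted:
        by_post_p.setdefault(s.post_id, []).append(s)
    for s in gold:
        by_post_g.setdefault(s.post_id, []).append(s)
    tp = 0
    for post_id in set(by_post_p) | set(by_post_g):
        tp += _match_overlap(by_post_p.get(post_id, []), by_post_g.get(post_id, []))
    return NerMetrics(tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)


def annotator_agreement(
    annotations_a: Sequence[EntitySpan],
    annotations_b: Sequence[EntitySpan],
    mode: str = "strict",
) -> float:
    """Inter-annotator agreement: micro-F of A with B taken as gold."""
    return evaluate_ner(annotations_a, annotations_b, mode=mode).f_measure
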