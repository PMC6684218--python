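"""Tokenization, sentence splitting and lemmatization.

The same lemma function is used when indexing concept names and when
normalizing extracted mention text — the two sides must be bit-identical for
retrieval to behave.  Lemmatization is dictionary-backed: a small exception
table handles irregular forms common in patient language ("been" → "be",
"peeling" → "peel"), and regular plural / -ing / -ed suffixes are stripped
by rule.  It is deliberately conservative: an unknown short word is left
alone rather than over-stemmed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "Token",
    "TokenizedSentence",
    "tokenize",
    "split_sentences",
    "lemmatize",
    "lemma_bag",
]


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    char_start: int
    char_end: int  # half-open


@dataclass
class TokenizedSentence:
    """Tokens of one sentence; offsets index into the original post body."""

    post_id: str
    tokens: list[Token]

    def __post_init__(self):
        prev_end = -1
        for t in self.tokens:
            if not (t.char_start < t.char_end and t.char_start >= prev_end):
                raise ValueError(
                    f"tokens must be non-overlapping and ascending; got {t}"
                )
            prev_end = t.char_end


_WORD = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z]+)?")
_SENT_BOUNDARY = re.compile(r"[.!?]+\s+|\n+")

# Irregular forms seen in colloquial ADR descriptions.  Keys and values are
# lowercase; applied before the suffix rules.
LEMMA_EXCEPTIONS: dict[str, str] = {
    "been": "be",
    "being": "be",
    "am": "be",
    "is": "be",
    "are": "be",
    "was": "be",
    "were": "be",
    "has": "have",
    "had": "have",
    "having": "have",
    "does": "do",
    "did": "do",
    "doing": "do",
    "goes": "go",
    "went": "go",
    "gone": "go",
    "feet": "foot",
    "teeth": "tooth",
    "worse": "bad",
    "worst": "bad",
    "got": "get",
    "gotten": "get",
    "me": "i",
    "my": "i",
    "lost": "lose",
    "losing": "lose",
    "swollen": "swell",
    "dryness": "dry",
    "itchy": "itch",
    "itchiness": "itch",
    "blistered": "blister",
    "blistering": "blister",
    "sweating": "sweat",
    "peeling": "peel",
    "cracked": "crack",
    "cracking": "crack",
    "flaking": "flake",
    "flaky": "flake",
}

_VOWELS = set("aeiou")


def lemmatize(word: str) -> str:
    """Lowercase lemma of a single token."""
    w = word.lower()
    if w in LEMMA_EXCEPTIONS:
        return LEMMA_EXCEPTIONS[w]
    n = len(w)
    # plural nouns / 3rd-person verbs
    if w.endswith("ies") and n > 4:
        return w[:-3] + "y"
    if w.endswith(("sses", "shes", "ches", "xes", "zes")) and n > 4:
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")) and n > 3:
        return w[:-1]
    # progressive
    if w.endswith("ing") and n > 5:
        stem = w[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]  # running → run
        if stem[-1] not in _VOWELS and len(stem) > 2 and stem[-2] in _VOWELS and stem[-3] not in _VOWELS:
            return stem + "e"  # scaling → scale
        return stem
    # past tense
    if w.endswith("ed") and n > 4:
        stem = w[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]
        if stem.endswith(("at", "iz", "ir", "ibl", "ur")):
            return stem + "e"
        return stem
    return w


def tokenize(text: str, post_id: str = "", offset: int = 0) -> TokenizedSentence:
    """Tokenize one sentence, keeping half-open character offsets.

    ``offset`` shifts offsets so they index into the full post body when the
    text passed in is a sentence slice.
    """
    tokens = [
        Token(
            surface=m.group(0),
            lemma=lemmatize(m.group(0)),
            char_start=m.start() + offset,
            char_end=m.end() + offset,
        )
        for m in _WORD.finditer(text)
    ]
    return TokenizedSentence(post_id=post_id, tokens=tokens)


def split_sentences(body: str, post_id: str = "") -> list[TokenizedSentence]:
    """Rule-based sentence split on terminal punctuation and newlines."""
    sentences: list[TokenizedSentence] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(body):
        chunk = body[start : m.end()]
        if chunk.strip():
            sentences.append(tokenize(chunk, post_id=post_id, offset=start))
        start = m.end()
    tail = body[start:]
    if tail.strip():
        sentences.append(tokenize(tail, post_id=post_id, offset=start))
    return [s for s in sentences if s.tokens]


def lemma_bag(text: str) -> list[str]:
    """Lemma multiset of a phrase, in surface order."""
    return [t.lemma for t in tokenize(text).tokens]
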