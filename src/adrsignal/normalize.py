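"""Concept normalization: map extracted mention text to grouped ADR concepts.

The target-ADR lexicon is built from seed concepts in a small ontology file
(a stand-in for licensed terminology access): every seed contributes its
preferred name and synonyms; seeds flagged for child expansion also
contribute the names and synonyms of concepts one hierarchy level below
(is-a children); physician-curated colloquial phrases are attached to each
seed's human-readable group.  Each lexicon entry carries a concept id
(CUI-style), its seed concept and a group id such as ``nail changes``.

Retrieval indexes one document per entry, keyed by the lemma bag of its
name, and ranks candidates by TF-IDF cosine similarity: the query mention is
tokenized and lemmatized with exactly the same function used at index time.
Stop-words are kept in the bag; their low IDF down-weights them naturally.
A mention with no shared *informative* lemma (one that does not occur in
every document) returns no match.  Ties break by larger lemma overlap, then
lexicographic concept id, so results are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import log, sqrt
from pathlib import Path
from typing import Iterable, Sequence

from .text import lemma_bag

__all__ = [
    "OntologyConcept",
    "Ontology",
    "LexiconEntry",
    "ConceptMatch",
    "ConceptIndex",
    "load_ontology",
    "load_lexicon",
    "write_lexicon",
    "load_colloquial",
    "load_seeds",
    "expand_lexicon",
    "build_index",
    "normalize_mention",
]

SOURCES = ("seed", "synonym", "child", "colloquial")


@dataclass(frozen=True)
class OntologyConcept:
    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...]
    parents: tuple[str, ...]


class Ontology:
    """Concept records with an is-a hierarchy; parent links must be acyclic."""

    def __init__(self, concepts: Iterable[OntologyConcept]):
        self.concepts: dict[str, OntologyConcept] = {}
        for c in concepts:
            if c.concept_id in self.concepts:
                raise ValueError(f"duplicate concept_id {c.concept_id!r}")
            self.concepts[c.concept_id] = c
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(cid: str) -> None:
            if state.get(cid) == 1:
                raise ValueError(f"cycle in ontology parent links at {cid!r}")
            if state.get(cid) == 2:
                return
            state[cid] = 1
            for parent in self.concepts.get(
                cid, OntologyConcept(cid, "", (), ())
            ).parents:
                visit(parent)
            state[cid] = 2

        for cid in self.concepts:
            visit(cid)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> OntologyConcept:
        return self.concepts[concept_id]

    def children(self, concept_id: str) -> list[OntologyConcept]:
        """Concepts one level below (direct is-a children), sorted by id."""
        return sorted(
            (c for c in self.concepts.values() if concept_id in c.parents),
            key=lambda c: c.concept_id,
        )


@dataclass(frozen=True)
class LexiconEntry:
    """One name in the target-ADR lexicon."""

    name: str
    concept_id: str
    seed_concept_id: str
    group_id: str
    source: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("lexicon entry name must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")


@dataclass(frozen=True)
class ConceptMatch:
    concept_id: str
    name: str
    group_id: str
    score: float
    rank: int


# ---------------------------------------------------------------------------
# file formats (all tab-separated)
# ---------------------------------------------------------------------------


def load_ontology(path: str | Path) -> Ontology:
    """TSV: concept_id, preferred_name, pipe-delimited synonyms, pipe-delimited parents."""
    concepts = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"ontology line {i}: expected 4 columns, got {len(parts)}")
        cid, name, syns, parents = parts
        concepts.append(
            OntologyConcept(
                concept_id=cid,
                preferred_name=name,
                synonyms=tuple(s for s in syns.split("|") if s),
                parents=tuple(p for p in parents.split("|") if p),
            )
        )
    return Ontology(concepts)


def load_seeds(path: str | Path) -> list[tuple[str, str, bool]]:
    """TSV: concept_id, group_id, expand_children (true/false)."""
    seeds = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"seeds line {i}: expected 3 columns, got {len(parts)}")
        seeds.append((parts[0], parts[1], parts[2].strip().lower() == "true"))
    return seeds


def load_colloquial(path: str | Path) -> list[tuple[str, str]]:
    """TSV: phrase, group_id."""
    rows = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"colloquial line {i}: expected 2 columns, got {len(parts)}")
        rows.append((parts[0], parts[1]))
    return rows


def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """TSV: name, concept_id, seed_concept_id, group_id, source."""
    entries = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"lexicon line {i}: expected 5 columns, got {len(parts)}")
        entries.append(LexiconEntry(*parts))
    return entries


def write_lexicon(entries: Iterable[LexiconEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(
                f"{e.name}\t{e.concept_id}\t{e.seed_concept_id}\t{e.group_id}\t{e.source}\n"
            )


# ---------------------------------------------------------------------------
# lexicon expansion
# ---------------------------------------------------------------------------


def expand_lexicon(
    seeds: Sequence[tuple[str, str, bool]],
    ontology: Ontology,
    colloquial: Sequence[tuple[str, str]] = (),
    child_depth: int = 1,
) -> list[LexiconEntry]:
    """Expand seed concepts into the full lexicon.

    Per seed: its preferred name, all synonyms, and — iff flagged — the
    names and synonyms of descendant concepts down to ``child_depth`` levels.
    Colloquial phrases attach to their group's seed.  Entries are
    deduplicated on (name, concept_id).
    """
    entries: list[LexiconEntry] = []
    seen: set[tuple[str, str]] = set()

    def add(name: str, cid: str, seed_cid: str, group: str, source: str) -> None:
        key = (name, cid)
        if name and key not in seen:
            seen.add(key)
            entries.append(
                LexiconEntry(
                    name=name,
                    concept_id=cid,
                    seed_concept_id=seed_cid,
                    group_id=group,
                    source=source,
                )
            )

    group_seed: dict[str, str] = {}
    for seed_cid, group_id, expand_children in seeds:
        if seed_cid not in ontology:
            raise KeyError(f"seed concept {seed_cid!r} not found in ontology")
        group_seed.setdefault(group_id, seed_cid)
        concept = ontology[seed_cid]
        add(concept.preferred_name, seed_cid, seed_cid, group_id, "seed")
        for syn in concept.synonyms:
            add(syn, seed_cid, seed_cid, group_id, "synonym")
        if expand_children:
            frontier = [seed_cid]
            for _ in range(child_depth):
                nxt: list[str] = []
                for cid in frontier:
                    for child in ontology.children(cid):
                        add(
                            child.preferred_name,
                            child.concept_id,
                            seed_cid,
                            group_id,
                            "child",
                        )
                        for syn in child.synonyms:
                            add(syn, child.concept_id, seed_cid, group_id, "child")
                        nxt.append(child.concept_id)
                frontier = nxt
    for phrase, group_id in colloquial:
        seed_cid = group_seed.get(group_id)
        if seed_cid is None:
            raise KeyError(f"colloquial phrase {phrase!r} names unknown group {group_id!r}")
        add(phrase, seed_cid, seed_cid, group_id, "colloquial")
    return entries


# ---------------------------------------------------------------------------
# TF-IDF lemma-bag index
# ---------------------------------------------------------------------------


@dataclass
class _IndexedDoc:
    entry: LexiconEntry
    lemmas: Counter
    weights: dict[str, float] = field(default_factory=dict)
    norm: float = 0.0


class ConceptIndex:
    """Inverted TF-IDF index over lexicon entry names."""

    def __init__(self, docs: list[_IndexedDoc], idf: dict[str, float]):
        self._docs = docs
        self._idf = idf
        self._postings: dict[str, list[int]] = {}
        for i, doc in enumerate(docs):
            for lemma in doc.lemmas:
                self._postings.setdefault(lemma, []).append(i)

    def __len__(self) -> int:
        return len(self._docs)

    def query(self, text: str, k: int = 5) -> list[ConceptMatch]:
        """Top-k candidates by TF-IDF cosine; empty when nothing informative matches."""
        q = Counter(lemma_bag(text))
        if not q:
            return []
        q_weights = {t: c * self._idf.get(t, 0.0) for t, c in q.items()}
        q_norm = sqrt(sum(w * w for w in q_weights.values()))
        if q_norm == 0.0:
            return []
        cand: set[int] = set()
        for lemma in q:
            if self._idf.get(lemma, 0.0) > 0.0:
                cand.update(self._postings.get(lemma, []))
        scored = []
        for i in sorted(cand):
            doc = self._docs[i]
            dot = sum(
                w * doc.weights.get(t, 0.0) for t, w in q_weights.items()
            )
            if dot <= 0.0 or doc.norm == 0.0:
                continue
            score = dot / (q_norm * doc.norm)
            shared = sum(min(c, doc.lemmas[t]) for t, c in q.items() if t in doc.lemmas)
            scored.append((-score, -shared, doc.entry.concept_id, doc.entry.name, i))
        scored.sort()
        out = []
        for rank, (neg_score, _, _, _, i) in enumerate(scored[:k], start=1):
            e = self._docs[i].entry
            out.append(
                ConceptMatch(
                    concept_id=e.concept_id,
                    name=e.name,
                    group_id=e.group_id,
                    score=-neg_score,
                    rank=rank,
                )
            )
        return out


def build_index(entries: Sequence[LexiconEntry]) -> ConceptIndex:
    """Index one document per lexicon entry, keyed by the name's lemma bag.

    The result is invariant to the input order of entries (documents are
    sorted internally on (concept_id, name)).
    """
    if not entries:
        raise ValueError("cannot index an empty lexicon")
    unique: dict[tuple[str, str], LexiconEntry] = {}
    for e in entries:
        unique.setdefault((e.name, e.concept_id), e)
    ordered = sorted(unique.values(), key=lambda e: (e.concept_id, e.name))
    docs = [_IndexedDoc(entry=e, lemmas=Counter(lemma_bag(e.name))) for e in ordered]
    n = len(docs)
    df: Counter = Counter()
    for doc in docs:
        df.update(set(doc.lemmas))
    # idf = ln(N/df); a lemma present in every document carries no weight
    idf = {t: log(n / c) for t, c in df.items()}
    for doc in docs:
        doc.weights = {t: c * idf[t] for t, c in doc.lemmas.items()}
        doc.norm = sqrt(sum(w * w for w in doc.weights.values()))
    return ConceptIndex(docs, idf)


def normalize_mention(
    mention_text: str, index: ConceptIndex, k: int = 5
) -> ConceptMatch | None:
    """Map mention text to the top-ranked lexicon concept, or None."""
    if not mention_text or not mention_text.strip():
        return None
    matches = index.query(mention_text, k=k)
    return matches[0] if matches else None
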