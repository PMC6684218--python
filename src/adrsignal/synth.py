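"""Synthetic forum corpora with planted drug–ADR association strengths.

Every pipeline stage is testable without any external data: this module
generates multi-user post corpora with gold span annotations, a matching
concept-lexicon fixture (ontology + colloquial phrases), drug alias tables
and known-association tables.

Generative model
----------------
Users are independent.  A user writes ``K ~ Poisson(posts_per_user_mean)``
posts.  Each post independently mentions at most one drug, drawn from a
categorical distribution over the configured drugs (with the remaining mass
producing drug-free chatter).  Given a mentioned drug D, the post reports
each ADR group R independently with probability ``emission[D][R]``; a
planted pair simply has a higher emission probability than the uniform
background.  Reported phrases are sampled from the group's phrase bank —
lexicon names, lemma-level inflections or colloquial variants — and embedded
in sentence templates with the gold span recorded at the exact insertion
offsets.  Posts are dated uniformly in the configured range.

Because users are independent and per-post events are independent, the
number of a user's posts reporting an event of per-post probability ``q`` is
Poisson(lambda*q), so the probability that a user contributes to a
unique-user count is ``1 - exp(-lambda*q)``.  :func:`expected_prr` combines
the four resulting inclusion probabilities through the PRR formula — a
plug-in approximation to E[PRR] that the pipeline estimate converges to as
the user count grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Post, write_posts
from .ner import EntitySpan, write_standoff
from .normalize import LexiconEntry, Ontology, OntologyConcept, expand_lexicon
from .stats import PairRecord, write_pair_records

__all__ = [
    "GroupSpec",
    "GenConfig",
    "GoldBundle",
    "DEFAULT_GROUPS",
    "BACKGROUND_GROUPS",
    "default_config",
    "generate_corpus",
    "expected_prr",
    "generate_lexicon_fixture",
    "lexicon_fixture_entries",
    "fixture_ontology",
]


# ---------------------------------------------------------------------------
# concept fixture: 8 target cutaneous ADR groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One target ADR group: seed concept, hierarchy children, phrase banks."""

    group_id: str
    seed_cui: str
    seed_name: str
    synonyms: tuple[str, ...] = ()
    # (cui, preferred name, synonyms) one hierarchy level below the seed
    children: tuple[tuple[str, str, tuple[str, ...]], ...] = ()
    expand_children: bool = False
    colloquial: tuple[str, ...] = ()
    # free-text inflections that must still normalize into this group
    inflected: tuple[str, ...] = ()


# The eight target groups mirror the cutaneous reactions studied with EGFR
# and PD-1 inhibitors: rash, acne, pruritus, nail changes, xerosis,
# hypohidrosis, bullous eruption and psoriasis.  Concept ids are CUI-style;
# the nail-changes subtree uses the published identifiers for disorder of
# nail (C0027339), ingrown toenail (C0027343) and peeling of nails
# (C0263531).
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec(
        group_id="rash",
        seed_cui="C0911001",
        seed_name="Rash",
        synonyms=("Skin rash", "Exanthem"),
        colloquial=("broke out in red bumps", "red spots all over"),
        inflected=("skin rashes",),
    ),
    GroupSpec(
        group_id="acne",
        seed_cui="C0911002",
        seed_name="Acne",
        synonyms=("Acneiform eruption", "Pimples"),
        colloquial=("face full of pimples",),
        inflected=("acneiform eruptions",),
    ),
    GroupSpec(
        group_id="pruritus",
        seed_cui="C0911003",
        seed_name="Pruritus",
        synonyms=("Itching", "Itchy skin"),
        colloquial=("scratching all night",),
        inflected=("skin keeps itching",),
    ),
    GroupSpec(
        group_id="nail changes",
        seed_cui="C0027339",
        seed_name="Disorder of nail",
        synonyms=("Nail changes",),
        children=(
            ("C0027343", "Ingrown toenail", ()),
            ("C0263531", "Peeling of nails", ("Nail peeling",)),
            ("C0911014", "Brittle nails", ()),
        ),
        expand_children=True,
        colloquial=("fingernails keep splitting",),
        inflected=("finger nails have been peeling",),
    ),
    GroupSpec(
        group_id="dry skin",
        seed_cui="C0911005",
        seed_name="Xerosis",
        synonyms=("Dry skin",),
        colloquial=("skin so dry it flakes",),
        inflected=("very dry flaking skin",),
    ),
    GroupSpec(
        group_id="hypohidrosis",
        seed_cui="C0911006",
        seed_name="Hypohidrosis",
        synonyms=("Decreased sweating", "Absent sweating"),
        colloquial=("cannot sweat anymore", "stopped sweating completely"),
        inflected=("decreased sweating lately",),
    ),
    GroupSpec(
        group_id="blistering",
        seed_cui="C0911007",
        seed_name="Bullous eruption",
        synonyms=("Blistering", "Blisters"),
        colloquial=("covered in blisters",),
        inflected=("skin is blistering badly",),
    ),
    GroupSpec(
        group_id="psoriasis",
        seed_cui="C0911008",
        seed_name="Psoriasis",
        synonyms=("Psoriasis flare",),
        colloquial=("scaly patches flaring up",),
        inflected=("psoriasis flares",),
    ),
)

# Non-target ADR chatter so count(D) reflects *all* extracted mentions, not
# only the eight target groups.  These never enter the lexicon.
BACKGROUND_GROUPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("fatigue", ("fatigue", "constant exhaustion")),
    ("nausea", ("nausea", "queasy stomach")),
    ("headache", ("headache", "pounding head")),
    ("weight gain", ("weight gain", "gained a lot of weight")),
)

_INDICATIONS = ("lung cancer", "breast cancer", "melanoma", "kidney cancer", "colon cancer")

_OPENERS = (
    "hope everyone is doing well today.",
    "checking in after another clinic visit.",
    "quick update from me.",
    "long time reader first time posting.",
    "sending good thoughts to this group.",
)
_CLOSERS = (
    "thanks for listening.",
    "grateful for this community.",
    "will keep you all posted.",
    "stay strong everyone.",
)
_DRUG_TEMPLATES = (
    "i started {drug} last month.",
    "my doctor put me on {drug} again.",
    "still taking {drug} every morning.",
    "the oncologist switched me to {drug}.",
)
_ADR_TEMPLATES = (
    "my {phrase} is getting worse.",
    "been dealing with {phrase} for weeks.",
    "the {phrase} started after the last dose.",
    "anyone else with {phrase} on this treatment?",
)
_COLLOQUIAL_TEMPLATES = (
    "{phrase} since starting treatment.",
    "lately {phrase} and it is wearing me down.",
    "honestly {phrase} these days.",
)
_IND_TEMPLATES = (
    "i was diagnosed with {phrase} two years ago.",
    "my {phrase} was caught early.",
)

_DRUG_STEMS = (
    "alba", "bora", "cerin", "dolu", "erva", "fina", "gora", "hexa", "ilo",
    "juva", "kora", "lima", "mira", "nova", "ora", "pira", "quena", "rova",
    "sela", "tova", "ulma", "vora", "wila", "xena", "yora", "zela", "arva",
    "brona", "cova", "dira",
)


def _default_drugs(n: int) -> dict[str, list[str]]:
    if n > len(_DRUG_STEMS):
        raise ValueError(f"at most {len(_DRUG_STEMS)} default drugs are available")
    out = {}
    for stem in _DRUG_STEMS[:n]:
        generic = f"{stem}nib"
        brand = f"{stem.capitalize()}vex"
        out[generic] = [generic, brand.lower()]
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenConfig:
    """Full generative specification of a synthetic forum corpus."""

    n_users: int
    posts_per_user_mean: float
    drug_probs: dict[str, float]  # categorical per post; sum <= 1
    emission: dict[str, dict[str, float]]  # P(report group | post mentions drug)
    aliases: dict[str, list[str]]
    indication_prob: float = 0.05
    nodrug_adr_prob: float = 0.05  # ADR chatter in drug-free posts
    colloquial_rate: float = 0.25
    inflected_rate: float = 0.15
    brand_rate: float = 0.3
    date_range: tuple[date, date] = (date(2010, 1, 1), date(2016, 12, 31))
    seed: int = 0
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    background_groups: tuple[tuple[str, tuple[str, ...]], ...] = BACKGROUND_GROUPS

    def __post_init__(self):
        if self.n_users < 1 or self.posts_per_user_mean <= 0:
            raise ValueError("need n_users >= 1 and a positive posts-per-user mean")
        if not self.drug_probs or not self.groups:
            raise ValueError("need at least one drug and one group")
        total = sum(self.drug_probs.values())
        if any(not 0.0 <= p <= 1.0 for p in self.drug_probs.values()) or total > 1.0 + 1e-12:
            raise ValueError("drug probabilities must lie in [0,1] and sum to at most 1")
        for drug, probs in self.emission.items():
            if drug not in self.drug_probs:
                raise ValueError(f"emission rates for unknown drug {drug!r}")
            for group, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"emission[{drug!r}][{group!r}]={p} outside [0,1]")
        for p in (self.indication_prob, self.nodrug_adr_prob, self.colloquial_rate,
                  self.inflected_rate, self.brand_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rate parameters must lie in [0,1]")
        for spec in self.groups:
            if not (spec.colloquial or spec.seed_name):
                raise ValueError(f"group {spec.group_id!r} has no phrases")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("empty date range")

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.drug_probs)

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    @property
    def all_group_ids(self) -> list[str]:
        return self.group_ids + [g for g, _ in self.background_groups]

    def plant(self, drug_id: str, group_id: str, prob: float) -> "GenConfig":
        """Copy of this config with one (drug, group) emission rate replanted."""
        if drug_id not in self.drug_probs:
            raise KeyError(drug_id)
        if group_id not in self.all_group_ids:
            raise KeyError(group_id)
        emission = {d: dict(p) for d, p in self.emission.items()}
        emission.setdefault(drug_id, {})[group_id] = prob
        return replace(self, emission=emission)


def default_config(
    n_users: int = 1000,
    seed: int = 0,
    n_drugs: int = 20,
    posts_per_user_mean: float = 3.0,
    drug_prob: float = 0.04,
    background_emission: float = 0.03,
) -> GenConfig:
    """Null-model configuration: every drug–group emission rate is equal.

    A planted pair is added with :meth:`GenConfig.plant`.  The defaults give
    each post a 0.8 chance of mentioning one of 20 drugs and each mentioned
    drug a 3% chance per group of co-reporting any of the 12 ADR groups
    (8 targets + 4 background).
    """
    aliases = _default_drugs(n_drugs)
    drugs = sorted(aliases)
    groups = [g.group_id for g in DEFAULT_GROUPS] + [g for g, _ in BACKGROUND_GROUPS]
    return GenConfig(
        n_users=n_users,
        posts_per_user_mean=posts_per_user_mean,
        drug_probs={d: drug_prob for d in drugs},
        emission={d: {g: background_emission for g in groups} for d in drugs},
        aliases=aliases,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


@dataclass
class GoldBundle:
    """A generated corpus with its gold annotations and pair table."""

    posts: list[Post]
    gold_spans: list[EntitySpan]
    gold_pairs: list[PairRecord]
    config: GenConfig

    def labeled_sentences(self):
        """(TokenizedSentence, gold spans) pairs for tagger training."""
        from .text import split_sentences

        by_post: dict[str, list[EntitySpan]] = {}
        for span in self.gold_spans:
            by_post.setdefault(span.post_id, []).append(span)
        labeled = []
        for post in self.posts:
            for sentence in split_sentences(post.body, post_id=post.post_id):
                labeled.append((sentence, by_post.get(post.post_id, [])))
        return labeled

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_posts(self.posts, out / "posts.jsonl")
        write_standoff(self.gold_spans, out / "gold_spans.tsv")
        write_pair_records(self.gold_pairs, out / "gold_pairs.tsv")
        with (out / "aliases.tsv").open("w", encoding="utf-8") as fh:
            for drug in sorted(self.config.aliases):
                for alias in self.config.aliases[drug]:
                    fh.write(f"{drug}\t{alias}\n")


def _group_phrase(spec: GroupSpec, rng: np.random.Generator, config: GenConfig):
    """Sample (surface phrase, is_colloquial) for one target group."""
    u = rng.random()
    if spec.colloquial and u < config.colloquial_rate:
        return str(rng.choice(spec.colloquial)), True
    if spec.inflected and u < config.colloquial_rate + config.inflected_rate:
        return str(rng.choice(spec.inflected)), False
    names = (spec.seed_name,) + spec.synonyms
    return str(rng.choice(names)).lower(), False


def generate_corpus(config: GenConfig) -> GoldBundle:
    """Generate posts, gold spans and the gold drug–ADR pair table.

    Identical configuration (including the seed) reproduces the bundle byte
    for byte.
    """
    rng = np.random.default_rng(config.seed)
    drugs = config.drug_ids
    probs = np.array([config.drug_probs[d] for d in drugs])
    p_none = 1.0 - probs.sum()
    choices = drugs + [None]
    choice_p = np.append(probs, max(p_none, 0.0))
    choice_p = choice_p / choice_p.sum()
    lo, hi = config.date_range
    n_days = (hi - lo).days + 1
    spec_by_group = {g.group_id: g for g in config.groups}
    bg_by_group = dict(config.background_groups)

    posts: list[Post] = []
    spans: list[EntitySpan] = []
    pairs: list[PairRecord] = []
    post_no = 0
    for u in range(config.n_users):
        user_id = f"u{u:05d}"
        for _ in range(int(rng.poisson(config.posts_per_user_mean))):
            post_no += 1
            post_id = f"p{post_no:07d}"
            when = lo + timedelta(days=int(rng.integers(n_days)))
            drug = choices[int(rng.choice(len(choices), p=choice_p))]

            body_parts: list[str] = [str(rng.choice(_OPENERS))]
            post_spans: list[tuple[int, int, str, str]] = []  # rel. later

            def _append_phrase_sentence(templates, phrase: str, label: str):
                template = str(rng.choice(templates))
                prefix, suffix = template.split("{phrase}")
                offset = sum(len(p) + 1 for p in body_parts)  # +1 per joining space
                start = offset + len(prefix)
                body_parts.append(prefix + phrase + suffix)
                post_spans.append((start, start + len(phrase), phrase, label))

            if drug is not None:
                alias = config.aliases[drug][1] if (
                    len(config.aliases[drug]) > 1 and rng.random() < config.brand_rate
                ) else config.aliases[drug][0]
                template = str(rng.choice(_DRUG_TEMPLATES))
                body_parts.append(template.format(drug=alias))
                emitted: list[str] = []
                for group in config.all_group_ids:
                    if rng.random() < config.emission.get(drug, {}).get(group, 0.0):
                        emitted.append(group)
                for group in emitted:
                    if group in spec_by_group:
                        phrase, colloquial = _group_phrase(
                            spec_by_group[group], rng, config
                        )
                        templates = (
                            _COLLOQUIAL_TEMPLATES if colloquial else _ADR_TEMPLATES
                        )
                    else:
                        phrase = str(rng.choice(bg_by_group[group]))
                        templates = _ADR_TEMPLATES
                    _append_phrase_sentence(templates, phrase, "ADR")
                    pairs.append(
                        PairRecord(
                            drug_id=drug,
                            group_id=group,
                            user_id=user_id,
                            post_id=post_id,
                            date=when,
                        )
                    )
            elif rng.random() < config.nodrug_adr_prob:
                group = config.all_group_ids[int(rng.integers(len(config.all_group_ids)))]
                if group in spec_by_group:
                    phrase, colloquial = _group_phrase(spec_by_group[group], rng, config)
                    templates = _COLLOQUIAL_TEMPLATES if colloquial else _ADR_TEMPLATES
                else:
                    phrase = str(rng.choice(bg_by_group[group]))
                    templates = _ADR_TEMPLATES
                _append_phrase_sentence(templates, phrase, "ADR")

            if rng.random() < config.indication_prob:
                _append_phrase_sentence(
                    _IND_TEMPLATES, str(rng.choice(_INDICATIONS)), "IND"
                )
            body_parts.append(str(rng.choice(_CLOSERS)))

            body = " ".join(body_parts)
            posts.append(
                Post(post_id=post_id, user_id=user_id, created_at=when, body=body)
            )
            for start, end, phrase, label in post_spans:
                assert body[start:end] == phrase
                spans.append(
                    EntitySpan(
                        post_id=post_id,
                        char_start=start,
                        char_end=end,
                        surface=phrase,
                        label=label,
                        score=1.0,
                    )
                )
    return GoldBundle(posts=posts, gold_spans=spans, gold_pairs=pairs, config=config)


# ---------------------------------------------------------------------------
# closed-form expected PRR
# ---------------------------------------------------------------------------


def _p_any_adr(config: GenConfig, drug: str) -> float:
    """Per-post P(the post mentions `drug` and reports >= 1 ADR group)."""
    none_reported = 1.0
    for group in config.all_group_ids:
        none_reported *= 1.0 - config.emission.get(drug, {}).get(group, 0.0)
    return config.drug_probs[drug] * (1.0 - none_reported)


def expected_prr(
    config: GenConfig,
    drug_id: str,
    group_id: str,
    comparison_drugs: Sequence[str] | None = None,
) -> float:
    """Plug-in expected PRR of a pair under the generative model.

    Each unique-user count is replaced by its expectation: a user's number
    of posts matching a per-post event of probability q is
    Poisson(lambda*q), so the user-inclusion probability is
    ``1 - exp(-lambda*q)``.  The four inclusion probabilities are combined
    through the PRR formula (the common factor n_users cancels).
    """
    if drug_id not in config.drug_probs:
        raise KeyError(drug_id)
    if group_id not in config.all_group_ids:
        raise KeyError(group_id)
    comparison = (
        [d for d in config.drug_ids if d != drug_id]
        if comparison_drugs is None
        else list(comparison_drugs)
    )
    if drug_id in comparison:
        raise ValueError("target drug cannot be its own comparator")
    lam = config.posts_per_user_mean

    def incl(q: float) -> float:
        return 1.0 - math.exp(-lam * q)

    q_dr = config.drug_probs[drug_id] * config.emission.get(drug_id, {}).get(group_id, 0.0)
    q_d = _p_any_adr(config, drug_id)
    q_ndr = sum(
        config.drug_probs[d] * config.emission.get(d, {}).get(group_id, 0.0)
        for d in comparison
    )
    q_nd = sum(_p_any_adr(config, d) for d in comparison)
    e_d, e_nd = incl(q_d), incl(q_nd)
    if e_d == 0.0 or e_nd == 0.0:
        raise ValueError("expected count(D) or count(!D) is zero under this config")
    e_ndr = incl(q_ndr)
    if e_ndr == 0.0:
        return math.inf
    return (incl(q_dr) / e_d) / (e_ndr / e_nd)


# ---------------------------------------------------------------------------
# lexicon fixture
# ---------------------------------------------------------------------------


def fixture_ontology(groups: Sequence[GroupSpec] = DEFAULT_GROUPS) -> Ontology:
    """Ontology stand-in with one subtree per target group under one root."""
    root = OntologyConcept("C0911000", "Skin disorder", (), ())
    concepts = [root]
    for spec in groups:
        concepts.append(
            OntologyConcept(
                concept_id=spec.seed_cui,
                preferred_name=spec.seed_name,
                synonyms=spec.synonyms,
                parents=(root.concept_id,),
            )
        )
        for cui, name, syns in spec.children:
            concepts.append(
                OntologyConcept(
                    concept_id=cui,
                    preferred_name=name,
                    synonyms=syns,
                    parents=(spec.seed_cui,),
                )
            )
    return Ontology(concepts)


def lexicon_fixture_entries(
    groups: Sequence[GroupSpec] = DEFAULT_GROUPS,
) -> list[LexiconEntry]:
    """The default lexicon: seeds + synonyms + children + colloquial phrases."""
    ontology = fixture_ontology(groups)
    seeds = [(g.seed_cui, g.group_id, g.expand_children) for g in groups]
    colloquial = [(p, g.group_id) for g in groups for p in g.colloquial]
    return expand_lexicon(seeds, ontology, colloquial)


def generate_lexicon_fixture(
    out_dir: str | Path, groups: Sequence[GroupSpec] = DEFAULT_GROUPS
) -> dict[str, Path]:
    """Write ontology, seeds, colloquial and expanded lexicon files.

    The files round-trip through the concept-normalizer loaders and the
    expanded lexicon satisfies self-resolution for every entry.
    """
    if not groups:
        raise ValueError("at least one group is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology = fixture_ontology(groups)
    paths = {
        "ontology": out / "ontology.tsv",
        "seeds": out / "seeds.tsv",
        "colloquial": out / "colloquial.tsv",
        "lexicon": out / "lexicon.tsv",
    }
    with paths["ontology"].open("w", encoding="utf-8") as fh:
        for concept in ontology.concepts.values():
            fh.write(
                f"{concept.concept_id}\t{concept.preferred_name}"
                f"\t{'|'.join(concept.synonyms)}\t{'|'.join(concept.parents)}\n"
            )
    with paths["seeds"].open("w", encoding="utf-8") as fh:
        for g in groups:
            fh.write(f"{g.seed_cui}\t{g.group_id}\t{str(g.expand_children).lower()}\n")
    with paths["colloquial"].open("w", encoding="utf-8") as fh:
        for g in groups:
            for phrase in g.colloquial:
                fh.write(f"{phrase}\t{g.group_id}\n")
    from .normalize import write_lexicon

    write_lexicon(lexicon_fixture_entries(groups), paths["lexicon"])
    return paths
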