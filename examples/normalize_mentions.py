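"""Map free-text ADR mentions to grouped medical concepts.

Builds the 8-group target-ADR lexicon (seed concepts + synonyms + hierarchy
children + colloquial phrases), indexes it by lemma bags, and resolves a
few patient-style mentions — including the classic inflected query
"finger nails have been peeling".
"""

from adrsignal.normalize import build_index, normalize_mention
from adrsignal.synth import lexicon_fixture_entries

entries = lexicon_fixture_entries()
groups = sorted({e.group_id for e in entries})
print(f"lexicon: {len(entries)} entries across {len(groups)} ADR groups")
print("groups:", ", ".join(groups))

index = build_index(entries)
queries = [
    "finger nails have been peeling",
    "cannot sweat anymore",
    "itchy skin",
    "scaly patches flaring up",
    "zzqq blargh",
]
for query in queries:
    match = normalize_mention(query, index)
    if match is None:
        print(f"{query!r:40s} -> no concept (nothing informative shared)")
    else:
        print(f"{query!r:40s} -> {match.concept_id} "
              f"({match.name}; group: {match.group_id}; score {match.score:.2f})")
print("-> queries and entry names pass through the identical tokenize+lemmatize")
print("   step; ranking is TF-IDF cosine over shared lemmas.")
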