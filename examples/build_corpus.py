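"""Build per-drug corpora from forum posts by alias matching.

Generates a small synthetic forum, selects the posts that mention a drug of
interest (by any generic or brand alias, at word boundaries), and merges
two drugs into a class corpus the way posts for same-mechanism drugs are
pooled.
"""

from adrsignal.corpus import build_drug_corpus, compile_drug_matcher, merge_corpora
from adrsignal.synth import default_config, generate_corpus

config = default_config(n_users=500, seed=1)
bundle = generate_corpus(config)
print(f"forum: {len(bundle.posts)} posts from {config.n_users} users")

corpora = {}
for drug in ("albanib", "boranib"):
    matcher = compile_drug_matcher(config.aliases[drug])
    corpora[drug] = build_drug_corpus(bundle.posts, matcher, drug)
    print(f"{drug}: {len(corpora[drug])} posts mention it "
          f"(aliases: {', '.join(config.aliases[drug])})")

merged = merge_corpora(list(corpora.values()), "example-class")
print(f"merged class corpus: {len(merged)} unique posts")
print("-> each count is the number of posts containing >=1 alias match;")
print("   the merge deduplicates posts that mention both drugs.")
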